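"""Concatenated-alignment phylogenetics: supermatrix, LogDet distances,
neighbour joining, and bootstrap support.

The distance used is the LogDet (paralinear) distance, which is robust to
compositional bias between lineages:

    d(x, y) = -(1/4) * [ ln det F  -  (1/2) * sum_i ln(r_i * c_i) ]

where ``F`` is the 4x4 joint relative-frequency matrix of aligned site
patterns over the usable sites of the pair (pairwise deletion of gaps and
N), and ``r``/``c`` are its row and column marginals. Sites are treated as
independent. If a base is absent from both sequences the corresponding
row/column pair is dropped before taking the determinant, so identical
sequences are at distance 0 regardless of composition; a non-positive
determinant (saturation) is an error state.

Tree inference is Saitou-Nei neighbour joining: iteratively join the pair
minimising Q(i,j) = (n-2) d(i,j) - R_i - R_j, with the standard branch
length and distance-update formulas. NJ recovers the generating tree
exactly on additive distance matrices. Ties on Q are broken towards the
lexicographically smallest cluster pair so results are deterministic.

Bootstrap support resamples supermatrix columns with replacement, re-infers
an NJ tree per replicate, and annotates each internal edge of the tree from
the *original* matrix with the percentage of replicates containing the same
bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seq_io import SeqRecord, newick_to_tree

logger = logging.getLogger(__name__)

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "SaturationError",
    "concatenate",
    "logdet_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

# Encoding used throughout: A=0 C=1 G=2 T=3, gap/N = 4 (excluded pairwise).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SaturationError(ValueError):
    """LogDet distance undefined: no usable sites or det F <= 0."""


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Genome x concatenated-aligned-columns matrix with block boundaries.

    ``boundaries`` holds (family_id, start, end) with 1-based inclusive
    column coordinates, partitioning the columns in family order.
    """

    genomes: list[str]
    rows: dict[str, str]
    boundaries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_records(self) -> list[SeqRecord]:
        return [SeqRecord(g, self.rows[g]) for g in self.genomes]


def concatenate(
    blocks: dict[str, list[SeqRecord]],
    genomes: list[str],
    family_order: list[str] | None = None,
) -> Supermatrix:
    """Concatenate per-family alignment blocks into a supermatrix.

    A genome absent from a block contributes an all-gap segment of that
    block's width. Duplicate genomes within one block are an error.
    """
    order = family_order if family_order is not None else sorted(blocks)
    rows = {g: [] for g in genomes}
    boundaries: list[tuple[str, int, int]] = []
    pos = 0
    for fam in order:
        recs = blocks[fam]
        seen: dict[str, str] = {}
        for rec in recs:
            if rec.id in seen:
                raise ValueError(f"block {fam}: duplicate genome {rec.id!r}")
            seen[rec.id] = rec.sequence
        widths = {len(s) for s in seen.values()}
        if len(widths) > 1:
            raise ValueError(f"block {fam}: rows of unequal length {sorted(widths)}")
        width = widths.pop() if widths else 0
        for g in genomes:
            rows[g].append(seen.get(g, "-" * width))
        boundaries.append((fam, pos + 1, pos + width))
        pos += width
    return Supermatrix(
        genomes=list(genomes),
        rows={g: "".join(parts) for g, parts in rows.items()},
        boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# LogDet distance
# ---------------------------------------------------------------------------

def _logdet_from_counts(joint: np.ndarray) -> float:
    """LogDet distance from a 4x4 matrix of joint site-pattern counts."""
    total = joint.sum()
    if total == 0:
        raise SaturationError("no usable (gap-free) sites shared by the pair")
    F = joint / total
    r = F.sum(axis=1)
    c = F.sum(axis=0)
    # Drop bases absent from both sequences: keeps identical sequences at
    # distance zero whatever their composition.
    present = (r > 0) | (c > 0)
    F = F[np.ix_(present, present)]
    r = r[present]
    c = c[present]
    if np.any(r == 0) or np.any(c == 0):
        raise SaturationError("a base occurs in only one sequence of the pair")
    det = np.linalg.det(F)
    if det <= 0:
        raise SaturationError(f"det F = {det:g} <= 0 (saturated pair)")
    return float(-0.25 * (np.log(det) - 0.5 * np.sum(np.log(r * c))))


def logdet_distance(x: str, y: str) -> float:
    """LogDet (paralinear) distance between two aligned sequences.

    Sites where either sequence has a gap or N are excluded (pairwise
    deletion). Raises :class:`SaturationError` when the distance is
    undefined (zero usable sites or a non-positive determinant).
    """
    if len(x) != len(y):
        raise ValueError("aligned rows must have equal length")
    ex, ey = _encode(x), _encode(y)
    usable = (ex < 4) & (ey < 4)
    joint = np.bincount(
        (ex[usable].astype(np.intp) * 4 + ey[usable]), minlength=16
    ).reshape(4, 4).astype(float)
    return _logdet_from_counts(joint)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v


def distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """All-pairs LogDet distances from a supermatrix."""
    taxa = list(matrix.genomes)
    enc = [_encode(matrix.rows[g]) for g in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (enc[i] < 4) & (enc[j] < 4)
            joint = np.bincount(
                enc[i][usable].astype(np.intp) * 4 + enc[j][usable], minlength=16
            ).reshape(4, 4).astype(float)
            d[i, j] = d[j, i] = _logdet_from_counts(joint)
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "edge_lengths", "rep")

    def __init__(self, label=None, children=None, edge_lengths=None, rep=None):
        self.label = label
        self.children = children or []
        self.edge_lengths = edge_lengths or []
        self.rep = rep if rep is not None else label  # smallest leaf name

    def newick(self) -> str:
        if not self.children:
            return self.label
        parts = [
            f"{c.newick()}:{l:.10f}"
            for c, l in zip(self.children, self.edge_lengths)
        ]
        return "(" + ",".join(parts) + ")"


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; exact on additive matrices.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge of the joined pair. Returns an unrooted dendropy tree.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    dist = d.values.astype(float).copy()
    nodes = [_Node(label=t) for t in d.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(
                sorted((nodes[active[ab[0]]].rep, nodes[active[ab[1]]].rep))
            ),
        )
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = dist[i, j]
        li = 0.5 * dij + (R[ai] - R[bi]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives; move the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        new = _Node(
            children=[nodes[i], nodes[j]],
            edge_lengths=[li, lj],
            rep=min(nodes[i].rep, nodes[j].rep),
        )
        # grow the distance matrix with the new cluster
        k = dist.shape[0]
        newrow = np.zeros(k + 1)
        for x in active:
            if x in (i, j):
                continue
            newrow[x] = 0.5 * (dist[i, x] + dist[j, x] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[k, :k] = newrow[:k]
        dist[:k, k] = newrow[:k]
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    # join the last three clusters at an unresolved root
    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    root = _Node(
        children=[nodes[a], nodes[b], nodes[c]],
        edge_lengths=[la, lb, lc],
        rep=min(nodes[a].rep, nodes[b].rep, nodes[c].rep),
    )
    return newick_to_tree(root.newick() + ";")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as leaf-name sets.

    Each bipartition is represented by the side not containing the
    alphabetically first leaf, making the representation rotation- and
    rooting-invariant.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    matrix: Supermatrix,
    n_reps: int = 100,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree from the original matrix, internal edges annotated with
    bootstrap support (percent of column-resampled replicates containing
    the same bipartition, rounded to an integer).

    Replicates in which a pair of rows shares no usable site (or the
    distance saturates) are skipped with a log message; the denominator
    stays ``n_reps``.
    """
    if len(matrix.genomes) < 4:
        raise ValueError("bootstrap support requires at least 4 taxa")
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    rng = np.random.default_rng(seed)
    tree = nj_tree(distance_matrix(matrix))
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)

    enc = np.vstack([_encode(matrix.rows[g]) for g in matrix.genomes])
    ncol = enc.shape[1]
    counts: dict[frozenset, int] = {}
    skipped = 0
    for rep in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        sub = enc[:, cols]
        try:
            d = _pairwise_logdet(sub)
        except SaturationError as exc:
            skipped += 1
            logger.info("bootstrap replicate %d skipped: %s", rep, exc)
            continue
        rep_tree = nj_tree(DistanceMatrix(list(matrix.genomes), d))
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    if skipped:
        logger.warning("%d/%d bootstrap replicates skipped", skipped, n_reps)

    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            support = round(100 * counts.get(frozenset(side), 0) / n_reps)
            node.label = str(int(support))
    return tree


def _pairwise_logdet(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (enc[i] < 4) & (enc[j] < 4)
            joint = np.bincount(
                enc[i][usable].astype(np.intp) * 4 + enc[j][usable], minlength=16
            ).reshape(4, 4).astype(float)
            d[i, j] = d[j, i] = _logdet_from_counts(joint)
    return d
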