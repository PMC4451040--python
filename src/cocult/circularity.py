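"""Circular-contig (plasmid) detection by contig end joining.

A contig assembled from a circular replicon, when linearised with a
terminal (k-1)-mer overlap, has a 5' end and a 3' end that join each other
and — crucially — join *no other* contig end. That unambiguous self-join is
the circularity criterion here. Ends are compared by their terminal
(k-1)-mers (default k = 51, i.e. 50 bp overlaps), reverse-complement aware.

Optionally, raw reads confirm each join: an edge's support is the number of
reads containing the junction-spanning 2(k-1)-mer on either strand, and a
self-join is only called circular when support reaches the cutoff (default
15). This contig-level check replaces a full read-graph traversal; the
read-support layer is the corresponding confirmation step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .seq_io import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "End",
    "EndGraph",
    "CircularityCall",
    "build_end_graph",
    "detect_circular",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

FIVE = "5p"
THREE = "3p"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


End = tuple[str, str]  # (contig_id, FIVE | THREE)


@dataclass
class EndGraph:
    k: int
    nodes: list[End]
    edges: dict[frozenset, int | None] = field(default_factory=dict)
    # edge -> junction read support (None when no reads were supplied)
    skipped: list[str] = field(default_factory=list)  # contigs shorter than k

    def edges_of(self, end: End) -> list[frozenset]:
        return [e for e in self.edges if end in e]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, support in sorted(self.edges.items(), key=lambda kv: sorted(kv[0])):
            (c1, e1), (c2, e2) = sorted(e)
            rows.append(
                {"contig_1": c1, "end_1": e1, "contig_2": c2, "end_2": e2,
                 "support": "" if support is None else support}
            )
        return pd.DataFrame(
            rows, columns=["contig_1", "end_1", "contig_2", "end_2", "support"]
        )


@dataclass
class CircularityCall:
    contig_id: str
    is_circular: bool
    reason: str  # self-join-unambiguous | no-join | ambiguous-join | insufficient-support
    support: int | None = None

    def __post_init__(self) -> None:
        if self.is_circular and self.reason != "self-join-unambiguous":
            raise ValueError("circular calls must be unambiguous self-joins")


def _ends_join(seqs: dict[str, str], a: End, b: End, k: int) -> bool:
    """Orientation-consistent terminal (k-1)-mer match between two ends."""
    o = k - 1
    ca, ea = a
    cb, eb = b
    prefix = lambda c: seqs[c][:o]
    suffix = lambda c: seqs[c][-o:]
    if ea == THREE and eb == FIVE:
        return suffix(ca) == prefix(cb)
    if ea == FIVE and eb == THREE:
        return suffix(cb) == prefix(ca)
    if ea == THREE and eb == THREE:
        return suffix(ca) == revcomp(suffix(cb))
    return prefix(ca) == revcomp(prefix(cb))


def build_end_graph(
    contigs: list[SeqRecord],
    k: int = 51,
    reads=None,
    support_cutoff: int = 15,
) -> EndGraph:
    """Join contig ends whose terminal (k-1)-mers match, orientation-aware.

    Contigs shorter than ``k`` are skipped with a warning. When ``reads``
    are supplied every edge is annotated with the number of reads (either
    strand) containing the 2(k-1) bp junction formed by the join.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    seqs: dict[str, str] = {}
    skipped: list[str] = []
    for rec in contigs:
        if len(rec.sequence) < k:
            logger.warning("contig %s shorter than k=%d; skipped", rec.id, k)
            skipped.append(rec.id)
        else:
            seqs[rec.id] = rec.sequence
    o = k - 1
    nodes: list[End] = [(c, e) for c in seqs for e in (FIVE, THREE)]

    # group ends by canonical terminal mer, then verify orientation in-group
    groups: dict[str, list[End]] = {}
    for c in seqs:
        for end, mer in ((FIVE, seqs[c][:o]), (THREE, seqs[c][-o:])):
            canon = min(mer, revcomp(mer))
            groups.setdefault(canon, []).append((c, end))

    edges: dict[frozenset, int | None] = {}
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a == b:
                    continue
                if _ends_join(seqs, a, b, k):
                    edges[frozenset((a, b))] = None

    if reads is not None:
        haystack = _read_haystack(reads)
        for edge in edges:
            junction = _junction(seqs, edge, k)
            edges[edge] = haystack.count(junction) + haystack.count(
                revcomp(junction)
            )
    return EndGraph(k=k, nodes=nodes, edges=edges, skipped=skipped)


def _read_haystack(reads) -> str:
    seqs = []
    for item in reads:
        rec = item[0] if isinstance(item, tuple) else item
        seqs.append(rec.sequence if isinstance(rec, SeqRecord) else str(rec))
    return "\n".join(seqs)


def _junction(seqs: dict[str, str], edge: frozenset, k: int) -> str:
    """The 2(k-1) bp sequence spanning a join, in the joined orientation."""
    o = k - 1
    (a, b) = sorted(edge)
    (ca, ea), (cb, eb) = a, b
    if ea == THREE and eb == FIVE:
        return seqs[ca][-o:] + seqs[cb][o : 2 * o]
    if ea == FIVE and eb == THREE:
        return seqs[cb][-o:] + seqs[ca][o : 2 * o]
    if ea == THREE and eb == THREE:
        return seqs[ca][-o:] + revcomp(seqs[cb][-2 * o : -o])
    # 5'-5' join: revcomp of a precedes b
    return revcomp(seqs[ca][:o]) + seqs[cb][o : 2 * o]


def detect_circular(
    graph: EndGraph, support_cutoff: int = 15
) -> list[CircularityCall]:
    """Apply the unambiguous self-join rule to every contig in the graph.

    Circular iff the contig's 5' and 3' ends join each other, neither end
    has any other edge, and (when read support was annotated) the self-join
    support reaches ``support_cutoff``.
    """
    contigs = sorted({c for c, _ in graph.nodes})
    calls = []
    for c in contigs:
        five, three = (c, FIVE), (c, THREE)
        self_edge = frozenset((five, three))
        e5 = graph.edges_of(five)
        e3 = graph.edges_of(three)
        if self_edge not in graph.edges:
            calls.append(CircularityCall(c, False, "no-join"))
            continue
        support = graph.edges[self_edge]
        if len(e5) > 1 or len(e3) > 1:
            calls.append(CircularityCall(c, False, "ambiguous-join", support))
            continue
        if support is not None and support < support_cutoff:
            calls.append(CircularityCall(c, False, "insufficient-support", support))
            continue
        calls.append(CircularityCall(c, True, "self-join-unambiguous", support))
    return calls
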