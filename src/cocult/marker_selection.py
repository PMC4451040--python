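"""Phylogenomic marker curation.

Starting from per-family copy-number profiles over a set of trusted genomes,
markers suitable for concatenated phylogenetic inference are selected in four
steps:

1. **Prevalence filter** — keep families present *exactly once* in more than a
   threshold fraction (default 90%) of the trusted genomes.
2. **Redundancy collapse** — the same protein family can be described by two
   annotation databases (an "A", Pfam-like, and a "B", TIGRFAM-like source).
   If an A-family and a B-family hit identical gene sets in more than 90% of
   the trusted genomes they are redundant and the B-family is preferred.
3. **Congruence test** — for every genome carrying two or more copies of a
   family, the copies have a congruent phylogenetic history iff every leaf
   under their most recent common ancestor in the family's gene tree belongs
   to a genome of the same species (a single conspecific clade).
4. **Divergence filter** — drop families whose copies are divergent in more
   than a threshold fraction (default 1%) of *all* trusted genomes.

All thresholds are strict ``>`` comparisons; boundary cases fall on the
excluded side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceMatrix",
    "GeneTree",
    "CongruenceReport",
    "SelectedMarkers",
    "SelectionConfig",
    "prevalence_filter",
    "redundancy_collapse",
    "congruence_test",
    "congruence_report",
    "divergence_filter",
    "select_markers",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Copy counts of gene families across trusted genomes.

    Parameters
    ----------
    counts :
        family_id -> {genome_id -> copy count}. Genomes not listed for a
        family have count 0.
    sources :
        family_id -> "A" (Pfam-like) or "B" (TIGRFAM-like).
    genomes :
        the full trusted-genome list (the denominator of every fraction).
    gene_hits :
        optional family_id -> {genome_id -> frozenset of gene ids hit};
        required for redundancy collapse.
    """

    counts: dict[str, dict[str, int]]
    sources: dict[str, str]
    genomes: list[str]
    gene_hits: dict[str, dict[str, frozenset]] | None = None

    def __post_init__(self) -> None:
        for fam, row in self.counts.items():
            for g, c in row.items():
                if c < 0:
                    raise ValueError(f"family {fam}: negative count for {g}")

    @property
    def families(self) -> list[str]:
        return sorted(self.counts)

    def copy_count(self, family: str, genome: str) -> int:
        return self.counts.get(family, {}).get(genome, 0)


@dataclass
class GeneTree:
    """A family gene tree with leaves labelled ``genome|copy_index``."""

    tree: dendropy.Tree
    taxonomy: dict[str, str]  # genome_id -> species_id

    def leaf_genomes(self) -> dict[str, list[str]]:
        """Map genome_id -> list of its leaf labels in the tree."""
        out: dict[str, list[str]] = {}
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label
            genome = label.rsplit("|", 1)[0]
            if genome not in self.taxonomy:
                raise KeyError(f"leaf genome {genome!r} absent from taxonomy map")
            out.setdefault(genome, []).append(label)
        return out


@dataclass
class CongruenceReport:
    """Per-family congruence summary over the trusted-genome set."""

    n_trusted_genomes: int
    per_family: dict[str, tuple[int, int]] = field(default_factory=dict)
    # family -> (n_multicopy_genomes, n_divergent_genomes)

    def divergent_fraction(self, family: str) -> float:
        _, n_div = self.per_family[family]
        return n_div / self.n_trusted_genomes


@dataclass
class SelectedMarkers:
    """Outcome of the full selection with a complete audit trail."""

    retained: list[str]
    initial: list[str]  # families passing the prevalence filter
    redundancy_removed: list[tuple[str, str]]  # (dropped A, kept B) pairs
    candidates: list[str]  # after redundancy collapse, fed to congruence test
    divergence_removed: list[str]


@dataclass
class SelectionConfig:
    prevalence_threshold: float = 0.90
    redundancy_threshold: float = 0.90
    max_divergent_fraction: float = 0.01


# ---------------------------------------------------------------------------
# Step 1: prevalence
# ---------------------------------------------------------------------------

def prevalence_filter(matrix: PresenceMatrix, threshold: float = 0.90) -> set[str]:
    """Families present exactly once in > ``threshold`` of the trusted genomes.

    The comparison is strict: a family exactly-single-copy in precisely 90%
    of genomes is excluded at the default threshold.
    """
    n = len(matrix.genomes)
    if n == 0 or not matrix.counts:
        raise ValueError("empty presence matrix")
    kept = set()
    for fam in matrix.counts:
        exactly_once = sum(
            1 for g in matrix.genomes if matrix.copy_count(fam, g) == 1
        )
        if exactly_once / n > threshold:
            kept.add(fam)
    return kept


# ---------------------------------------------------------------------------
# Step 2: cross-database redundancy
# ---------------------------------------------------------------------------

def redundancy_collapse(
    matrix: PresenceMatrix,
    families: set[str],
    overlap_threshold: float = 0.90,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Collapse A-families redundant with a B-family.

    An (A, B) pair is redundant when the two families hit an identical,
    non-empty gene-id set in more than ``overlap_threshold`` of the trusted
    genomes; the A-family is then dropped in favour of the B-family. Only
    A-vs-B comparisons are made.

    Returns the retained family set and the list of (dropped A, kept B) pairs.
    """
    if matrix.gene_hits is None:
        raise ValueError("redundancy collapse requires per-genome gene-id hit sets")
    n = len(matrix.genomes)
    fams_a = sorted(f for f in families if matrix.sources[f] == "A")
    fams_b = sorted(f for f in families if matrix.sources[f] == "B")
    removed: list[tuple[str, str]] = []
    for fa in fams_a:
        hits_a = matrix.gene_hits.get(fa, {})
        for fb in fams_b:
            hits_b = matrix.gene_hits.get(fb, {})
            same = 0
            for g in matrix.genomes:
                sa = hits_a.get(g, frozenset())
                sb = hits_b.get(g, frozenset())
                if sa and sa == sb:
                    same += 1
            if same / n > overlap_threshold:
                removed.append((fa, fb))
                break
    kept = set(families) - {fa for fa, _ in removed}
    return kept, removed


# ---------------------------------------------------------------------------
# Step 3: gene-tree congruence
# ---------------------------------------------------------------------------

def congruence_test(family_id: str, tree: GeneTree) -> dict[str, bool]:
    """Congruence flag for every genome with >= 2 copies in the gene tree.

    A multi-copy genome is congruent iff every leaf under the MRCA of its
    copies belongs to a genome of the same species (single conspecific
    clade). Genomes with a single copy are vacuously congruent and omitted
    from the returned mapping.
    """
    if len(tree.tree.leaf_nodes()) < 2:
        raise ValueError(f"gene tree for {family_id} has fewer than 2 leaves")
    # clades are read off the tree as given; treat the seed node as the root
    tree.tree.is_rooted = True
    by_genome = tree.leaf_genomes()
    flags: dict[str, bool] = {}
    for genome, labels in by_genome.items():
        if len(labels) < 2:
            continue
        species = tree.taxonomy[genome]
        mrca = tree.tree.mrca(taxon_labels=labels)
        congruent = True
        for leaf in mrca.leaf_iter():
            leaf_genome = leaf.taxon.label.rsplit("|", 1)[0]
            if tree.taxonomy[leaf_genome] != species:
                congruent = False
                break
        flags[genome] = congruent
    return flags


def congruence_report(
    families,
    gene_trees: dict[str, GeneTree],
    matrix: PresenceMatrix,
) -> CongruenceReport:
    """Run the congruence test across families and tally divergent genomes.

    A genome recorded as multi-copy in the presence matrix but missing from
    the family's gene tree (or a family with no tree at all while having
    multi-copy genomes) is treated conservatively as divergent, with a
    warning.
    """
    report = CongruenceReport(n_trusted_genomes=len(matrix.genomes))
    for fam in sorted(families):
        multicopy = [g for g in matrix.genomes if matrix.copy_count(fam, g) >= 2]
        flags: dict[str, bool] = {}
        tree = gene_trees.get(fam)
        if tree is not None:
            flags = congruence_test(fam, tree)
        for g in multicopy:
            if g not in flags:
                if tree is None:
                    logger.warning(
                        "family %s: no gene tree; multi-copy genome %s "
                        "treated as divergent", fam, g
                    )
                else:
                    logger.warning(
                        "family %s: multi-copy genome %s absent from gene "
                        "tree; treated as divergent", fam, g
                    )
                flags[g] = False
        n_div = sum(1 for ok in flags.values() if not ok)
        report.per_family[fam] = (len(multicopy), n_div)
    return report


# ---------------------------------------------------------------------------
# Step 4: divergence filter
# ---------------------------------------------------------------------------

def divergence_filter(
    candidates,
    report: CongruenceReport,
    max_fraction: float = 0.01,
    *,
    initial=None,
    redundancy_removed=None,
) -> SelectedMarkers:
    """Drop families divergent in > ``max_fraction`` of all trusted genomes.

    The denominator is the full trusted-genome set, not the genomes carrying
    the family. The comparison is strict.
    """
    candidates = sorted(candidates)
    removed = [
        f for f in candidates if report.divergent_fraction(f) > max_fraction
    ]
    retained = [f for f in candidates if f not in set(removed)]
    return SelectedMarkers(
        retained=retained,
        initial=sorted(initial) if initial is not None else list(candidates),
        redundancy_removed=list(redundancy_removed or []),
        candidates=list(candidates),
        divergence_removed=removed,
    )


# ---------------------------------------------------------------------------
# End-to-end composition
# ---------------------------------------------------------------------------

def select_markers(
    matrix: PresenceMatrix,
    gene_trees: dict[str, GeneTree],
    config: SelectionConfig | None = None,
) -> SelectedMarkers:
    """prevalence -> redundancy collapse -> congruence -> divergence filter."""
    cfg = config or SelectionConfig()
    initial = prevalence_filter(matrix, cfg.prevalence_threshold)
    candidates, removed_pairs = redundancy_collapse(
        matrix, initial, cfg.redundancy_threshold
    )
    report = congruence_report(candidates, gene_trees, matrix)
    return divergence_filter(
        candidates,
        report,
        cfg.max_divergent_fraction,
        initial=initial,
        redundancy_removed=removed_pairs,
    )
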