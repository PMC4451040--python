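"""Synthetic co-culture and marker-scenario generators with planted truth.

Every input the pipeline consumes can be generated here with a known ground
truth, so each downstream stage is testable against what was planted:

* :func:`generate_coculture` emulates shotgun data from a two-organism
  predator/host co-culture: a high-coverage predator chromosome at a
  characteristic GC (default 51.4%, ~250x) emitted pre-fragmented into
  contigs, two circular plasmids at chromosome-like coverage, and a
  low-coverage, GC-distinct host fraction. Unique 60-mer marker tags stand
  in for single-copy marker genes (one planted in duplicate), and rRNA
  reference fragments are planted into a recorded subset of reads.
* :func:`generate_marker_scenario` builds a trusted-genome family scenario
  for the marker-selection stage: a presence/copy-number matrix over two
  annotation sources, per-family gene trees grown on a known species tree
  (with planted congruent duplications, planted divergent duplications
  grafted into foreign species' subtrees, and planted redundant A/B family
  pairs), a taxonomy map and per-family aligned blocks evolved by
  site-independent substitution.

Background sequence is i.i.d. per base with P(G)=P(C)=gc/2 and P(A)=P(T),
so expected GC is analytic; reads are error-free with uniform start
positions (wrap-around on circular plasmids), so every downstream contract
has an exact oracle. Identical parameters and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circularity import revcomp
from .marker_selection import GeneTree, PresenceMatrix
from .rrna_screen import RrnaReference
from .seq_io import (
    SeqRecord,
    newick_to_tree,
    write_fasta,
    write_fastq,
    write_tsv,
)

__all__ = [
    "CocultureParams",
    "MarkerScenarioParams",
    "ScenarioTruth",
    "CocultureScenario",
    "MarkerScenario",
    "generate_coculture",
    "generate_marker_scenario",
]

_BASES = np.array(list("ACGT"))

PREDATOR = "predator"
HOST = "host"


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# Co-culture scenario
# ---------------------------------------------------------------------------

@dataclass
class CocultureParams:
    """Composition of the simulated predator/host co-culture.

    Defaults are a scaled stand-in for the real dataset: predator GC 51.4%
    well above the 180x binning cutoff, host at distinct GC and low
    coverage sized so the predator fraction holds ~94% of the data, two
    circular plasmids at chromosome-like coverage, 104 planted single-copy
    marker tags with one duplicate, and planted rRNA read counts of
    333 / 16 / 3.
    """

    predator_gc: float = 0.514
    predator_len: int = 200_000
    host_gc: float = 0.61
    host_len: int = 119_000
    predator_cov: float = 250.0
    host_cov: float = 30.0
    plasmid_lens: tuple[int, ...] = (14_400, 10_000)
    read_len: int = 300
    insert: int = 700
    n_marker_tags: int = 104
    tag_len: int = 60
    n_predator_contigs: int = 26
    n_host_contigs: int = 85
    end_overlap: int = 50  # (k-1) terminal overlap on linearised plasmids
    rrna_read_counts: dict = field(
        default_factory=lambda: {
            ("Vampirovibrio_chlorellavorus", "16S"): 333,
            ("Chlorella_vulgaris_chloroplast", "chloroplast-16S"): 16,
            ("Chlorella_vulgaris_mitochondrion", "mitochondrial-rRNA"): 3,
        }
    )
    seed: int = 42

    def __post_init__(self) -> None:
        for name, gc in (("predator_gc", self.predator_gc), ("host_gc", self.host_gc)):
            if not 0 < gc < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if min(self.predator_len, self.host_len, *self.plasmid_lens) <= 0:
            raise ValueError("all lengths must be positive")
        if self.predator_cov <= self.host_cov:
            raise ValueError("predator_cov must exceed host_cov")
        if self.insert < self.read_len:
            raise ValueError("insert must be >= read_len")
        min_piece = self.insert
        if self.predator_len < self.n_predator_contigs * min_piece:
            raise ValueError("predator_len too short for the contig count/insert")
        if self.host_len < self.n_host_contigs * min_piece:
            raise ValueError("host_len too short for the contig count/insert")
        if any(p < 2 * self.end_overlap + self.insert for p in self.plasmid_lens):
            raise ValueError("plasmids must be longer than the overlap and insert")


@dataclass
class ScenarioTruth:
    """Planted ground truth; every generated object has an entry."""

    # co-culture side
    contig_bins: dict[str, str] = field(default_factory=dict)
    read_sources: dict[str, str] = field(default_factory=dict)  # unit -> contig
    circular_ids: list[str] = field(default_factory=list)
    marker_tag_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    duplicated_marker: str | None = None
    rrna_reads: dict[str, tuple[str, str]] = field(default_factory=dict)
    predator_data_fraction: float | None = None
    # marker-scenario side
    species: dict[str, str] = field(default_factory=dict)
    prevalence_pass: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)
    divergent_families: list[str] = field(default_factory=list)
    divergent_genomes: dict[str, list[str]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["marker_tag_positions"] = {
            k: [list(t) for t in v] for k, v in self.marker_tag_positions.items()
        }
        d["rrna_reads"] = {k: list(v) for k, v in self.rrna_reads.items()}
        return json.dumps(d, indent=1, sort_keys=True, default=default)


@dataclass
class CocultureScenario:
    contigs: list[SeqRecord]
    reads: list[tuple[SeqRecord, SeqRecord]]
    coverage: pd.DataFrame
    rrna_refs: list[RrnaReference]
    marker_tags: dict[str, str]
    truth: ScenarioTruth
    params: CocultureParams

    def predator_contigs(self) -> list[SeqRecord]:
        return [
            c for c in self.contigs if self.truth.contig_bins[c.id] == PREDATOR
        ]

    def all_reads_flat(self) -> list[SeqRecord]:
        out = []
        for r1, r2 in self.reads:
            out.append(r1)
            out.append(r2)
        return out

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qual = "I"
        paths = {
            "contigs": outdir / "contigs.fasta",
            "reads_r1": outdir / "reads_R1.fastq",
            "reads_r2": outdir / "reads_R2.fastq",
            "coverage": outdir / "coverage.tsv",
            "rrna_refs": outdir / "rrna_refs.fasta",
            "marker_tags": outdir / "marker_tags.fasta",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.contigs, paths["contigs"])
        write_fastq(
            [(r1, qual * len(r1.sequence)) for r1, _ in self.reads],
            paths["reads_r1"],
        )
        write_fastq(
            [(r2, qual * len(r2.sequence)) for _, r2 in self.reads],
            paths["reads_r2"],
        )
        write_tsv(self.coverage, paths["coverage"])
        write_fasta(
            [
                SeqRecord(f"{r.taxon}|{r.gene}", r.sequence)
                for r in self.rrna_refs
            ],
            paths["rrna_refs"],
        )
        write_fasta(
            [SeqRecord(m, t) for m, t in sorted(self.marker_tags.items())],
            paths["marker_tags"],
        )
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _fragment_lengths(
    rng: np.random.Generator, total: int, n_pieces: int, min_piece: int
) -> list[int]:
    """Random composition of ``total`` into pieces each >= min_piece."""
    slack = total - n_pieces * min_piece
    extra = rng.multinomial(slack, np.full(n_pieces, 1 / n_pieces))
    return [min_piece + int(e) for e in extra]


def _sample_linear_reads(
    rng, seq: str, contig_id: str, cov: float, read_len: int, insert: int
):
    """Error-free read pairs with uniform fragment starts on a linear contig."""
    L = len(seq)
    n_pairs = int(round(cov * L / (2 * read_len)))
    pairs = []
    if n_pairs == 0:
        return pairs, 0.0
    starts = rng.integers(0, L - insert + 1, size=n_pairs)
    for i, s in enumerate(sorted(starts.tolist())):
        frag = seq[s : s + insert]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        unit = f"{contig_id}_r{i:06d}"
        pairs.append(
            (SeqRecord(f"{unit}/1", r1), SeqRecord(f"{unit}/2", r2))
        )
    coverage = n_pairs * 2 * read_len / L
    return pairs, coverage


def _sample_circular_reads(
    rng, circ: str, contig_id: str, contig_len: int, cov: float,
    read_len: int, insert: int,
):
    """Read pairs from a circular molecule (wrap-around fragment starts)."""
    L = len(circ)
    n_pairs = int(round(cov * L / (2 * read_len)))
    pairs = []
    if n_pairs == 0:
        return pairs, 0.0
    doubled = circ + circ
    starts = rng.integers(0, L, size=n_pairs)
    for i, s in enumerate(sorted(starts.tolist())):
        frag = doubled[s : s + insert]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        unit = f"{contig_id}_r{i:06d}"
        pairs.append(
            (SeqRecord(f"{unit}/1", r1), SeqRecord(f"{unit}/2", r2))
        )
    coverage = n_pairs * 2 * read_len / contig_len
    return pairs, coverage


def generate_coculture(params: CocultureParams | None = None) -> CocultureScenario:
    """Generate contigs, paired reads, a coverage table and planted truth."""
    p = params or CocultureParams()
    rng = np.random.default_rng(p.seed)
    truth = ScenarioTruth()
    contigs: list[SeqRecord] = []
    reads: list[tuple[SeqRecord, SeqRecord]] = []
    cov_rows: list[dict] = []

    # --- predator chromosome, pre-fragmented ------------------------------
    pieces = _fragment_lengths(
        rng, p.predator_len, p.n_predator_contigs, p.insert
    )
    pred_seqs = {
        f"pred_c{i + 1:02d}": _random_dna(rng, L, p.predator_gc)
        for i, L in enumerate(pieces)
    }

    # --- marker tags: unique 60-mers, one planted twice -------------------
    tags: dict[str, str] = {}
    while len(tags) < p.n_marker_tags:
        t = _random_dna(rng, p.tag_len, p.predator_gc)
        if t not in tags.values():
            tags[f"marker_{len(tags) + 1:03d}"] = t
    duplicated = "marker_001"
    placements: list[tuple[str, str]] = [(m, t) for m, t in tags.items()]
    placements.append((duplicated, tags[duplicated]))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in pred_seqs}
    ids = list(pred_seqs)
    weights = np.array([len(pred_seqs[c]) for c in ids], dtype=float)
    weights /= weights.sum()
    for marker, tag in placements:
        while True:
            c = ids[rng.choice(len(ids), p=weights)]
            seq = pred_seqs[c]
            if len(seq) < p.tag_len + 2 * p.end_overlap:
                continue
            pos = int(
                rng.integers(p.end_overlap, len(seq) - p.tag_len - p.end_overlap)
            )
            if any(
                pos < e and pos + p.tag_len > s for s, e in occupied[c]
            ):
                continue
            pred_seqs[c] = seq[:pos] + tag + seq[pos + p.tag_len :]
            occupied[c].append((pos, pos + p.tag_len))
            truth.marker_tag_positions.setdefault(marker, []).append((c, pos))
            break
    truth.duplicated_marker = duplicated

    for cid in ids:
        contigs.append(SeqRecord(cid, pred_seqs[cid]))
        truth.contig_bins[cid] = PREDATOR

    # --- circular plasmids, linearised with a terminal overlap ------------
    for i, L in enumerate(p.plasmid_lens):
        cid = f"plasmid_{i + 1:02d}"
        circ = _random_dna(rng, L, p.predator_gc)
        linearised = circ + circ[: p.end_overlap]
        contigs.append(SeqRecord(cid, linearised))
        truth.contig_bins[cid] = PREDATOR
        truth.circular_ids.append(cid)

    # --- host fraction -----------------------------------------------------
    pieces = _fragment_lengths(rng, p.host_len, p.n_host_contigs, p.insert)
    for i, L in enumerate(pieces):
        cid = f"host_c{i + 1:02d}"
        contigs.append(SeqRecord(cid, _random_dna(rng, L, p.host_gc)))
        truth.contig_bins[cid] = HOST

    # --- reads and the coverage table --------------------------------------
    seq_by_id = {c.id: c.sequence for c in contigs}
    for c in contigs:
        bin_ = truth.contig_bins[c.id]
        cov = p.predator_cov if bin_ == PREDATOR else p.host_cov
        if c.id in truth.circular_ids:
            circ = c.sequence[: -p.end_overlap]
            pairs, actual = _sample_circular_reads(
                rng, circ, c.id, len(c.sequence), cov, p.read_len, p.insert
            )
        else:
            pairs, actual = _sample_linear_reads(
                rng, c.sequence, c.id, cov, p.read_len, p.insert
            )
        reads.extend(pairs)
        for r1, _ in pairs:
            truth.read_sources[r1.id[:-2]] = c.id
        cov_rows.append({"contig_id": c.id, "coverage": actual})
    coverage = pd.DataFrame(cov_rows, columns=["contig_id", "coverage"])

    # --- rRNA references and planted rRNA reads ----------------------------
    ref_lens = {
        "16S": 1500,
        "chloroplast-16S": 1400,
        "mitochondrial-rRNA": 1200,
        "18S": 1800,
    }
    ref_specs = sorted(set(p.rrna_read_counts) | {("Chlorella_vulgaris", "18S")})
    refs = [
        RrnaReference(taxon, gene, _random_dna(rng, ref_lens.get(gene, 1500), 0.52))
        for taxon, gene in ref_specs
    ]
    ref_by_key = {(r.taxon, r.gene): r for r in refs}

    pred_units = [
        i for i, (r1, _) in enumerate(reads)
        if truth.contig_bins[truth.read_sources[r1.id[:-2]]] == PREDATOR
    ]
    host_units = [
        i for i, (r1, _) in enumerate(reads)
        if truth.contig_bins[truth.read_sources[r1.id[:-2]]] == HOST
    ]
    taken: set[int] = set()
    for (taxon, gene), count in sorted(p.rrna_read_counts.items()):
        pool = pred_units if gene == "16S" else host_units
        pool = [i for i in pool if i not in taken]
        if count > len(pool):
            raise ValueError(
                f"cannot plant {count} rRNA reads for {taxon}|{gene}: "
                f"only {len(pool)} reads available"
            )
        chosen = rng.choice(len(pool), size=count, replace=False)
        ref = ref_by_key[(taxon, gene)]
        for idx in sorted(int(i) for i in chosen):
            ridx = pool[idx]
            taken.add(ridx)
            r1, r2 = reads[ridx]
            start = int(rng.integers(0, len(ref.sequence) - p.read_len + 1))
            window = ref.sequence[start : start + p.read_len]
            if rng.random() < 0.5:
                window = revcomp(window)
            reads[ridx] = (SeqRecord(r1.id, window), r2)
            truth.rrna_reads[r1.id] = (taxon, gene)

    # --- planted data fraction and generation-time self-checks --------------
    data = {
        row["contig_id"]: row["coverage"] * len(seq_by_id[row["contig_id"]])
        for _, row in coverage.iterrows()
    }
    pred_data = sum(
        v for k, v in data.items() if truth.contig_bins[k] == PREDATOR
    )
    total = sum(data.values())
    truth.predator_data_fraction = pred_data / total if total else 0.0

    final_seqs = {c.id: c.sequence for c in contigs}
    for marker, tag in tags.items():
        expected = 2 if marker == duplicated else 1
        rc = revcomp(tag)
        n = sum(
            s.count(tag) + (s.count(rc) if rc != tag else 0)
            for s in final_seqs.values()
        )
        if n != expected:
            raise AssertionError(
                f"tag {marker} occurs {n} times, expected {expected} "
                "(chance collision; re-seed)"
            )

    return CocultureScenario(
        contigs=contigs,
        reads=reads,
        coverage=coverage,
        rrna_refs=refs,
        marker_tags=tags,
        truth=truth,
        params=p,
    )


# ---------------------------------------------------------------------------
# Marker-selection scenario
# ---------------------------------------------------------------------------

@dataclass
class MarkerScenarioParams:
    """Planted composition of the trusted-genome marker scenario.

    By construction: all B-source families pass the prevalence filter;
    ``n_candidates + n_redundant_pairs`` families pass in total; the
    redundancy collapse removes exactly the A-members of the planted
    redundant pairs, leaving ``n_candidates`` candidates; ``n_divergent``
    of those carry a duplicated genome whose second copy is grafted into a
    foreign species' subtree.
    """

    n_trusted_genomes: int = 50
    genomes_per_species: int = 2
    n_families_A: int = 120
    n_families_B: int = 80
    n_redundant_pairs: int = 10
    n_candidates: int = 178
    n_divergent: int = 69
    n_congruent_multicopy: int = 20
    block_len: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if min(
            self.n_trusted_genomes, self.n_families_A, self.n_families_B,
            self.n_candidates, self.block_len,
        ) <= 0:
            raise ValueError("counts must be positive")
        if self.n_divergent > self.n_candidates:
            raise ValueError("n_divergent must be <= n_candidates")
        if self.n_trusted_genomes % self.genomes_per_species:
            raise ValueError("n_trusted_genomes must divide by genomes_per_species")
        if self.n_trusted_genomes // self.genomes_per_species < 2:
            raise ValueError("need at least two species")
        a_pass = self.n_candidates + self.n_redundant_pairs - self.n_families_B
        if not 0 <= a_pass <= self.n_families_A:
            raise ValueError(
                "inconsistent family counts: candidates + redundant pairs must "
                "lie between n_families_B and n_families_A + n_families_B"
            )
        if self.n_redundant_pairs > min(a_pass, self.n_families_B):
            raise ValueError("too many redundant pairs for the family counts")
        eligible = self.n_candidates - self.n_redundant_pairs
        if self.n_divergent + self.n_congruent_multicopy > eligible:
            raise ValueError(
                "n_divergent + n_congruent_multicopy exceeds the candidate "
                "families available for planting duplications"
            )
        # exactly-once prevalence must stay > 90% with one duplicated genome
        if (self.n_trusted_genomes - 1) / self.n_trusted_genomes <= 0.90:
            raise ValueError("n_trusted_genomes too small for planted prevalence")


# nested tree node: ("leaf", genome) | ("node", [(child, edge_length), ...])

def _random_species_tree(rng, species: list[str]):
    nodes = [("leaf", s) for s in species]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.03, 0.12, size=2)
        nodes.append(("node", [(a, float(la)), (b, float(lb))]))
    return nodes[0]


def _expand_to_genomes(tree, members: dict[str, list[str]], cherry_len=0.01):
    kind, payload = tree
    if kind == "leaf":
        genomes = members[payload]
        if len(genomes) == 1:
            return ("leaf", genomes[0])
        node = ("leaf", genomes[0])
        for g in genomes[1:]:
            node = ("node", [(node, cherry_len), (("leaf", g), cherry_len)])
        return node
    return ("node", [(_expand_to_genomes(c, members), l) for c, l in payload])


def _prune(tree, keep: set[str]):
    kind, payload = tree
    if kind == "leaf":
        return (tree, 0.0) if payload in keep else None
    kept = []
    for child, length in payload:
        sub = _prune(child, keep)
        if sub is not None:
            node, extra = sub
            kept.append((node, length + extra))
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return (("node", kept), 0.0)


def _leaves(tree) -> list[str]:
    kind, payload = tree
    if kind == "leaf":
        return [payload]
    out = []
    for child, _ in payload:
        out.extend(_leaves(child))
    return out


def _to_newick(tree, label=None) -> str:
    kind, payload = tree
    if kind == "leaf":
        return payload if label is None else label(payload)
    parts = [f"{_to_newick(c, label)}:{l:.6f}" for c, l in payload]
    return "(" + ",".join(parts) + ")"


def _graft(tree, target_leaf: str, new_leaf: str, edge=0.005):
    """Replace leaf ``target_leaf`` with a cherry (target, new_leaf)."""
    kind, payload = tree
    if kind == "leaf":
        if payload == target_leaf:
            return (
                "node",
                [(("leaf", target_leaf), edge), (("leaf", new_leaf), edge)],
            )
        return tree
    return ("node", [(_graft(c, target_leaf, new_leaf, edge), l) for c, l in payload])


@dataclass
class MarkerScenario:
    presence: PresenceMatrix
    gene_trees: dict[str, str]  # family -> newick
    taxonomy: pd.DataFrame
    blocks: dict[str, list[SeqRecord]]
    truth: ScenarioTruth
    params: MarkerScenarioParams

    def gene_tree_objects(self) -> dict[str, GeneTree]:
        tax = dict(zip(self.taxonomy["genome_id"], self.taxonomy["species_id"]))
        return {
            fam: GeneTree(newick_to_tree(nwk), tax)
            for fam, nwk in self.gene_trees.items()
        }

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        (outdir / "families").mkdir(parents=True, exist_ok=True)
        (outdir / "gene_trees").mkdir(parents=True, exist_ok=True)
        rows = []
        for fam in self.presence.families:
            for g in self.presence.genomes:
                rows.append(
                    {
                        "family_id": fam,
                        "source": self.presence.sources[fam],
                        "genome_id": g,
                        "copy_count": self.presence.copy_count(fam, g),
                        "gene_ids": ";".join(
                            sorted(self.presence.gene_hits[fam].get(g, ()))
                        ),
                    }
                )
        paths = {
            "presence": outdir / "presence.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth": outdir / "truth.json",
        }
        write_tsv(pd.DataFrame(rows), paths["presence"])
        write_tsv(self.taxonomy, paths["taxonomy"])
        paths["truth"].write_text(self.truth.to_json())
        for fam, nwk in self.gene_trees.items():
            (outdir / "gene_trees" / f"{fam}.nwk").write_text(nwk + "\n")
        for fam, recs in self.blocks.items():
            write_fasta(recs, outdir / "families" / f"{fam}.aln.fasta")
        return paths


def _evolve_block(rng, tree, length: int) -> dict[str, np.ndarray]:
    """Site-independent substitution of a root sequence down the tree."""
    out: dict[str, np.ndarray] = {}

    def walk(node, seq):
        kind, payload = node
        if kind == "leaf":
            out[payload] = seq
            return
        for child, t in payload:
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            mask = rng.random(length) < p_sub
            child_seq = seq.copy()
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                child_seq[mask] = (child_seq[mask] + shift) % 4
            walk(child, child_seq)

    walk(tree, rng.integers(0, 4, size=length))
    return out


def generate_marker_scenario(
    params: MarkerScenarioParams | None = None,
) -> MarkerScenario:
    """Generate a presence matrix, gene trees, taxonomy and aligned blocks
    with an exactly-known selection outcome."""
    p = params or MarkerScenarioParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_trusted_genomes

    genomes = [f"g{i:03d}" for i in range(n)]
    n_species = n // p.genomes_per_species
    species = [f"s{i:03d}" for i in range(n_species)]
    members = {
        s: genomes[i * p.genomes_per_species : (i + 1) * p.genomes_per_species]
        for i, s in enumerate(species)
    }
    taxonomy_map = {g: s for s, gs in members.items() for g in gs}
    taxonomy = pd.DataFrame(
        {"genome_id": genomes, "species_id": [taxonomy_map[g] for g in genomes]}
    )

    species_tree = _random_species_tree(rng, species)
    genome_tree = _expand_to_genomes(species_tree, members)

    fams_a = [f"famA_{i:03d}" for i in range(p.n_families_A)]
    fams_b = [f"famB_{i:03d}" for i in range(p.n_families_B)]
    a_pass_n = p.n_candidates + p.n_redundant_pairs - p.n_families_B
    a_pass = fams_a[:a_pass_n]
    a_fail = fams_a[a_pass_n:]
    prevalence_pass = a_pass + fams_b

    redundant_pairs = list(zip(a_pass[: p.n_redundant_pairs], fams_b[: p.n_redundant_pairs]))
    redundant_a = {a for a, _ in redundant_pairs}
    candidates = sorted(set(prevalence_pass) - redundant_a)

    # redundant B partners stay single-copy everywhere, so duplications are
    # planted only among the other candidates
    partner_bs = {b for _, b in redundant_pairs}
    cand_arr = np.array([f for f in candidates if f not in partner_bs])
    div_idx = rng.choice(len(cand_arr), size=p.n_divergent, replace=False)
    divergent = sorted(cand_arr[np.sort(div_idx)].tolist())
    rest = [f for f in cand_arr.tolist() if f not in set(divergent)]
    rest_idx = rng.choice(len(rest), size=p.n_congruent_multicopy, replace=False)
    congruent_multi = sorted(np.array(rest)[np.sort(rest_idx)].tolist())

    counts: dict[str, dict[str, int]] = {}
    gene_hits: dict[str, dict[str, frozenset]] = {}
    sources = {f: "A" for f in fams_a}
    sources.update({f: "B" for f in fams_b})
    gene_trees: dict[str, str] = {}
    blocks: dict[str, list[SeqRecord]] = {}
    truth = ScenarioTruth(
        species=taxonomy_map,
        prevalence_pass=sorted(prevalence_pass),
        candidates=list(candidates),
        redundant_pairs=redundant_pairs,
        divergent_families=list(divergent),
        retained=sorted(set(candidates) - set(divergent)),
    )

    gene_counter = 0

    def fresh_gene(g: str) -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{g}:gene{gene_counter:05d}"

    redundant_b_for_a = dict(redundant_pairs)

    # each redundant pair shares identical gene ids in all but 2 genomes,
    # putting the overlap fraction above the 0.9 collapse threshold
    shared_sets: dict[str, dict[str, frozenset]] = {}

    for fam in sorted(fams_a + fams_b):
        fam_counts: dict[str, int] = {}
        fam_hits: dict[str, frozenset] = {}
        multicopy_genome: str | None = None
        victim: str | None = None

        if fam in set(a_fail):
            # boundary case: exactly-once in exactly 90% of genomes (excluded)
            n_present = int(round(0.9 * n))
            present = sorted(
                np.array(genomes)[
                    np.sort(rng.choice(n, size=n_present, replace=False))
                ].tolist()
            )
            for g in present:
                fam_counts[g] = 1
                fam_hits[g] = frozenset([fresh_gene(g)])
        else:
            present = list(genomes)
            if fam in set(divergent):
                midx = int(rng.integers(0, n))
                multicopy_genome = genomes[midx]
                others = [
                    g for g in genomes
                    if taxonomy_map[g] != taxonomy_map[multicopy_genome]
                ]
                victim = others[int(rng.integers(0, len(others)))]
            elif fam in set(congruent_multi):
                multicopy_genome = genomes[int(rng.integers(0, n))]
            is_redundant_a = fam in redundant_a
            partner = redundant_b_for_a.get(fam)
            for g in present:
                c = 2 if g == multicopy_genome else 1
                fam_counts[g] = c
                ids = frozenset(fresh_gene(g) for _ in range(c))
                fam_hits[g] = ids
            if partner is not None:
                # the B partner reuses the A family's gene ids in enough
                # genomes to clear the strict >0.9 overlap threshold
                shared = dict(fam_hits)
                fam_hits_b = {}
                n_shared = int(np.floor(0.9 * n + 1e-9)) + 1
                n_diff = n - n_shared
                differing = sorted(
                    np.array(genomes)[
                        np.sort(rng.choice(n, size=n_diff, replace=False))
                    ].tolist()
                ) if n_diff else []
                for g in present:
                    if g in differing:
                        fam_hits_b[g] = frozenset([fresh_gene(g)])
                    else:
                        fam_hits_b[g] = shared[g]
                shared_sets[partner] = fam_hits_b

        counts[fam] = fam_counts
        gene_hits[fam] = fam_hits

        # gene tree: prune the genome tree to present genomes, add copies
        pruned, _ = _prune(genome_tree, set(present))
        if multicopy_genome is not None:
            if victim is not None:
                pruned = _graft(pruned, victim, f"__copy__{multicopy_genome}")
                truth.divergent_genomes.setdefault(fam, []).append(
                    multicopy_genome
                )
            else:
                pruned = _graft(
                    pruned, multicopy_genome, f"__copy__{multicopy_genome}"
                )

        def leaf_label(leaf: str) -> str:
            if leaf.startswith("__copy__"):
                return f"{leaf[len('__copy__'):]}|2"
            return f"{leaf}|1"

        gene_trees[fam] = _to_newick(pruned, leaf_label) + ";"

        # aligned block evolved on the pruned (single-copy) topology
        block_tree, _ = _prune(genome_tree, set(present))
        seqs = _evolve_block(rng, block_tree, p.block_len)
        blocks[fam] = [
            SeqRecord(g, "".join(_BASES[seqs[g]])) for g in sorted(seqs)
        ]

    # overwrite the B partners' hit sets with the planted shared ids
    for b_fam, hits in shared_sets.items():
        gene_hits[b_fam] = hits
        counts[b_fam] = {g: len(ids) for g, ids in hits.items()}

    presence = PresenceMatrix(
        counts=counts, sources=sources, genomes=genomes, gene_hits=gene_hits
    )
    return MarkerScenario(
        presence=presence,
        gene_trees=gene_trees,
        taxonomy=taxonomy,
        blocks=blocks,
        truth=truth,
        params=p,
    )
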