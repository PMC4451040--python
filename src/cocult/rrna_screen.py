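"""Read screening for rRNA content by shared-kmer voting.

Reads are assigned to reference rRNA taxa (e.g. a bacterial 16S, an algal
18S, chloroplast 16S, mitochondrial rRNA) by counting the canonical kmers
each read shares with each reference. A read is assigned to the taxon with
the most shared kmers provided that count reaches ``min_hits``; ties are
broken towards the lexicographically smallest (taxon, gene) pair and
recorded. Mates of a pair are screened independently, but a pair counts
once if either mate hits, so the output tallies read pairs/fragments the
way read-level screening reports do.

This is a deliberately simple exact-kmer classifier, documented as a
stand-in for HMM/placement-based screeners: on data where references share
no kmers with the genomic background it is exact.

Kmers are canonicalised as the lexicographic minimum of the kmer and its
reverse complement, so the screen is strand-invariant. The engine packs
bases 2 bits each into uint64 codes and screens with vectorised membership
tests, so hundreds of thousands of reads scan in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import SeqRecord

__all__ = [
    "RrnaReference",
    "ScreenResult",
    "KmerIndex",
    "build_kmer_index",
    "screen_reads",
    "canonical_kmers",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class RrnaReference:
    """A reference rRNA sequence tagged with its taxon and gene."""

    taxon: str
    gene: str  # e.g. 16S, 18S, chloroplast-16S, mitochondrial-rRNA
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError(
                f"reference {self.taxon}|{self.gene}: sequences must be >= 200 bp"
            )


@dataclass
class ScreenResult:
    """Per-(taxon, gene) read counts plus the unassigned remainder."""

    counts: dict[tuple[str, str], int]
    unassigned: int
    n_scanned: int
    ties: list[str] = field(default_factory=list)  # read ids with tied votes

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.unassigned != self.n_scanned:
            raise ValueError("counts + unassigned must equal reads scanned")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": t, "gene": g, "count": c}
            for (t, g), c in sorted(self.counts.items())
        ]
        rows.append({"taxon": "(unassigned)", "gene": "-", "count": self.unassigned})
        return pd.DataFrame(rows, columns=["taxon", "gene", "count"])


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical uint64 codes of every gap/N-free length-k window of seq."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.uint64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = ~(win == 255).any(axis=1)
    fwd = (win.astype(np.uint64) * powers).sum(axis=1)
    comp = np.where(arr == 255, np.uint8(255), 3 - arr)
    win_rc = np.lib.stride_tricks.sliding_window_view(comp[::-1], k)
    rc = (win_rc.astype(np.uint64) * powers).sum(axis=1)[::-1]
    return np.minimum(fwd, rc)[valid]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical kmer strings of ``seq`` (reference/brute-force interface)."""
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) - set("ACGT"):
            continue
        out.add(min(w, w.translate(comp)[::-1]))
    return out


@dataclass
class KmerIndex:
    """Canonical-kmer index over a reference set.

    ``by_taxon`` maps (taxon, gene) -> sorted array of canonical kmer codes;
    ``union`` is the sorted union used as a fast pre-filter.
    """

    k: int
    by_taxon: dict[tuple[str, str], np.ndarray]
    union: np.ndarray

    def n_kmers(self, taxon: str, gene: str) -> int:
        return int(self.by_taxon[(taxon, gene)].size)

    def __len__(self) -> int:
        return int(self.union.size)

    def contains(self, kmer: str) -> bool:
        codes = _window_codes(kmer, self.k)
        if codes.size != 1:
            raise ValueError(f"expected a single {self.k}-mer")
        i = np.searchsorted(self.union, codes[0])
        return bool(i < self.union.size and self.union[i] == codes[0])

    def taxa_of(self, kmer: str) -> set[tuple[str, str]]:
        codes = _window_codes(kmer, self.k)
        if codes.size != 1:
            raise ValueError(f"expected a single {self.k}-mer")
        hits = set()
        for key, arr in self.by_taxon.items():
            i = np.searchsorted(arr, codes[0])
            if i < arr.size and arr[i] == codes[0]:
                hits.add(key)
        return hits


def build_kmer_index(refs: list[RrnaReference], k: int = 21) -> KmerIndex:
    """Index every canonical length-k window of every reference.

    ``k`` must be odd (an even k makes a kmer its own reverse complement
    possible, leaving the canonical form ill-defined) and within [11, 31].
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 11 <= k <= 31:
        raise ValueError(f"k must be in [11, 31], got {k}")
    seen: set[tuple[str, str]] = set()
    by_taxon: dict[tuple[str, str], np.ndarray] = {}
    for ref in refs:
        key = (ref.taxon, ref.gene)
        if key in seen:
            raise ValueError(f"duplicate reference for taxon/gene {key}")
        seen.add(key)
        by_taxon[key] = np.unique(_window_codes(ref.sequence, k))
    union = (
        np.unique(np.concatenate(list(by_taxon.values())))
        if by_taxon
        else np.empty(0, dtype=np.uint64)
    )
    return KmerIndex(k=k, by_taxon=by_taxon, union=union)


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def screen_reads(
    reads,
    index: KmerIndex,
    min_hits: int = 5,
) -> ScreenResult:
    """Assign reads to reference taxa by canonical-kmer voting.

    ``reads`` is an iterable of :class:`~cocult.seq_io.SeqRecord` (or
    (record, quality) tuples). Mates named ``<id>/1`` and ``<id>/2`` are
    screened independently but counted as a single unit: the unit is
    assigned if either mate reaches ``min_hits`` shared kmers, to the taxon
    with the highest total vote across mates. Vote ties go to the
    lexicographically smallest (taxon, gene) and the unit id is recorded in
    ``ties``.
    """
    votes: dict[str, dict[tuple[str, str], int]] = {}
    units: dict[str, None] = {}
    for item in reads:
        rec = item[0] if isinstance(item, tuple) else item
        unit = _pair_key(rec.id)
        units.setdefault(unit, None)
        codes = _window_codes(rec.sequence, index.k)
        if codes.size == 0:
            continue
        # cheap union pre-filter: most reads share nothing with the refs
        pos = np.searchsorted(index.union, codes)
        pos[pos == index.union.size] = 0
        if index.union.size == 0 or not (index.union[pos] == codes).any():
            continue
        tally = votes.setdefault(unit, {})
        for key, arr in index.by_taxon.items():
            p = np.searchsorted(arr, codes)
            p[p == arr.size] = 0
            n = int((arr[p] == codes).sum()) if arr.size else 0
            if n:
                tally[key] = tally.get(key, 0) + n

    counts: dict[tuple[str, str], int] = {key: 0 for key in index.by_taxon}
    ties: list[str] = []
    assigned = 0
    for unit, tally in votes.items():
        best = max(tally.values())
        if best < min_hits:
            continue
        winners = sorted(k for k, v in tally.items() if v == best)
        if len(winners) > 1:
            ties.append(unit)
        counts[winners[0]] = counts.get(winners[0], 0) + 1
        assigned += 1
    return ScreenResult(
        counts=counts,
        unassigned=len(units) - assigned,
        n_scanned=len(units),
        ties=sorted(ties),
    )
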