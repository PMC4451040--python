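"""Coverage x GC binning of co-culture assembly contigs.

A two-organism co-culture (high-coverage predator bacterium, low-coverage
host alga) separates cleanly on a read-depth vs GC-content ordination. A
contig is assigned to the predator bin iff its coverage strictly exceeds
the cutoff (default 180x) and its GC fraction lies within the inclusive
window (default 0.42-0.54); everything else goes to the host bin. The
thresholds are explicit parameters chosen by inspecting the ordination —
no automatic cluster detection is attempted.

"Data" in the per-bin fractions means sum(length x coverage) per contig, a
proxy for mapped bases; a bp-based convention is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq_io import SeqRecord

__all__ = [
    "ContigMetrics",
    "BinningParams",
    "BinAssignment",
    "contig_metrics",
    "assign_bins",
    "bin_fractions",
    "gc_content",
]

PREDATOR = "predator"
HOST = "host"


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N bases are ignored in the denominator."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return gc / acgt


@dataclass
class ContigMetrics:
    contig_id: str
    length: int
    gc: float
    coverage: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: length must be positive")
        if not 0 <= self.gc <= 1:
            raise ValueError(f"{self.contig_id}: gc outside [0, 1]")
        if self.coverage < 0:
            raise ValueError(f"{self.contig_id}: negative coverage")

    @property
    def data(self) -> float:
        return self.length * self.coverage


@dataclass
class BinningParams:
    coverage_cutoff: float = 180.0  # strict >
    gc_min: float = 0.42            # inclusive
    gc_max: float = 0.54            # inclusive

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if self.coverage_cutoff <= 0:
            raise ValueError("coverage_cutoff must be positive")


@dataclass
class BinAssignment:
    bins: dict[str, str]  # contig_id -> PREDATOR | HOST
    params: BinningParams
    metrics: list[ContigMetrics] = field(repr=False, default_factory=list)

    def per_bin(self) -> pd.DataFrame:
        rows = []
        for b in (PREDATOR, HOST):
            ms = [m for m in self.metrics if self.bins[m.contig_id] == b]
            rows.append(
                {
                    "bin": b,
                    "n_contigs": len(ms),
                    "bp": sum(m.length for m in ms),
                    "data": sum(m.data for m in ms),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [m.contig_id for m in self.metrics],
                "length": [m.length for m in self.metrics],
                "gc": [m.gc for m in self.metrics],
                "coverage": [m.coverage for m in self.metrics],
                "bin": [self.bins[m.contig_id] for m in self.metrics],
            }
        )


def contig_metrics(
    contigs: list[SeqRecord], coverage: pd.DataFrame
) -> list[ContigMetrics]:
    """Per-contig length, GC and coverage. Every contig needs a coverage row."""
    cov = dict(zip(coverage["contig_id"], coverage["coverage"]))
    out = []
    for rec in contigs:
        if rec.id not in cov:
            raise KeyError(f"contig {rec.id!r} has no coverage table row")
        out.append(
            ContigMetrics(
                contig_id=rec.id,
                length=len(rec.sequence),
                gc=gc_content(rec.sequence),
                coverage=float(cov[rec.id]),
            )
        )
    return out


def assign_bins(
    metrics: list[ContigMetrics], params: BinningParams | None = None
) -> BinAssignment:
    """Predator iff coverage > cutoff (strict) and gc_min <= gc <= gc_max."""
    if not metrics:
        raise ValueError("no contigs to bin")
    p = params or BinningParams()
    bins = {
        m.contig_id: (
            PREDATOR
            if m.coverage > p.coverage_cutoff and p.gc_min <= m.gc <= p.gc_max
            else HOST
        )
        for m in metrics
    }
    return BinAssignment(bins=bins, params=p, metrics=list(metrics))


def bin_fractions(
    assignment: BinAssignment, convention: str = "data"
) -> dict[str, float]:
    """Per-bin fraction of the assembly, by sum(length x coverage) ("data")
    or by bp ("bp"). Fractions sum to 1."""
    if convention not in ("data", "bp"):
        raise ValueError("convention must be 'data' or 'bp'")
    weight = (
        (lambda m: m.data) if convention == "data" else (lambda m: float(m.length))
    )
    totals = {PREDATOR: 0.0, HOST: 0.0}
    for m in assignment.metrics:
        totals[assignment.bins[m.contig_id]] += weight(m)
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("zero total data; cannot form fractions")
    return {b: v / grand for b, v in totals.items()}
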