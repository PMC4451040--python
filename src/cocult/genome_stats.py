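"""Assembly summary statistics (contig counts, N50, GC, coding density)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .binning import gc_content
from .seq_io import SeqRecord

__all__ = ["AssemblyReport", "n50", "assembly_report"]


@dataclass
class AssemblyReport:
    n_contigs: int
    total_bp: int
    n50_bp: int
    gc_percent: float
    coding_density_percent: float | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {
            "Number of contigs": self.n_contigs,
            "Total length (bp)": self.total_bp,
            "N50": self.n50_bp,
            "GC (%)": round(self.gc_percent, 1),
        }
        if self.coding_density_percent is not None:
            row["Coding density (%)"] = round(self.coding_density_percent, 1)
        return pd.DataFrame([row])


def n50(lengths) -> int:
    """Largest length L such that contigs of length >= L hold >= half the
    total assembly (sort descending, accumulate, first length reaching
    total/2 — the >= boundary is inclusive, so [50, 50] -> 50)."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def _union_bp(intervals) -> int:
    """Total bp covered by a union of 1-based inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def assembly_report(
    contigs: list[SeqRecord], genes: pd.DataFrame | None = None
) -> AssemblyReport:
    """Table-1-style assembly summary.

    ``genes``, if given, is a table with columns (contig, start, end) in
    1-based inclusive coordinates; coding density is the percentage of
    assembly bp covered by the union of gene intervals (strand-agnostic,
    overlaps not double-counted).
    """
    if not contigs:
        raise ValueError("no contigs")
    lengths = {rec.id: len(rec.sequence) for rec in contigs}
    total = sum(lengths.values())
    all_seq = "".join(rec.sequence for rec in contigs)
    report = AssemblyReport(
        n_contigs=len(contigs),
        total_bp=total,
        n50_bp=n50(lengths.values()),
        gc_percent=100.0 * gc_content(all_seq),
    )
    if genes is not None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for row in genes.itertuples(index=False):
            c, s, e = row.contig, int(row.start), int(row.end)
            if c not in lengths:
                raise ValueError(f"gene on unknown contig {c!r}")
            if not 1 <= s <= e <= lengths[c]:
                raise ValueError(
                    f"gene interval {s}-{e} outside contig {c} (1..{lengths[c]})"
                )
            by_contig.setdefault(c, []).append((s, e))
        covered = sum(_union_bp(iv) for iv in by_contig.values())
        report.coding_density_percent = 100.0 * covered / total
    return report
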