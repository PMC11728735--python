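"""Candidate-region interval arithmetic: intersection across replicate scans
and size accounting.

A :class:`CandidateRegion` is a contiguous genomic interval bounded by SNP
positions (1-based, both endpoints are scan positions inside the region).
Replicate-year scans are combined by plain interval intersection; a QTL call
is only reported when both years place a region over it.

Size convention: the reported span is ``end - start`` base pairs, converted
to Mb and rounded half-away-from-zero to 4 decimals.  Gene overlap elsewhere
treats both endpoints as inclusive; the two conventions are independent and
both documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CandidateRegion",
    "intersect",
    "region_size",
    "total_size",
    "read_region_table",
    "write_region_table",
    "write_bed",
]


def _round_half_up(value_bp: int) -> float:
    """Convert bp to Mb with 4-decimal half-away-from-zero rounding."""
    mb = Decimal(value_bp) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CandidateRegion:
    """A contiguous above-threshold genomic interval (a QTL call).

    Coordinates are 1-based SNP-position bounds.  ``source_labels`` records
    which scan run(s) (e.g. years) support the region.
    """

    chromosome: str
    start: int
    end: int
    source_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        object.__setattr__(self, "source_labels", frozenset(self.source_labels))

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_mb(self) -> float:
        return _round_half_up(self.size_bp)

    def overlaps(self, other: "CandidateRegion") -> bool:
        """Inclusive-endpoint overlap on the same chromosome."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


def region_size(region: CandidateRegion) -> tuple[int, float]:
    """Return ``(size_bp, size_mb)`` for one region."""
    return region.size_bp, region.size_mb


def _check_sorted_disjoint(regions: Sequence[CandidateRegion], name: str) -> None:
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, regs in by_chrom.items():
        for prev, cur in zip(regs, regs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"{name}: regions on {chrom} overlap or are unsorted "
                    f"({prev.start}-{prev.end} vs {cur.start}-{cur.end})"
                )


def intersect(
    regions_a: Sequence[CandidateRegion], regions_b: Sequence[CandidateRegion]
) -> list[CandidateRegion]:
    """Pairwise intersection of two sorted, internally disjoint region lists.

    For every overlapping pair the interval ``[max(starts), min(ends)]`` is
    kept; source labels are unioned.  Raises if the two lists come from
    different chromosome namespaces (no shared chromosome names at all).
    """
    _check_sorted_disjoint(regions_a, "regions_a")
    _check_sorted_disjoint(regions_b, "regions_b")
    if regions_a and regions_b:
        chroms_a = {r.chromosome for r in regions_a}
        chroms_b = {r.chromosome for r in regions_b}
        if not chroms_a & chroms_b:
            raise ValueError(
                "region lists share no chromosome names; inputs appear to come "
                f"from different genomes ({sorted(chroms_a)} vs {sorted(chroms_b)})"
            )
    out: list[CandidateRegion] = []
    for a in regions_a:
        for b in regions_b:
            if a.overlaps(b):
                out.append(
                    CandidateRegion(
                        chromosome=a.chromosome,
                        start=max(a.start, b.start),
                        end=min(a.end, b.end),
                        source_labels=a.source_labels | b.source_labels,
                    )
                )
    out.sort(key=lambda r: (r.chromosome, r.start))
    return out


def total_size(regions: Iterable[CandidateRegion]) -> float:
    """Total span of non-overlapping regions, in Mb (4 decimals).

    Raises on overlapping input: overlapping calls must be intersected or
    merged before they can be accounted.
    """
    regions = sorted(regions, key=lambda r: (r.chromosome, r.start))
    _check_sorted_disjoint(regions, "regions")
    return _round_half_up(sum(r.size_bp for r in regions))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "size_mb": [r.size_mb for r in regions],
            "sources": [",".join(sorted(r.source_labels)) for r in regions],
        }
    )


def write_region_table(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """Write a 1-based TSV (chromosome, start, end, size_mb, sources)."""
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list[CandidateRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    out = []
    for row in df.itertuples(index=False):
        labels = frozenset()
        if "sources" in df.columns and isinstance(row.sources, str) and row.sources:
            labels = frozenset(row.sources.split(","))
        out.append(
            CandidateRegion(
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                source_labels=labels,
            )
        )
    return out


def write_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """Write BED (0-based half-open covering the inclusive 1-based span)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\n")


def read_bed(path: str | Path, label: str | None = None) -> list[CandidateRegion]:
    labels = frozenset({label}) if label else frozenset()
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(
                CandidateRegion(
                    chromosome=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    source_labels=labels,
                )
            )
    return out


def relabel(regions: Sequence[CandidateRegion], label: str) -> list[CandidateRegion]:
    """Return regions with ``label`` added to their source sets."""
    return [replace(r, source_labels=r.source_labels | {label}) for r in regions]
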