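"""Variant-level QC for pooled bulk sequencing.

The scan operates on biallelic SNPs with per-pool allele depths (samples
``HIGH`` and ``LOW`` in the VCF).  QC mirrors standard array/short-read
practice:

* a pool's observation at a site is *valid* only when its total depth is at
  least ``min_depth`` (default 5x); lower-depth observations are missing;
* a site is dropped when its missing fraction over pools exceeds
  ``max_site_missing`` (default 0.5 — with two pools this drops a site only
  when both pools are missing);
* pooled minor-allele frequency, computed from the combined depths of the
  valid pools, must be at least ``min_maf`` (default 0.20, boundary
  inclusive);
* only biallelic SNP records enter at all — indels and multiallelic records
  are dropped at read time.

``marker_density`` summarises the retained panel: SNP counts in
non-overlapping windows (default 500 kb) and adjacent-marker gap sizes per
chromosome.  Window bins are half-open ``[k*w, (k+1)*w)`` on 0-based
coordinates; all I/O stays 1-based.

The per-sample filters that only make sense with many samples (sample
missing rate, per-variety het calling with >= ``het_min_reads_per_allele``
reads per allele) are exposed for per-variety tables but are inert in
two-pool mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

POOLS = ("HIGH", "LOW")

__all__ = [
    "POOLS",
    "VariantSite",
    "QCParams",
    "read_variant_table",
    "apply_validity",
    "apply_maf",
    "apply_qc",
    "marker_density",
    "qc_report",
]


@dataclass
class VariantSite:
    """One biallelic SNP with per-pool (ref_depth, alt_depth) counts."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    depths: dict[str, tuple[int, int]]
    valid: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based; got position < 1")
        for pool, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth at {self.chromosome}:{self.position} ({pool})")
        if not self.valid:
            self.valid = {pool: True for pool in self.depths}

    def total_depth(self, pool: str) -> int:
        r, a = self.depths[pool]
        return r + a


@dataclass(frozen=True)
class QCParams:
    """Filter thresholds; defaults follow common pooled-BSA practice."""

    min_depth: int = 5
    max_site_missing: float = 0.5
    max_sample_missing: float = 0.3
    min_maf: float = 0.2
    het_min_reads_per_allele: int = 4
    density_window: int = 500_000

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("max_site_missing", "max_sample_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> list[VariantSite]:
    """Read biallelic SNPs with AD depths for samples HIGH and LOW.

    Non-SNP and multiallelic records are dropped (count logged).  A missing
    AD field raises, naming the offending sample.
    """
    sites: list[VariantSite] = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for pool in POOLS:
            if pool not in vcf.header.samples:
                raise ValueError(f"VCF lacks required sample {pool!r}")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_dropped += 1
                continue
            depths = {}
            for pool in POOLS:
                ad = rec.samples[pool].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(
                        f"sample {pool!r} lacks AD at {rec.chrom}:{rec.pos}"
                    )
                depths[pool] = (int(ad[0]), int(ad[1]))
            sites.append(
                VariantSite(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    depths=depths,
                )
            )
    if n_dropped:
        logger.info("dropped %d non-SNP/multiallelic records", n_dropped)
    return sites


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_validity(
    sites: Sequence[VariantSite], params: QCParams = QCParams()
) -> list[VariantSite]:
    """Mark low-depth pool observations missing; drop over-missing sites.

    A pool observation with total depth < ``min_depth`` is marked invalid.
    A site is dropped when the fraction of invalid pools exceeds
    ``max_site_missing``.
    """
    out: list[VariantSite] = []
    n_dropped = 0
    for site in sites:
        valid = {
            pool: site.valid[pool] and site.total_depth(pool) >= params.min_depth
            for pool in site.depths
        }
        missing_frac = sum(not v for v in valid.values()) / len(valid)
        if missing_frac > params.max_site_missing:
            n_dropped += 1
            continue
        out.append(replace(site, valid=valid))
    if n_dropped:
        logger.info("validity filter dropped %d sites", n_dropped)
    return out


def pooled_maf(site: VariantSite) -> float:
    """Minor-allele frequency from combined depths of the valid pools."""
    ref = sum(site.depths[p][0] for p in site.depths if site.valid[p])
    alt = sum(site.depths[p][1] for p in site.depths if site.valid[p])
    total = ref + alt
    if total == 0:
        raise ValueError(
            f"zero combined depth at {site.chromosome}:{site.position}; "
            "site should have been dropped by the validity filter"
        )
    return min(ref, alt) / total


def apply_maf(
    sites: Sequence[VariantSite], params: QCParams = QCParams()
) -> list[VariantSite]:
    """Drop sites whose pooled MAF is below ``min_maf`` (boundary retained)."""
    out = [s for s in sites if pooled_maf(s) >= params.min_maf]
    if len(out) != len(sites):
        logger.info("MAF filter dropped %d sites", len(sites) - len(out))
    return out


def apply_qc(
    sites: Sequence[VariantSite], params: QCParams = QCParams()
) -> list[VariantSite]:
    """Full site-level QC: validity/missingness then MAF."""
    return apply_maf(apply_validity(sites, params), params)


def qc_report(
    n_input: int, after_validity: int, after_maf: int
) -> pd.DataFrame:
    """Per-rule drop accounting in tidy form."""
    return pd.DataFrame(
        {
            "stage": ["input", "validity_missingness", "maf"],
            "retained": [n_input, after_validity, after_maf],
            "dropped": [0, n_input - after_validity, after_validity - after_maf],
        }
    )


# ---------------------------------------------------------------------------
# Marker density / gaps
# ---------------------------------------------------------------------------

def marker_density(
    sites: Iterable[VariantSite], window: int = 500_000
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """SNP counts per non-overlapping window and adjacent-marker gaps.

    Windows are ``[k*window, (k+1)*window)`` on 0-based coordinates, so a
    1-based position ``p`` falls into window ``(p - 1) // window``.  Gaps
    are successive position differences per chromosome (empty with < 2
    markers).  Returns a tidy (chromosome, window_start, count) frame —
    1-based window_start — and a gaps dict.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s.position)
    rows = []
    gaps: dict[str, np.ndarray] = {}
    for chrom, positions in by_chrom.items():
        pos = np.sort(np.asarray(positions, dtype=np.int64))
        gaps[chrom] = np.diff(pos)
        idx = (pos - 1) // window
        for k in range(int(idx.max()) + 1):
            rows.append(
                {
                    "chromosome": chrom,
                    "window_start": k * window + 1,
                    "count": int(np.sum(idx == k)),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "window_start", "count"]), gaps
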