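"""The Euclidean-distance (ED) genome scan.

For each QC-passed SNP the two bulks give allele-frequency vectors
``H = (h_ref, h_alt)`` and ``L = (l_ref, l_alt)``; the per-site statistic is

    ED = sqrt( sum_a (H_a - L_a)^2 ),

bounded by sqrt(2) for biallelic sites, zero when the pools agree and large
at trait-linked loci where extreme-tail selection has driven the pooled
frequencies apart.  Raising ED to a power x (default ED^2) suppresses
background relative to signal while preserving rank order.

The per-site track is noisy (finite read depth), so ED^x is smoothed along
each chromosome by a tricube-kernel local weighted mean over physical
distance (default bandwidth 2 Mb).  The significance threshold is computed
per chromosome as ``median(fitted) + 3 * SD(fitted)`` (sample SD), and
candidate regions are maximal runs of sites strictly above it, with runs
closer than ``merge_gap`` bp merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .region_ops import CandidateRegion
from .variant_qc import POOLS, VariantSite

__all__ = [
    "EDProfile",
    "ScanThreshold",
    "pool_frequencies",
    "ed_statistic",
    "build_profiles",
    "power_transform",
    "fit_profile",
    "compute_threshold",
    "call_regions",
    "scan_to_frame",
]


@dataclass
class EDProfile:
    """Per-chromosome scan track: positions with ED, ED^x, and fitted values."""

    chromosome: str
    positions: np.ndarray  # sorted, 1-based bp
    ed: np.ndarray
    x: float = 2.0
    ed_x: np.ndarray | None = None
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ed = np.asarray(self.ed, dtype=float)
        if len(self.positions) != len(self.ed):
            raise ValueError("positions and ed must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions on {self.chromosome} must be strictly increasing")
        if np.any(self.ed < 0):
            raise ValueError("ED values must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ScanThreshold:
    """Per-chromosome significance cut-off: median + 3 SD of the fitted track."""

    chromosome: str
    median: float
    sd: float

    @property
    def value(self) -> float:
        return self.median + 3.0 * self.sd


def pool_frequencies(site: VariantSite) -> tuple[np.ndarray, np.ndarray]:
    """Per-pool (ref, alt) frequency vectors; each sums to 1."""
    freqs = []
    for pool in POOLS:
        r, a = site.depths[pool]
        total = r + a
        if total == 0 or not site.valid.get(pool, True):
            raise ValueError(
                f"pool {pool} unusable at {site.chromosome}:{site.position}; "
                "such sites must be removed by QC before scanning"
            )
        freqs.append(np.array([r, a], dtype=float) / total)
    return freqs[0], freqs[1]


def ed_statistic(H: np.ndarray, L: np.ndarray) -> float:
    """Euclidean distance between two allele-frequency vectors."""
    H = np.asarray(H, dtype=float)
    L = np.asarray(L, dtype=float)
    if H.shape != L.shape:
        raise ValueError(f"frequency vectors differ in length: {H.shape} vs {L.shape}")
    return float(np.sqrt(np.sum((H - L) ** 2)))


def build_profiles(sites: Sequence[VariantSite], x: float = 2.0) -> list[EDProfile]:
    """Per-chromosome ED profiles from QC-passed sites.

    Sites where either pool is invalid or has zero depth cannot contribute
    an ED value and are skipped.
    """
    by_chrom: dict[str, tuple[list[int], list[float]]] = {}
    for s in sites:
        if not all(s.valid.get(p, True) and s.total_depth(p) > 0 for p in POOLS):
            continue
        H, L = pool_frequencies(s)
        pos, ed = by_chrom.setdefault(s.chromosome, ([], []))
        pos.append(s.position)
        ed.append(ed_statistic(H, L))
    profiles = []
    for chrom, (pos, ed) in by_chrom.items():
        order = np.argsort(pos)
        profiles.append(
            EDProfile(
                chromosome=chrom,
                positions=np.asarray(pos)[order],
                ed=np.asarray(ed)[order],
                x=x,
            )
        )
    return profiles


def power_transform(profile: EDProfile, x: float | None = None) -> EDProfile:
    """Set ``ed_x = ed ** x`` (monotone, order-preserving; x >= 1)."""
    if x is not None:
        profile.x = x
    if profile.x < 1:
        raise ValueError("power x must be >= 1")
    profile.ed_x = profile.ed ** profile.x
    return profile


def fit_profile(profile: EDProfile, bandwidth: float = 2_000_000.0) -> EDProfile:
    """Tricube-kernel local weighted mean of ED^x over physical distance.

    fitted_i = sum_j w_ij * ed_x_j / sum_j w_ij over sites j with
    |pos_j - pos_i| < bandwidth, w = (1 - (|d|/bw)^3)^3.  The window always
    contains the site itself (weight 1), so the fit preserves constants and
    reproduces ed_x exactly for isolated sites.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if profile.ed_x is None:
        power_transform(profile)
    pos = profile.positions.astype(float)
    y = profile.ed_x
    n = len(pos)
    if n > 1:
        med_gap = float(np.median(np.diff(pos)))
        if bandwidth < med_gap:
            warnings.warn(
                f"bandwidth {bandwidth:g} bp is below the median marker gap "
                f"({med_gap:g} bp) on {profile.chromosome}; fitted values will "
                "mostly reproduce raw ED^x",
                stacklevel=2,
            )
    fitted = np.empty(n)
    left = np.searchsorted(pos, pos - bandwidth, side="left")
    right = np.searchsorted(pos, pos + bandwidth, side="right")
    for i in range(n):
        d = np.abs(pos[left[i]:right[i]] - pos[i]) / bandwidth
        w = (1.0 - d ** 3) ** 3
        fitted[i] = np.dot(w, y[left[i]:right[i]]) / np.sum(w)
    profile.fitted = fitted
    return profile


def compute_threshold(profile: EDProfile) -> ScanThreshold:
    """median + 3*SD of the fitted track for one chromosome (sample SD, ddof=1)."""
    if profile.fitted is None:
        raise ValueError("profile must be fitted before thresholding")
    if profile.n_sites < 2:
        raise ValueError("threshold undefined with fewer than 2 sites (SD needs n >= 2)")
    return ScanThreshold(
        chromosome=profile.chromosome,
        median=float(np.median(profile.fitted)),
        sd=float(np.std(profile.fitted, ddof=1)),
    )


def call_regions(
    profile: EDProfile,
    threshold: ScanThreshold,
    merge_gap: float = 100_000.0,
    label: str | None = None,
) -> list[CandidateRegion]:
    """Maximal runs of sites strictly above the threshold, as regions.

    Runs separated by less than ``merge_gap`` bp are merged.  Region bounds
    are the first and last above-threshold SNP positions.
    """
    if profile.fitted is None:
        raise ValueError("profile must be fitted before region calling")
    if threshold.chromosome != profile.chromosome:
        raise ValueError(
            f"threshold for {threshold.chromosome} applied to {profile.chromosome}"
        )
    above = profile.fitted > threshold.value
    labels = frozenset({label}) if label else frozenset()
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and profile.positions[run[0]] - profile.positions[merged[-1][1]] < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [
        CandidateRegion(
            chromosome=profile.chromosome,
            start=int(profile.positions[i]),
            end=int(profile.positions[j]),
            source_labels=labels,
        )
        for i, j in merged
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def scan_to_frame(
    profiles: Sequence[EDProfile],
    thresholds: Sequence[ScanThreshold] | None = None,
) -> pd.DataFrame:
    """Tidy per-site scan table (chrom, pos, ed, ed_x, fitted[, threshold])."""
    thr = {t.chromosome: t.value for t in thresholds} if thresholds else {}
    frames = []
    for p in profiles:
        df = pd.DataFrame(
            {
                "chromosome": p.chromosome,
                "position": p.positions,
                "ed": p.ed,
                "ed_x": p.ed_x if p.ed_x is not None else np.nan,
                "fitted": p.fitted if p.fitted is not None else np.nan,
            }
        )
        if thr:
            df["threshold"] = thr.get(p.chromosome, np.nan)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chromosome", "position", "ed", "ed_x", "fitted"]
    )


def thresholds_to_frame(thresholds: Sequence[ScanThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": [t.chromosome for t in thresholds],
            "median": [t.median for t in thresholds],
            "sd": [t.sd for t in thresholds],
            "value": [t.value for t in thresholds],
        }
    )
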