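"""Forward simulation of a BSA pooled-sequencing experiment with known truth.

The generator emulates the study design the scan is built for: a natural
panel of soybean-like varieties genotyped at a multi-chromosome SNP panel, a
quantitative trait (basal internode diameter) controlled by one or more
additive QTLs, replicate "years" that share genotypes but redraw
environmental noise, extreme-tail bulk selection, and pooled short-read
sequencing of the two bulks.

Model
-----
* **Haplotypes.** Each chromosome carries SNPs at uniform-random positions.
  A small pool of founder haplotypes is drawn site-wise from per-SNP panel
  allele frequencies; every individual haplotype is a Markov mosaic of
  founders, switching founders between adjacent SNPs with probability
  ``r = min(0.5, d_bp * 1e-8 * recomb_scale)``.  This yields linkage
  disequilibrium that decays with physical distance — enough to give ED
  peaks of controllable width — without coalescent machinery.
* **Phenotype.** ``y = sum_q effect_q * dosage_q + e``, with Gaussian noise
  scaled so the realized genetic-variance fraction equals the requested
  narrow-sense heritability ``h2``.  ``h2 = 0`` gives a pure-noise (null)
  trait; ``h2 = 1`` is noise-free.
* **Pooled reads.** Per site and pool, depth ~ Poisson(mean depth) and the
  alternate read count ~ Binomial(depth, p'), where ``p`` is the bulk's true
  pooled alternate frequency and ``p' = p(1-e) + (1-p)e`` folds a symmetric
  per-base error rate.

A single master seed expands into independent substreams for panel,
phenotype noise, and read sampling, so every stage is reproducible in
isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .variant_qc import POOLS, VariantSite

__all__ = [
    "QTLSpec",
    "TruthSet",
    "BulkPair",
    "simulate_panel",
    "select_bulks",
    "simulate_pool_reads",
    "write_variant_table",
    "write_truth_json",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QTLSpec:
    """One additive trait locus in the founding panel."""

    chromosome: str
    position: int
    additive_effect: float
    allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("QTL position must be >= 1")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"allele_freq must be in (0, 1), got {self.allele_freq}")
        if not math.isfinite(self.additive_effect):
            raise ValueError("additive_effect must be finite")


@dataclass
class TruthSet:
    """Simulator ground truth: the oracle every downstream stage is tested against."""

    chromosome_lengths: dict[str, int]
    snp_positions: dict[str, np.ndarray]  # sorted, 1-based, per chromosome
    genotypes: dict[str, np.ndarray]  # (n_individuals, n_snps) dosage in {0,1,2}
    phenotypes: np.ndarray  # (n_individuals, n_years)
    qtls: list[QTLSpec]
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.phenotypes.shape[0]

    @property
    def n_years(self) -> int:
        return self.phenotypes.shape[1]

    def qtl_snp_index(self, qtl: QTLSpec) -> int:
        """Index of the QTL's SNP within its chromosome's position array."""
        pos = self.snp_positions[qtl.chromosome]
        i = int(np.searchsorted(pos, qtl.position))
        if i >= len(pos) or pos[i] != qtl.position:
            raise KeyError(f"QTL position {qtl.chromosome}:{qtl.position} not in panel")
        return i


@dataclass(frozen=True)
class BulkPair:
    """The two extreme-phenotype pools selected for sequencing."""

    high_members: frozenset
    low_members: frozenset
    selection_fractions: tuple[float, float]  # (low_q, high_q)

    def __post_init__(self) -> None:
        if not self.high_members or not self.low_members:
            raise ValueError("both bulks must be non-empty")
        if self.high_members & self.low_members:
            raise ValueError("bulk membership must be disjoint")


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _mosaic_haplotypes(
    founders: np.ndarray, r: np.ndarray, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov founder-copying mosaic. founders: (K, n_snp); r: per-SNP switch prob."""
    k, n_snp = founders.shape
    draws = rng.integers(0, k, size=(n_hap, n_snp))
    switch = rng.random((n_hap, n_snp)) < r[None, :]
    switch[:, 0] = True
    # index of most recent switch, carried forward
    col = np.arange(n_snp)[None, :]
    last = np.maximum.accumulate(np.where(switch, col, -1), axis=1)
    founder_idx = np.take_along_axis(draws, last, axis=1)
    return founders[founder_idx, col]


def simulate_panel(
    n_individuals: int,
    chromosome_lengths: Mapping[str, int],
    snp_density: float,
    qtls: Sequence[QTLSpec],
    h2: float,
    n_years: int = 2,
    seed: int = 0,
    *,
    n_founders: int = 16,
    recomb_scale: float = 40.0,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> TruthSet:
    """Simulate genotypes and replicate-year phenotypes for a variety panel.

    Parameters
    ----------
    n_individuals
        Panel size (>= 4).
    chromosome_lengths
        Map chromosome name -> length in bp (all > 0).
    snp_density
        Expected SNPs per Mb; each chromosome gets ``round(len/1e6 * density)``
        markers (at least 1) at uniform-random positions.
    qtls
        Trait loci; each QTL position is forced into the SNP panel and its
        founder allele frequency set to ``allele_freq``.
    h2
        Narrow-sense heritability in [0, 1].  0 gives a pure-noise trait.
    n_years
        Replicates sharing genotypes with independent noise.
    """
    if n_individuals < 4:
        raise ValueError("need at least 4 individuals")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
    for q in qtls:
        if q.chromosome not in chromosome_lengths:
            raise ValueError(f"QTL chromosome {q.chromosome!r} not in panel")
        if q.position > chromosome_lengths[q.chromosome]:
            raise ValueError(
                f"QTL position {q.position} outside {q.chromosome} "
                f"(length {chromosome_lengths[q.chromosome]})"
            )

    ss = np.random.SeedSequence(seed)
    rng_panel, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    snp_positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    lo, hi = freq_range
    for chrom, length in chromosome_lengths.items():
        n_snp = max(1, round(length / 1e6 * snp_density))
        pos = rng_panel.choice(length, size=min(n_snp, length), replace=False) + 1
        qtl_here = [q for q in qtls if q.chromosome == chrom]
        pos = np.union1d(pos, [q.position for q in qtl_here]).astype(np.int64)
        freqs = rng_panel.uniform(lo, hi, size=len(pos))
        for q in qtl_here:
            freqs[np.searchsorted(pos, q.position)] = q.allele_freq
        founders = (rng_panel.random((n_founders, len(pos))) < freqs[None, :]).astype(np.int8)
        d = np.diff(pos, prepend=pos[0])
        r = np.minimum(0.5, d * 1e-8 * recomb_scale)
        haps = _mosaic_haplotypes(founders, r, 2 * n_individuals, rng_panel)
        genotypes[chrom] = (haps[::2] + haps[1::2]).astype(np.int8)
        snp_positions[chrom] = pos

    g = np.zeros(n_individuals)
    for q in qtls:
        pos = snp_positions[q.chromosome]
        g += q.additive_effect * genotypes[q.chromosome][:, np.searchsorted(pos, q.position)]
    var_g = float(np.var(g))

    if h2 == 0.0 or var_g == 0.0:
        genetic, sigma_e = np.zeros(n_individuals), 1.0
    else:
        genetic = g
        sigma_e = math.sqrt(var_g * (1.0 - h2) / h2) if h2 < 1.0 else 0.0
    noise = rng_noise.normal(0.0, sigma_e, size=(n_individuals, n_years)) if sigma_e else 0.0
    phenotypes = genetic[:, None] + noise
    if np.isscalar(noise):
        phenotypes = np.repeat(genetic[:, None], n_years, axis=1)

    return TruthSet(
        chromosome_lengths=dict(chromosome_lengths),
        snp_positions=snp_positions,
        genotypes=genotypes,
        phenotypes=phenotypes,
        qtls=list(qtls),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bulk selection
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_bulks(
    phenotypes: Sequence[float],
    low_q: float,
    high_q: float,
    ids: Sequence | None = None,
) -> BulkPair:
    """Select the extreme tails of a trait distribution as the two bulks.

    The high bulk is the top ``high_q`` fraction by trait value, the low
    bulk the bottom ``low_q`` fraction; tail sizes are round-half-up of
    ``q * n``.  Ties are broken by stable individual-id order, so the
    selection is invariant to input permutation.
    """
    values = np.asarray(phenotypes, dtype=float)
    n = len(values)
    if ids is None:
        ids = list(range(n))
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids and phenotypes must have equal length")
    if not (0 < low_q <= 0.5 and 0 < high_q <= 0.5):
        raise ValueError("tail fractions must be in (0, 0.5]")
    if np.ptp(values) == 0:
        raise ValueError("all phenotypes identical: no extremes definable")
    n_low = _round_half_up(low_q * n)
    n_high = _round_half_up(high_q * n)
    if n_low < 1 or n_high < 1:
        raise ValueError("tail fraction too small: empty bulk after rounding")

    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    low = frozenset(ids[i] for i in order[:n_low])
    high_order = sorted(range(n), key=lambda i: (-values[i], ids[i]))
    high = frozenset(ids[i] for i in high_order[:n_high])
    if high & low:
        raise ValueError("tail fractions overlap: an individual fell in both bulks")
    return BulkPair(high_members=high, low_members=low, selection_fractions=(low_q, high_q))


# ---------------------------------------------------------------------------
# Pooled reads
# ---------------------------------------------------------------------------

def simulate_pool_reads(
    truth: TruthSet,
    bulks: BulkPair,
    depth: float,
    error_rate: float = 0.001,
    seed: int = 0,
) -> list[VariantSite]:
    """Sample pooled sequencing depths for the two bulks at every panel SNP.

    Returns VariantSites sorted by (chromosome in panel order, position),
    ready for :func:`edscan.synth_data.write_variant_table`.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    members = {
        "HIGH": np.array(sorted(bulks.high_members)),
        "LOW": np.array(sorted(bulks.low_members)),
    }
    sites: list[VariantSite] = []
    for chrom, pos in truth.snp_positions.items():
        geno = truth.genotypes[chrom]
        n_snp = len(pos)
        ref_idx = rng.integers(0, 4, size=n_snp)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snp)) % 4
        pool_counts = {}
        for pool in POOLS:
            p = geno[members[pool]].mean(axis=0) / 2.0
            p_err = p * (1 - error_rate) + (1 - p) * error_rate
            dp = rng.poisson(depth, size=n_snp)
            alt = rng.binomial(dp, p_err)
            pool_counts[pool] = (dp - alt, alt)
        for j in range(n_snp):
            sites.append(
                VariantSite(
                    chromosome=chrom,
                    position=int(pos[j]),
                    ref_allele=str(_BASES[ref_idx[j]]),
                    alt_allele=str(_BASES[alt_idx[j]]),
                    depths={
                        pool: (int(pool_counts[pool][0][j]), int(pool_counts[pool][1][j]))
                        for pool in POOLS
                    },
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _check_sorted(sites: Sequence[VariantSite]) -> list[str]:
    """Return chromosome first-appearance order; raise on unsorted input."""
    order: list[str] = []
    last_pos: dict[str, int] = {}
    for s in sites:
        if s.chromosome not in last_pos:
            if s.chromosome in order:
                raise ValueError(f"sites not grouped by chromosome at {s.chromosome}")
            order.append(s.chromosome)
        elif s.position <= last_pos[s.chromosome]:
            raise ValueError(
                f"positions not strictly increasing on {s.chromosome} at {s.position}"
            )
        last_pos[s.chromosome] = s.position
    return order


def write_variant_table(
    sites: Sequence[VariantSite],
    path: str | Path,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write sites as an uncompressed VCF 4.2 with samples HIGH and LOW (AD, DP).

    Input must be sorted by (chromosome, position); round-trips losslessly
    through :func:`edscan.variant_qc.read_variant_table`.
    """
    order = _check_sorted(sites)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lengths = dict(chromosome_lengths or {})
    for chrom in order:
        if chrom in lengths:
            header.contigs.add(chrom, length=lengths[chrom])
        else:
            header.contigs.add(chrom)
    for chrom, length in lengths.items():
        if chrom not in header.contigs:
            header.contigs.add(chrom, length=length)
    for pool in POOLS:
        header.add_sample(pool)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sites:
            rec = vcf.new_record(
                contig=s.chromosome,
                start=s.position - 1,
                stop=s.position,
                alleles=(s.ref_allele, s.alt_allele),
            )
            for pool in POOLS:
                r, a = s.depths[pool]
                rec.samples[pool]["AD"] = (r, a)
                rec.samples[pool]["DP"] = r + a
            vcf.write(rec)


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    """Persist the ground truth needed for downstream validation (QTLs, seed)."""
    payload = {
        "seed": truth.seed,
        "n_individuals": truth.n_individuals,
        "n_years": truth.n_years,
        "chromosome_lengths": truth.chromosome_lengths,
        "qtls": [
            {
                "chromosome": q.chromosome,
                "position": q.position,
                "additive_effect": q.additive_effect,
                "allele_freq": q.allele_freq,
            }
            for q in truth.qtls
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
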