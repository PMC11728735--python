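"""End-to-end orchestration: simulate -> QC -> ED scan -> regions -> overlap -> genes.

``run_pipeline`` drives every stage from a single :class:`RunConfig`, writes
all tables under an output directory, and records a manifest with the seeds,
a parameter hash, per-stage record counts, and content hashes of every
output file, so a rerun with the same config is verifiably bit-identical.

Seed handling: the master seed expands through ``numpy.random.SeedSequence``
into one substream for the panel and one per year for read sampling; all
derived seeds are logged in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate, ed_scan, pheno_stats, region_ops, synth_data, variant_qc
from .region_ops import CandidateRegion
from .synth_data import QTLSpec
from .variant_qc import QCParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "scan_year", "overlap_years"]


@dataclass
class RunConfig:
    """Every stage parameter of a simulated two-bulk scan, in one place."""

    # panel / trait
    n_individuals: int = 200
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {f"Chr{i}": 40_000_000 for i in range(1, 6)}
    )
    snp_density: float = 25.0  # SNPs per Mb
    qtls: list[QTLSpec] = field(
        default_factory=lambda: [QTLSpec("Chr1", 20_000_000, 1.0, 0.5)]
    )
    h2: float = 0.8
    n_years: int = 2
    # bulks / sequencing
    low_q: float = 0.15
    high_q: float = 0.15
    depth: float = 50.0
    error_rate: float = 0.001
    # QC / scan
    qc: QCParams = field(default_factory=QCParams)
    power: float = 2.0
    bandwidth: float = 2_000_000.0
    merge_gap: float = 100_000.0
    # misc
    seed: int = 0
    gff: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "qtls" in raw:
            raw["qtls"] = [QTLSpec(**q) for q in raw["qtls"]]
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def scan_year(
    sites: Sequence[variant_qc.VariantSite],
    qc: QCParams,
    power: float,
    bandwidth: float,
    merge_gap: float,
    label: str,
) -> dict[str, Any]:
    """QC one year's sites and run the full ED scan on the survivors."""
    n_input = len(sites)
    after_validity = variant_qc.apply_validity(sites, qc)
    passed = variant_qc.apply_maf(after_validity, qc)
    profiles = ed_scan.build_profiles(passed, x=power)
    thresholds, regions = [], []
    for p in profiles:
        ed_scan.power_transform(p)
        ed_scan.fit_profile(p, bandwidth)
        if p.n_sites < 2:
            logger.info("%s: %s has <2 sites, no threshold", label, p.chromosome)
            continue
        t = ed_scan.compute_threshold(p)
        thresholds.append(t)
        regions.extend(ed_scan.call_regions(p, t, merge_gap, label=label))
    regions.sort(key=lambda r: (r.chromosome, r.start))
    logger.info(
        "%s: %d sites in, %d after validity, %d after MAF, %d regions",
        label, n_input, len(after_validity), len(passed), len(regions),
    )
    return {
        "label": label,
        "counts": (n_input, len(after_validity), len(passed)),
        "sites": passed,
        "profiles": profiles,
        "thresholds": thresholds,
        "regions": regions,
    }


def overlap_years(yearly_regions: Sequence[Sequence[CandidateRegion]]) -> list[CandidateRegion]:
    """Fold interval intersection over the per-year region lists."""
    if not yearly_regions:
        return []
    result = list(yearly_regions[0])
    for regs in yearly_regions[1:]:
        if not result or not regs:
            return []
        try:
            result = region_ops.intersect(result, list(regs))
        except ValueError:
            # no shared chromosome names between non-empty lists: empty overlap
            return []
    return result


def _file_hashes(outdir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return hashes


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the whole simulated BSA analysis; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_years)
    panel_seed = int(children[0].generate_state(1)[0] % (2**31))
    year_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[1:]]

    truth = synth_data.simulate_panel(
        n_individuals=config.n_individuals,
        chromosome_lengths=config.chromosome_lengths,
        snp_density=config.snp_density,
        qtls=config.qtls,
        h2=config.h2,
        n_years=config.n_years,
        seed=panel_seed,
    )
    synth_data.write_truth_json(truth, outdir / "truth.json")

    pheno = pd.DataFrame(
        [
            {"id": i, "year": y, "trait": truth.phenotypes[i, y]}
            for i in range(truth.n_individuals)
            for y in range(truth.n_years)
        ]
    )
    pheno_stats.write_phenotypes(pheno, outdir / "phenotypes.tsv")
    pheno_stats.summarize_table(pheno).to_csv(
        outdir / "phenotype_summary.tsv", sep="\t", index=False
    )

    stage_counts = {}
    yearly_regions: list[list[CandidateRegion]] = []
    for year in range(config.n_years):
        label = f"year{year}"
        bulks = synth_data.select_bulks(
            truth.phenotypes[:, year], config.low_q, config.high_q
        )
        sites = synth_data.simulate_pool_reads(
            truth, bulks, config.depth, config.error_rate, seed=year_seeds[year]
        )
        synth_data.write_variant_table(
            sites, outdir / f"{label}.vcf", truth.chromosome_lengths
        )
        result = scan_year(
            sites, config.qc, config.power, config.bandwidth, config.merge_gap, label
        )
        stage_counts[label] = {
            "sites_input": result["counts"][0],
            "sites_after_validity": result["counts"][1],
            "sites_after_maf": result["counts"][2],
            "regions": len(result["regions"]),
        }
        ed_scan.scan_to_frame(result["profiles"], result["thresholds"]).to_csv(
            outdir / f"{label}_scan.tsv", sep="\t", index=False, float_format="%.6g"
        )
        ed_scan.thresholds_to_frame(result["thresholds"]).to_csv(
            outdir / f"{label}_thresholds.tsv", sep="\t", index=False, float_format="%.6g"
        )
        region_ops.write_region_table(result["regions"], outdir / f"{label}_regions.tsv")
        region_ops.write_bed(result["regions"], outdir / f"{label}_regions.bed")
        density, _ = variant_qc.marker_density(result["sites"], config.qc.density_window)
        density.to_csv(outdir / f"{label}_density.tsv", sep="\t", index=False)
        yearly_regions.append(result["regions"])

    overlap = overlap_years(yearly_regions)
    region_ops.write_region_table(overlap, outdir / "overlap_regions.tsv")
    region_ops.write_bed(overlap, outdir / "overlap_regions.bed")
    total_mb = region_ops.total_size(overlap)
    logger.info("cross-year overlap: %d regions, %.4f Mb", len(overlap), total_mb)

    n_genes = None
    if config.gff:
        genes = annotate.read_gff3(config.gff)
        assignment = annotate.genes_in_regions(genes, overlap)
        gene_frame = annotate.genes_to_frame(assignment)
        gene_frame.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
        n_genes = len(gene_frame)

    manifest: dict[str, Any] = {
        "parameters": config.to_dict(),
        "param_hash": config.param_hash(),
        "seeds": {"master": config.seed, "panel": panel_seed, "years": year_seeds},
        "stage_counts": stage_counts,
        "overlap": {
            "n_regions": len(overlap),
            "total_mb": total_mb,
            "n_candidate_genes": n_genes,
        },
        "outputs": _file_hashes(outdir),
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
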