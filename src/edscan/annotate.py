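"""Gene-model annotation of candidate regions from GFF3.

Once the scan has produced cross-year candidate intervals, the remaining
step is listing the gene models they contain.  A gene is assigned to a
region when the two intervals share at least 1 bp (1-based inclusive on
both sides); a stricter containment-only mode is available.  Strand is
carried through but ignored for overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd

from .region_ops import CandidateRegion

__all__ = ["GeneModel", "read_gff3", "write_gff3", "genes_in_regions", "genes_to_frame"]


@dataclass(frozen=True)
class GeneModel:
    """One gene feature from a GFF3 (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    attributes: tuple = field(default_factory=tuple)  # sorted (key, value) pairs

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def _validate_gff3(path: str | Path) -> None:
    """Cheap structural check so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}: line {lineno}: bad interval {start}-{end}")


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """All features of the given type (default ``gene``), coordinates verbatim."""
    _validate_gff3(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes = []
    for feat in db.features_of_type(feature_type):
        attrs = tuple(sorted((k, ",".join(v)) for k, v in feat.attributes.items()))
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or "+",
                attributes=attrs,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene features back to GFF3 (used for round-trip validation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = dict(g.attributes)
            attrs.setdefault("ID", g.gene_id)
            attr_str = ";".join(f"{k}={v}" for k, v in sorted(attrs.items()))
            fh.write(
                f"{g.chromosome}\tedscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attr_str}\n"
            )


def genes_in_regions(
    genes: Sequence[GeneModel],
    regions: Sequence[CandidateRegion],
    containment_only: bool = False,
) -> dict[CandidateRegion, list[GeneModel]]:
    """Assign genes to the candidate regions they overlap.

    Overlap is >= 1 bp with both intervals 1-based inclusive; with
    ``containment_only`` the gene must lie entirely inside the region.
    Output lists are sorted by gene start; assignment is independent of
    input order.
    """
    out: dict[CandidateRegion, list[GeneModel]] = {r: [] for r in regions}
    for region in regions:
        for gene in genes:
            if gene.chromosome != region.chromosome:
                continue
            if containment_only:
                hit = region.start <= gene.start and gene.end <= region.end
            else:
                hit = gene.start <= region.end and region.start <= gene.end
            if hit:
                out[region].append(gene)
        out[region].sort(key=lambda g: (g.start, g.gene_id))
    return out


def genes_to_frame(assignment: Mapping[CandidateRegion, Sequence[GeneModel]]) -> pd.DataFrame:
    """Flat candidate-gene table (region, gene_id, start, end, strand)."""
    rows = []
    for region, genes in assignment.items():
        for g in genes:
            rows.append(
                {
                    "chromosome": region.chromosome,
                    "region_start": region.start,
                    "region_end": region.end,
                    "gene_id": g.gene_id,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "strand": g.strand,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "region_start", "region_end",
            "gene_id", "gene_start", "gene_end", "strand",
        ],
    )
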