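"""Genomic-context classification of CNVRs against gene models.

Each CNVR receives exactly one of five classes with the precedence
exonic > intronic > upstream > downstream > intergenic:

- exonic: overlaps >= 1 exon base of any gene;
- intronic: overlaps a gene body but no exon;
- upstream / downstream: within ``flank_bp`` of a gene start/end respecting
  strand (upstream of a ``+`` gene lies below its start; of a ``-`` gene,
  above its end);
- intergenic: none of the above.

All interval arithmetic is on closed 1-based coordinates. The flank defaults
to 1900 bp; it is a parameter everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

EXONIC = "exonic"
INTRONIC = "intronic"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
INTERGENIC = "intergenic"
REGION_CLASSES = (EXONIC, INTRONIC, UPSTREAM, DOWNSTREAM, INTERGENIC)

DEFAULT_FLANK_BP = 1900


@dataclass(frozen=True)
class GeneModel:
    """A gene with normalized exons, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s}, {e}) outside gene span"
                )


def _normalize_exons(
    exons: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Sort exons and merge any that overlap by >= 1 base."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(exons):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (exons linked to genes via Parent/ID
    chains, possibly through mRNA).

    Genes without exon children become single-exon genes spanning the gene
    body. Exons whose Parent chain reaches no gene, and features without a
    strand, raise errors naming the feature.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon, featuretype="gene"))
        if not parents:
            raise ValueError(
                f"orphan exon {exon.id or exon.attributes}: no gene ancestor"
            )
        for gene in parents:
            exons_by_gene.setdefault(gene.id, []).append((exon.start, exon.end))
    models = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.id}: missing strand")
        exons = exons_by_gene.get(gene.id) or [(gene.start, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=_normalize_exons(exons),
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


class GeneIndex:
    """Interval indexes over exons, gene bodies, and strand-aware flanks.

    Trees hold 0-based half-open intervals (the intervaltree convention);
    the query converts from closed 1-based.
    """

    def __init__(self, models: Sequence[GeneModel], flank_bp: int = DEFAULT_FLANK_BP):
        if flank_bp <= 0:
            raise ValueError("flank_bp must be > 0")
        self.flank_bp = flank_bp
        self.models = list(models)
        self._exons: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        self._upstream: dict[str, IntervalTree] = {}
        self._downstream: dict[str, IntervalTree] = {}
        for g in models:
            bodies = self._bodies.setdefault(g.chrom, IntervalTree())
            bodies.addi(g.start - 1, g.end, g.gene_id)
            exons = self._exons.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                exons.addi(s - 1, e, g.gene_id)
            if g.strand == "+":
                up = (g.start - flank_bp, g.start - 1)  # 1-based inclusive
                down = (g.end + 1, g.end + flank_bp)
            else:
                up = (g.end + 1, g.end + flank_bp)
                down = (g.start - flank_bp, g.start - 1)
            for tree_map, (s, e) in ((self._upstream, up), (self._downstream, down)):
                s = max(1, s)
                if s <= e:
                    tree_map.setdefault(g.chrom, IntervalTree()).addi(
                        s - 1, e, g.gene_id
                    )

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, start: int, end: int):
        tree = trees.get(chrom)
        return tree.overlap(start - 1, end) if tree is not None else set()

    def classify(self, chrom: str, start: int, end: int) -> str:
        if self._hits(self._exons, chrom, start, end):
            return EXONIC
        if self._hits(self._bodies, chrom, start, end):
            return INTRONIC
        if self._hits(self._upstream, chrom, start, end):
            return UPSTREAM
        if self._hits(self._downstream, chrom, start, end):
            return DOWNSTREAM
        return INTERGENIC

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        return sorted({iv.data for iv in self._hits(self._bodies, chrom, start, end)})


def classify_region(
    region,
    gene_models: Sequence[GeneModel] | GeneIndex,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> str:
    """Classify one region (anything with chrom/start/end) by precedence."""
    index = (
        gene_models
        if isinstance(gene_models, GeneIndex)
        else GeneIndex(gene_models, flank_bp)
    )
    return index.classify(region.chrom, region.start, region.end)


def overlap_genes(
    regions: Sequence, gene_models: Sequence[GeneModel] | GeneIndex
) -> dict[str, list[str]]:
    """Gene ids whose span overlaps each region by >= 1 bp (region id keyed)."""
    index = (
        gene_models
        if isinstance(gene_models, GeneIndex)
        else GeneIndex(gene_models)
    )
    return {
        r.id: index.genes_overlapping(r.chrom, r.start, r.end) for r in regions
    }


def region_distribution(
    regions: Sequence,
    gene_models: Sequence[GeneModel] | GeneIndex,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> dict[str, float]:
    """Fraction of regions in each of the five classes (sums to 1)."""
    if len(regions) == 0:
        raise ValueError("region distribution undefined for an empty set")
    index = (
        gene_models
        if isinstance(gene_models, GeneIndex)
        else GeneIndex(gene_models, flank_bp)
    )
    counts = {c: 0 for c in REGION_CLASSES}
    for r in regions:
        counts[index.classify(r.chrom, r.start, r.end)] += 1
    n = len(regions)
    return {c: counts[c] / n for c in REGION_CLASSES}


def annotation_table(
    regions: Sequence,
    gene_models: Sequence[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Per-region class and semicolon-joined overlapping gene ids."""
    index = GeneIndex(gene_models, flank_bp)
    rows = []
    for r in regions:
        rows.append(
            {
                "cnvr_id": r.id,
                "region_class": index.classify(r.chrom, r.start, r.end),
                "gene_ids": ";".join(
                    index.genes_overlapping(r.chrom, r.start, r.end)
                ),
            }
        )
    return pd.DataFrame(rows)
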