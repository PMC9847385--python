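"""Breakpoint annotation: genomic region class, DNase-I hypersensitivity, repeats.

Breakpoints are annotated as points (1-based).  Region classes follow the
precedence promoter > five_prime_utr > three_prime_utr > exon > intron >
intergenic, with the promoter defined as an orientation-aware window around
the TSS (default -2,000/+200).  UTRs are derived from CDS-vs-exon geometry on
protein-coding genes; genes without CDS have only exon/intron classes.
Repeat classes map onto {LTR, LINE, SINE, Retroposon, Simple_repeat, none}
with priority LTR > LINE > SINE > Retroposon > Simple_repeat after score.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from virin.breakpoint_calling import BreakpointCluster
from virin.config import AnnotationConfig
from virin.io_formats import GeneModel, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

REGION_CLASSES = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "intergenic",
)
_REGION_PRECEDENCE = {
    "promoter": 0,
    "five_prime_utr": 1,
    "three_prime_utr": 2,
    "exon": 3,
    "intron": 4,
    "intergenic": 5,
}

REPEAT_CLASSES = ("LTR", "LINE", "SINE", "Retroposon", "Simple_repeat", "none")
_REPEAT_PRIORITY = {c: i for i, c in enumerate(REPEAT_CLASSES)}
_REPEAT_SYNONYMS = {
    "ltr": "LTR",
    "line": "LINE",
    "sine": "SINE",
    "retroposon": "Retroposon",
    "simple_repeat": "Simple_repeat",
    "simple repeat": "Simple_repeat",
}


@dataclass
class AnnotatedBreakpoint:
    cluster: BreakpointCluster
    region_class: str
    dnase: bool
    repeat_class: str
    gene_name: str | None
    gene_type: str  # {protein_coding, lncRNA, pseudogene, other, none}


class IntervalLookup:
    """Point-in-interval queries over sorted per-chromosome start arrays."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, list[GenomicInterval]]] = {}
        grouped: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in intervals:
            grouped[iv.chrom].append(iv)
        for chrom, ivs in grouped.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ivs)

    def overlapping_1based(self, chrom: str, pos: int) -> list[GenomicInterval]:
        entry = self._by_chrom.get(normalize_chrom(chrom))
        if entry is None:
            return []
        starts, ivs = entry
        hi = int(np.searchsorted(starts, pos, side="left"))  # starts < pos
        # intervals start anywhere before pos; scan back (desk-scale tracks)
        return [iv for iv in ivs[:hi] if iv.contains_1based(pos)]


def classify_region(
    chrom: str,
    pos: int,
    gene_model: GeneModel,
    config: AnnotationConfig | None = None,
) -> tuple[str, str | None, str]:
    """Region class of a 1-based point, with the responsible gene.

    Returns (region_class, gene_name or None, gene_type or 'none').
    Overlapping genes resolve by class precedence, then smaller gene span,
    then lexicographic gene name.
    """
    config = config or AnnotationConfig()
    chrom = normalize_chrom(chrom)
    p0 = pos - 1  # 0-based point
    hits: list[tuple[int, int, str, str, str]] = []
    for gene in gene_model.genes:
        if gene.chrom != chrom:
            continue
        tss = gene.tss
        if gene.strand == "+":
            prom_lo, prom_hi = tss - config.promoter_up, tss + config.promoter_down
        else:
            prom_lo, prom_hi = tss - config.promoter_down, tss + config.promoter_up
        if prom_lo <= p0 <= prom_hi:
            hits.append(
                (_REGION_PRECEDENCE["promoter"], gene.span, gene.name, "promoter", gene.gene_type)
            )
        if gene.start <= p0 < gene.end:
            in_exon = any(s <= p0 < e for s, e in gene.exons)
            if not in_exon:
                region = "intron"
            elif gene.gene_type == "protein_coding" and gene.cds:
                cds_lo, cds_hi = gene.cds[0][0], gene.cds[-1][1]
                if p0 < cds_lo:
                    region = "five_prime_utr" if gene.strand == "+" else "three_prime_utr"
                elif p0 >= cds_hi:
                    region = "three_prime_utr" if gene.strand == "+" else "five_prime_utr"
                else:
                    region = "exon"
            else:
                region = "exon"
            hits.append((_REGION_PRECEDENCE[region], gene.span, gene.name, region, gene.gene_type))
    if not hits:
        return "intergenic", None, "none"
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    _, _, gene_name, region, gene_type = hits[0]
    return region, gene_name, gene_type


def annotate_dnase(chrom: str, pos: int, dnase: IntervalLookup) -> bool:
    """True iff the 1-based position falls inside any DNase-I HS interval."""
    return bool(dnase.overlapping_1based(chrom, pos))


def map_repeat_class(raw: str) -> str:
    """Map an annotation label onto the repeat-class vocabulary; unknown -> none."""
    key = raw.strip().lower().split("/")[0]
    mapped = _REPEAT_SYNONYMS.get(key)
    if mapped is None:
        logger.warning("unknown repeat class %r mapped to none", raw)
        return "none"
    return mapped


def annotate_repeat(chrom: str, pos: int, repeats: IntervalLookup) -> str:
    """Repeat class at a point; overlaps resolve by score then class priority."""
    overlaps = repeats.overlapping_1based(chrom, pos)
    best: tuple[float, int, str] | None = None
    for iv in overlaps:
        cls = map_repeat_class(iv.attrs.get("repeat_class", iv.name))
        if cls == "none":
            continue
        score = iv.score if iv.score is not None else 0.0
        key = (-score, _REPEAT_PRIORITY[cls], cls)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else "none"


def annotate_all(
    clusters: list[BreakpointCluster],
    gene_model: GeneModel,
    dnase_intervals: list[GenomicInterval],
    repeat_intervals: list[GenomicInterval],
    config: AnnotationConfig | None = None,
) -> list[AnnotatedBreakpoint]:
    config = config or AnnotationConfig()
    dnase = IntervalLookup(dnase_intervals)
    repeats = IntervalLookup(repeat_intervals)
    annotated = []
    for cluster in clusters:
        chrom, pos = cluster.chrom, cluster.representative_pos
        region, gene_name, gene_type = classify_region(chrom, pos, gene_model, config)
        annotated.append(
            AnnotatedBreakpoint(
                cluster=cluster,
                region_class=region,
                dnase=annotate_dnase(chrom, pos, dnase),
                repeat_class=annotate_repeat(chrom, pos, repeats),
                gene_name=gene_name,
                gene_type=gene_type,
            )
        )
    return annotated


def annotated_table(annotated: list[AnnotatedBreakpoint]) -> pd.DataFrame:
    """Per-breakpoint TSV rows in the standard schema."""
    rows = []
    for ab in annotated:
        c = ab.cluster
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "pos_1based": c.representative_pos,
                "virus_id": c.virus_id,
                "evidence": "softclip" if c.exact_members else "discordant",
                "support": c.support,
                "region_class": ab.region_class,
                "dnase": int(ab.dnase),
                "repeat_class": ab.repeat_class,
                "gene_name": ab.gene_name if ab.gene_name else ".",
                "gene_type": ab.gene_type,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos_1based", "virus_id", "evidence", "support",
            "region_class", "dnase", "repeat_class", "gene_name", "gene_type",
        ],
    )


def summary_tables(annotated: list[AnnotatedBreakpoint]) -> dict[str, pd.DataFrame]:
    """Cohort-style summaries: per-chromosome counts, region-class percentages
    (printed to 2 decimals), per-sample DNase counts, repeat-class counts, and
    the per-gene frequency list."""
    df = annotated_table(annotated)
    n = len(df)
    per_chrom = (
        df.groupby("chrom").size().rename("n_breakpoints").reset_index()
        if n else pd.DataFrame(columns=["chrom", "n_breakpoints"])
    )
    region = pd.DataFrame({"region_class": list(REGION_CLASSES)})
    counts = df["region_class"].value_counts() if n else pd.Series(dtype=int)
    region["n"] = region["region_class"].map(counts).fillna(0).astype(int)
    region["pct"] = (100.0 * region["n"] / n).round(2) if n else 0.0
    dnase_per_sample = (
        df.groupby("sample_id")["dnase"].sum().rename("n_dnase").reset_index()
        if n else pd.DataFrame(columns=["sample_id", "n_dnase"])
    )
    repeat = pd.DataFrame({"repeat_class": [c for c in REPEAT_CLASSES if c != "none"]})
    rcounts = df.loc[df["repeat_class"] != "none", "repeat_class"].value_counts() if n else pd.Series(dtype=int)
    repeat["n"] = repeat["repeat_class"].map(rcounts).fillna(0).astype(int)
    genes = (
        df.loc[df["gene_name"] != "."]
        .groupby(["gene_name", "gene_type"])
        .size()
        .rename("n_breakpoints")
        .reset_index()
        .sort_values(["n_breakpoints", "gene_name"], ascending=[False, True])
        .reset_index(drop=True)
        if n else pd.DataFrame(columns=["gene_name", "gene_type", "n_breakpoints"])
    )
    return {
        "per_chromosome": per_chrom,
        "region_distribution": region,
        "dnase_per_sample": dnase_per_sample,
        "repeat_classes": repeat,
        "gene_list": genes,
    }
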