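"""Peak annotation against promoter windows and enhancer catalogues.

A peak is *promoter* when it overlaps the strand-aware window -1500/+500
around any TSS (upstream means 5' of the gene), *enhancer* when it is not
promoter but overlaps a catalogued enhancer interval, and *distal*
otherwise. Promoter takes precedence over enhancer. Variant intersection
with differentially accessible regions (DARs) applies the GWAS
association-p filter first, then point-in-interval on the half-open
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval, VariantRecord

logger = logging.getLogger("epinteg")

PROMOTER_WINDOW = (-1500, 500)  # upstream, downstream of the TSS (bp)


@dataclass
class AnnotatedPeak:
    """A peak with its category, assigned genes and (optional) differential row."""

    interval: GenomicInterval
    category: str  # promoter | enhancer | distal
    genes: list[str] = field(default_factory=list)
    diff: pd.Series | None = None

    def __post_init__(self):
        if self.category not in ("promoter", "enhancer", "distal"):
            raise ValueError(f"invalid category {self.category!r}")
        if self.category == "distal" and self.genes:
            raise ValueError("distal peaks carry no gene assignment")


def promoter_window(gene: GeneModel,
                    window: tuple[int, int] = PROMOTER_WINDOW) -> tuple[int, int]:
    """Genomic half-open promoter interval for a gene, strand-aware.

    ``window = (upstream, downstream)`` with upstream < 0 < downstream,
    measured along the gene's direction of transcription. On the + strand
    the window is [tss + upstream, tss + downstream); on the - strand it
    mirrors to [tss - downstream + 1, tss - upstream + 1), so that the
    same bases relative to the TSS are covered.
    """
    up, down = window
    if not (up < 0 < down):
        raise ValueError(f"window must satisfy upstream < 0 < downstream, got {window}")
    if gene.strand == "+":
        lo, hi = gene.tss + up, gene.tss + down
    else:
        lo, hi = gene.tss - down + 1, gene.tss - up + 1
    return max(0, lo), hi


class _GenomeIndex:
    """Per-chromosome interval trees over promoter windows and enhancers."""

    def __init__(self, gene_models: list[GeneModel],
                 enhancers: list[GenomicInterval],
                 enhancer_links: pd.DataFrame,
                 window: tuple[int, int] = PROMOTER_WINDOW):
        self.promoter_trees: dict[str, IntervalTree] = {}
        self.enhancer_trees: dict[str, IntervalTree] = {}
        for g in gene_models:
            lo, hi = promoter_window(g, window)
            self.promoter_trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
        known = {e.id for e in enhancers}
        bad = set(enhancer_links["enhancer_id"]) - known
        if bad:
            raise ValueError(f"links reference unknown enhancer id(s): {sorted(bad)[:5]}")
        by_enh = enhancer_links.groupby("enhancer_id")["gene_id"].apply(list).to_dict()
        for e in enhancers:
            genes = by_enh.get(e.id, [])
            self.enhancer_trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, genes)


def classify_peak(peak: GenomicInterval, index: _GenomeIndex) -> AnnotatedPeak:
    """Assign one peak to promoter / enhancer / distal with its genes."""
    ptree = index.promoter_trees.get(peak.chrom)
    etree = index.enhancer_trees.get(peak.chrom)
    if ptree is None and etree is None:
        logger.warning("peak %s on chromosome %r with no genes or enhancers; distal",
                       peak.id, peak.chrom)
        return AnnotatedPeak(peak, "distal")
    if ptree is not None:
        hits = ptree.overlap(peak.start, peak.end)
        if hits:
            genes = sorted({h.data for h in hits})
            return AnnotatedPeak(peak, "promoter", genes)
    if etree is not None:
        hits = etree.overlap(peak.start, peak.end)
        if hits:
            genes = sorted({g for h in hits for g in h.data})
            return AnnotatedPeak(peak, "enhancer", genes)
    return AnnotatedPeak(peak, "distal")


def annotate_peaks(peaks: list[GenomicInterval], gene_models: list[GeneModel],
                   enhancers: list[GenomicInterval], enhancer_links: pd.DataFrame,
                   window: tuple[int, int] = PROMOTER_WINDOW,
                   diff: pd.DataFrame | None = None) -> list[AnnotatedPeak]:
    """Classify every peak; attach its differential row when provided."""
    index = _GenomeIndex(gene_models, enhancers, enhancer_links, window)
    out = []
    for p in peaks:
        ap = classify_peak(p, index)
        if diff is not None and p.id in diff.index:
            ap.diff = diff.loc[p.id]
        out.append(ap)
    return out


def annotation_table(annotated: list[AnnotatedPeak]) -> pd.DataFrame:
    """Flat TSV-ready table of annotated peaks (one row per peak)."""
    rows = []
    for ap in annotated:
        iv = ap.interval
        row = {
            "peak_id": iv.id, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "category": ap.category, "genes": ",".join(ap.genes),
        }
        if ap.diff is not None:
            for col in ("log2fc", "p", "q", "confect"):
                if col in ap.diff.index:
                    row[col] = ap.diff[col]
        rows.append(row)
    return pd.DataFrame(rows)


def build_enhancer_locus_map(enhancer_links: pd.DataFrame,
                             enhancers: list[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    """Invert the enhancer->gene link table into gene -> enhancer intervals."""
    by_id = {e.id: e for e in enhancers}
    out: dict[str, list[GenomicInterval]] = {}
    for row in enhancer_links.itertuples():
        if row.enhancer_id not in by_id:
            raise ValueError(f"link references unknown enhancer id {row.enhancer_id!r}")
        out.setdefault(row.gene_id, []).append(by_id[row.enhancer_id])
    return out


def intersect_variants(variants: list[VariantRecord],
                       dars: list[AnnotatedPeak],
                       max_assoc_p: float = 0.05) -> pd.DataFrame:
    """Overlap GWAS variants with differentially accessible peaks.

    Variants with association p > ``max_assoc_p`` are removed first. A
    variant overlaps a DAR iff ``start <= pos < end``. Returns rows
    (rsid, peak_id, category, direction) where direction is the sign of
    the peak's accessibility log2fc ("up"/"down", "" if unknown).
    """
    kept = [v for v in variants if v.assoc_p <= max_assoc_p]
    trees: dict[str, IntervalTree] = {}
    for ap in dars:
        iv = ap.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, ap)
    rows = []
    for v in kept:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.at(v.pos), key=lambda h: h.data.interval.id):
            ap = hit.data
            direction = ""
            if ap.diff is not None and "log2fc" in ap.diff.index:
                direction = "up" if ap.diff["log2fc"] > 0 else "down"
            rows.append({"rsid": v.rsid, "peak_id": ap.interval.id,
                         "category": ap.category, "direction": direction})
    return pd.DataFrame(rows, columns=["rsid", "peak_id", "category", "direction"])


def set_memberships(sets: dict[str, set]) -> pd.DataFrame:
    """Counts for every non-empty region of the n-set partition (Venn input).

    Returns rows (members, count) where ``members`` is a "+"-joined sorted
    tuple of set labels; counts over all regions sum to the union size.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    labels = sorted(sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(*(sets[l] for l in labels if l not in combo)) if len(combo) < len(labels) else set()
            region = inside - outside
            if region:
                rows.append({"members": "+".join(combo), "count": len(region)})
    return pd.DataFrame(rows, columns=["members", "count"])
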