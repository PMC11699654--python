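"""Joint analysis of differential accessibility and differential expression.

Per condition, genes significant in both assays (FDR < 0.05 in RNA and in
at least one assigned ATAC peak) are joined to a single prioritized peak
(promoter peaks first, then largest |confect|). Confident effect sizes of
the chosen peaks and of the genes are z-scored across the joined gene
set, and their product is the *correlation score*: positive when
accessibility and expression deviate concordantly, negative when
discordantly. Separately, promoter, enhancer and expression z-scores per
gene feed Pareto non-dominated sorting in an up- and a down-orientation;
the resulting rankings drive CERNO enrichment, and category-direction
gene sets drive drug-target overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import RankedList, cerno_test
from .io_formats import DrugTargetNetwork, GeneSetCollection
from .peaks import AnnotatedPeak

logger = logging.getLogger("epinteg")


@dataclass
class IntegratedGeneRecord:
    """One gene of the DEG/DAR intersect with its chosen peak and scores."""

    gene_id: str
    chosen_peak_id: str
    chosen_peak_category: str
    confect_rna: float
    confect_atac: float
    z_rna: float = np.nan
    z_atac: float = np.nan
    corr_score: float = np.nan


# ---------------------------------------------------------------------------
# DEG/DAR intersect and peak prioritization
# ---------------------------------------------------------------------------


def intersect_deg_dar(rna_results: pd.DataFrame,
                      annotated_peaks: list[AnnotatedPeak],
                      threshold: float = 0.05) -> dict[str, list[AnnotatedPeak]]:
    """Genes significant in RNA with >= 1 significant assigned peak.

    A gene enters the map iff its RNA q < ``threshold`` and at least one
    promoter or enhancer peak assigned to it has ATAC q < ``threshold``.
    Distal peaks carry no gene and never contribute.
    """
    sig_genes = set(rna_results.index[rna_results["q"] < threshold])
    out: dict[str, list[AnnotatedPeak]] = {}
    for ap in annotated_peaks:
        if ap.category == "distal" or ap.diff is None:
            continue
        if not (ap.diff.get("q", 1.0) < threshold):
            continue
        for g in ap.genes:
            if g in sig_genes:
                out.setdefault(g, []).append(ap)
    return out


def prioritize_peaks(gene_peaks: dict[str, list[AnnotatedPeak]]) -> dict[str, AnnotatedPeak]:
    """Choose one peak per gene: promoters first, then max |confect|.

    Peaks whose confect is null are dropped first; genes left with no
    usable peak are excluded with a warning. Ties on |confect| break by
    peak id for determinism.
    """
    chosen: dict[str, AnnotatedPeak] = {}
    for gene, peaks in gene_peaks.items():
        usable = [p for p in peaks
                  if p.diff is not None and pd.notna(p.diff.get("confect", np.nan))]
        if not usable:
            logger.warning("gene %s: no peak with a non-null confect; excluded", gene)
            continue
        promoters = [p for p in usable if p.category == "promoter"]
        pool = promoters if promoters else [p for p in usable if p.category == "enhancer"]
        if not pool:
            logger.warning("gene %s: only distal peaks; excluded", gene)
            continue
        chosen[gene] = max(pool, key=lambda p: (abs(p.diff["confect"]), p.interval.id))
    return chosen


def correlation_scores(rna_results: pd.DataFrame,
                       chosen: dict[str, AnnotatedPeak]) -> pd.DataFrame:
    """z-score RNA and chosen-peak confects and multiply them.

    z-scoring uses the mean and (population) sd over the joined gene set;
    ``corr_score = z_rna * z_atac``. Requires >= 3 genes and non-zero
    spread in both confect vectors.
    """
    genes = sorted(chosen)
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes to z-score, got {len(genes)}")
    c_rna = np.array([rna_results.loc[g, "confect"] for g in genes], dtype=float)
    c_atac = np.array([chosen[g].diff["confect"] for g in genes], dtype=float)
    if np.isnan(c_rna).any():
        raise ValueError("null RNA confect inside the intersect")
    sd_rna, sd_atac = c_rna.std(), c_atac.std()
    if sd_rna == 0 or sd_atac == 0:
        raise ValueError("zero spread in confects; cannot z-score")
    z_rna = (c_rna - c_rna.mean()) / sd_rna
    z_atac = (c_atac - c_atac.mean()) / sd_atac
    return pd.DataFrame(
        {
            "gene_id": genes,
            "chosen_peak_id": [chosen[g].interval.id for g in genes],
            "chosen_peak_category": [chosen[g].category for g in genes],
            "confect_rna": c_rna,
            "confect_atac": c_atac,
            "peak_log2fc": [chosen[g].diff["log2fc"] for g in genes],
            "z_rna": z_rna,
            "z_atac": z_atac,
            "corr_score": z_rna * z_atac,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Pareto ranking
# ---------------------------------------------------------------------------


def _dominates(a: np.ndarray, b: np.ndarray, sign: float) -> bool:
    """Pair-wise domination on the objectives both points share.

    ``sign = +1`` maximizes, ``-1`` minimizes. NaN marks a missing
    objective; comparison is restricted to coordinates finite in both.
    """
    shared = ~(np.isnan(a) | np.isnan(b))
    if not shared.any():
        return False
    da, db = sign * a[shared], sign * b[shared]
    return bool(np.all(da >= db) and np.any(da > db))


def pareto_fronts(z: np.ndarray, orientation: str = "up") -> np.ndarray:
    """Non-dominated sorting front index (1-based) per row.

    ``orientation='up'`` treats larger objectives as better, ``'down'``
    smaller. Missing objectives (NaN) participate pair-wise: domination
    is decided on the objectives two points share.
    """
    if orientation not in ("up", "down"):
        raise ValueError("orientation must be 'up' or 'down'")
    sign = 1.0 if orientation == "up" else -1.0
    n = z.shape[0]
    dominated_by: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(z[i], z[j], sign):
                dominated_by[j].add(i)
            elif _dominates(z[j], z[i], sign):
                dominated_by[i].add(j)
    fronts = np.zeros(n, dtype=int)
    remaining = set(range(n))
    front = 1
    while remaining:
        # a point joins the current front when all its dominators are placed
        current = [j for j in remaining
                   if all(fronts[i] != 0 for i in dominated_by[j])]
        if not current:
            raise RuntimeError("non-dominated sorting failed to converge")
        for j in current:
            fronts[j] = front
            remaining.discard(j)
        front += 1
    return fronts


def pareto_rank(z_table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by Pareto fronts over (z_prom, z_enh, z_rna) objectives.

    ``z_table`` is indexed by gene with columns among ``z_prom``,
    ``z_enh``, ``z_rna`` (NaN = missing objective; each gene needs
    ``z_rna`` plus at least one accessibility objective). Returns the
    table with ``front_up``, ``front_down``, ``rank_up`` and
    ``rank_down`` columns; ranking within an orientation orders by
    (front, descending [ascending] objective sum, gene id).
    """
    cols = [c for c in ("z_prom", "z_enh", "z_rna") if c in z_table.columns]
    if "z_rna" not in cols:
        raise ValueError("z_table must contain z_rna")
    z = z_table[cols].to_numpy(dtype=float)
    has_rna = ~np.isnan(z[:, cols.index("z_rna")])
    acc_cols = [i for i, c in enumerate(cols) if c != "z_rna"]
    has_acc = ~np.all(np.isnan(z[:, acc_cols]), axis=1) if acc_cols else np.zeros(len(z), bool)
    complete = has_rna & has_acc
    if not complete.any():
        raise ValueError("no genes with z_rna and an accessibility objective")
    if (~complete).any():
        dropped = list(z_table.index[~complete])
        logger.warning("dropping %d gene(s) without complete objectives", len(dropped))
    sub = z_table.loc[complete, cols].copy()
    zz = sub.to_numpy(dtype=float)
    out = sub.copy()
    out["front_up"] = pareto_fronts(zz, "up")
    out["front_down"] = pareto_fronts(zz, "down")
    out["_s"] = np.nansum(zz, axis=1)

    def _ranking(front_col: str, sum_ascending: bool) -> pd.Series:
        order = out.reset_index().sort_values(
            [front_col, "_s", "gene_id"], ascending=[True, sum_ascending, True]
        )["gene_id"]
        return pd.Series(np.arange(1, len(out) + 1), index=order)

    out.index.name = "gene_id"
    out["rank_up"] = _ranking("front_up", sum_ascending=False)
    out["rank_down"] = _ranking("front_down", sum_ascending=True)
    return out.drop(columns="_s")


def build_z_table(rna_results: pd.DataFrame,
                  annotated_peaks: list[AnnotatedPeak],
                  objectives: int = 3) -> pd.DataFrame:
    """Per-gene promoter/enhancer/expression z-scores for Pareto ranking.

    For each gene, takes the largest-|log2fc| promoter peak and enhancer
    peak among its assigned peaks, z-scores the peak log2FCs (within
    category) and the gene log2FCs across the genes present, and returns
    columns ``z_prom``, ``z_enh``, ``z_rna``. ``objectives=2`` collapses
    promoter and enhancer into a single accessibility objective
    (promoter preferred).
    """
    prom: dict[str, float] = {}
    enh: dict[str, float] = {}
    for ap in annotated_peaks:
        if ap.diff is None or ap.category == "distal":
            continue
        lfc = float(ap.diff["log2fc"])
        store = prom if ap.category == "promoter" else enh
        for g in ap.genes:
            if g not in store or abs(lfc) > abs(store[g]):
                store[g] = lfc
    genes = sorted((set(prom) | set(enh)) & set(rna_results.index))
    if not genes:
        raise ValueError("no genes shared between peak assignments and RNA results")

    def _z(values: pd.Series) -> pd.Series:
        sd = values.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            return values * 0.0
        return (values - values.mean()) / sd

    z_prom = _z(pd.Series({g: prom[g] for g in genes if g in prom}))
    z_enh = _z(pd.Series({g: enh[g] for g in genes if g in enh}))
    z_rna = _z(pd.Series({g: float(rna_results.loc[g, "log2fc"]) for g in genes}))
    table = pd.DataFrame({"z_prom": z_prom, "z_enh": z_enh, "z_rna": z_rna},
                         index=pd.Index(genes, name="gene_id"))
    if objectives == 2:
        acc = table["z_prom"].where(table["z_prom"].notna(), table["z_enh"])
        table = pd.DataFrame({"z_prom": acc, "z_rna": table["z_rna"]}, index=table.index)
    elif objectives != 3:
        raise ValueError("objectives must be 2 or 3")
    return table


def integrate_and_enrich(ranked_table: pd.DataFrame, sets: GeneSetCollection,
                         min_size: int = 5) -> pd.DataFrame:
    """CERNO enrichment of the up- and down-oriented Pareto rankings.

    Returns the concatenated enrichment rows labelled by ``orientation``.
    """
    frames = []
    for orientation, col in (("up", "rank_up"), ("down", "rank_down")):
        order = ranked_table.sort_values(col)
        ranked = RankedList(list(order.index), -order[col].to_numpy(dtype=float))
        rows = cerno_test(ranked, sets, min_size=min_size)
        rows.insert(0, "orientation", orientation)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Drug-target overlap
# ---------------------------------------------------------------------------


def categorize_genes(records: pd.DataFrame) -> dict[str, set[str]]:
    """Split intersect genes by chosen-peak category and accessibility sign.

    Categories: promoter-up, promoter-down, enhancer-up, enhancer-down;
    the direction is the sign of the chosen peak's log2 accessibility
    change.
    """
    out: dict[str, set[str]] = {
        "promoter-up": set(), "promoter-down": set(),
        "enhancer-up": set(), "enhancer-down": set(),
    }
    for gene, row in records.iterrows():
        direction = "up" if row["peak_log2fc"] > 0 else "down"
        out[f"{row['chosen_peak_category']}-{direction}"].add(gene)
    return out


def drug_target_overlap(categories: dict[str, set[str]],
                        network: DrugTargetNetwork) -> pd.DataFrame:
    """Genes per category that are targets of >= 1 drug, with the drugs.

    Returns rows (category, gene_id, n_drugs, drugs) where ``drugs`` is a
    comma-joined sorted drug list; a gene appears once per category.
    """
    by_gene: dict[str, set[str]] = {}
    for d, g in network.edges:
        by_gene.setdefault(g, set()).add(d)
    rows = []
    for cat in sorted(categories):
        for gene in sorted(categories[cat]):
            drugs = by_gene.get(gene)
            if drugs:
                rows.append({"category": cat, "gene_id": gene,
                             "n_drugs": len(drugs), "drugs": ",".join(sorted(drugs))})
    return pd.DataFrame(rows, columns=["category", "gene_id", "n_drugs", "drugs"])
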