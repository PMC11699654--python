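"""DEG/DAR integration: intersect, prioritization, z-products, Pareto."""

import numpy as np
import pandas as pd
import pytest

from epinteg import (
    DrugTargetNetwork,
    GeneSetCollection,
    GenomicInterval,
    build_z_table,
    categorize_genes,
    correlation_scores,
    drug_target_overlap,
    integrate_and_enrich,
    intersect_deg_dar,
    pareto_fronts,
    pareto_rank,
    prioritize_peaks,
)
from epinteg.peaks import AnnotatedPeak


def _peak(peak_id, category, genes, q=0.01, confect=1.0, log2fc=None):
    iv = GenomicInterval("chr1", 0, 100, ".", peak_id)
    diff = pd.Series({"q": q, "confect": confect,
                      "log2fc": log2fc if log2fc is not None else confect})
    return AnnotatedPeak(iv, category, list(genes), diff)


def _rna(rows):
    """rows: {gene: (q, confect, log2fc)}"""
    df = pd.DataFrame(
        {g: {"q": v[0], "confect": v[1], "log2fc": v[2]} for g, v in rows.items()}
    ).T
    df.index.name = "feature_id"
    return df


class TestIntersect:
    def test_rna_only_gene_excluded(self):
        rna = _rna({"gA": (0.01, 1.0, 1.0)})
        peaks = [_peak("p1", "promoter", ["gA"], q=0.5)]
        assert intersect_deg_dar(rna, peaks) == {}

    def test_double_significant_gene_included_with_peak(self):
        rna = _rna({"gA": (0.01, 1.0, 1.0)})
        peaks = [_peak("p1", "promoter", ["gA"], q=0.02)]
        out = intersect_deg_dar(rna, peaks)
        assert list(out) == ["gA"] and out["gA"][0].interval.id == "p1"

    def test_distal_peaks_never_contribute(self):
        rna = _rna({"gA": (0.01, 1.0, 1.0)})
        iv = GenomicInterval("chr1", 0, 10, ".", "d1")
        distal = AnnotatedPeak(iv, "distal", [], pd.Series({"q": 0.001, "confect": 2.0}))
        assert intersect_deg_dar(rna, [distal]) == {}


class TestPrioritize:
    def test_promoter_beats_larger_enhancer_confect(self):
        peaks = {"gA": [_peak("prom", "promoter", ["gA"], confect=0.5),
                        _peak("enh", "enhancer", ["gA"], confect=2.0)]}
        assert prioritize_peaks(peaks)["gA"].interval.id == "prom"

    def test_abs_confect_decides_within_category(self):
        peaks = {"gA": [_peak("p1", "promoter", ["gA"], confect=0.5),
                        _peak("p2", "promoter", ["gA"], confect=-1.2)]}
        assert prioritize_peaks(peaks)["gA"].interval.id == "p2"

    def test_single_peak_identity(self):
        peaks = {"gA": [_peak("only", "enhancer", ["gA"], confect=0.3)]}
        assert prioritize_peaks(peaks)["gA"].interval.id == "only"

    def test_null_confect_peaks_dropped(self):
        peaks = {"gA": [_peak("p1", "promoter", ["gA"], confect=np.nan)]}
        assert prioritize_peaks(peaks) == {}


class TestCorrelationScores:
    def _records(self):
        rna = _rna({"g1": (0.01, 1.0, 1.0), "g2": (0.01, -1.0, -1.0),
                    "g3": (0.01, 2.0, 2.0), "g4": (0.01, 0.5, 0.5)})
        chosen = {g: _peak(f"p_{g}", "promoter", [g], confect=c)
                  for g, c in [("g1", 0.8), ("g2", -0.9), ("g3", 1.9), ("g4", 0.1)]}
        return rna, chosen

    def test_z_vectors_standardized_exactly(self):
        rna, chosen = self._records()
        rec = correlation_scores(rna, chosen)
        for col in ("z_rna", "z_atac"):
            assert abs(rec[col].mean()) < 1e-9
            assert abs(rec[col].std(ddof=0) - 1) < 1e-9
        assert np.allclose(rec["corr_score"], rec["z_rna"] * rec["z_atac"])

    def test_concordant_deviation_scores_positive(self):
        rna, chosen = self._records()
        rec = correlation_scores(rna, chosen)
        assert rec.loc["g3", "corr_score"] > 0  # high in both
        assert rec.loc["g2", "corr_score"] > 0  # low in both

    def test_too_few_genes_rejected(self):
        rna = _rna({"g1": (0.01, 1.0, 1.0), "g2": (0.01, -1.0, -1.0)})
        chosen = {g: _peak(f"p_{g}", "promoter", [g]) for g in ("g1", "g2")}
        with pytest.raises(ValueError, match=">= 3"):
            correlation_scores(rna, chosen)

    def test_zero_spread_rejected(self):
        rna = _rna({g: (0.01, 1.0, 1.0) for g in ("g1", "g2", "g3")})
        chosen = {g: _peak(f"p_{g}", "promoter", [g], confect=0.7)
                  for g in ("g1", "g2", "g3")}
        with pytest.raises(ValueError, match="zero spread"):
            correlation_scores(rna, chosen)


def _brute_force_fronts(z, maximize=True):
    """Independent O(n^2) peeling oracle on complete objective matrices."""
    zz = z if maximize else -z
    n = len(zz)
    fronts = np.zeros(n, dtype=int)
    remaining = list(range(n))
    front = 0
    while remaining:
        front += 1
        nondom = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if i == j:
                    continue
                if np.all(zz[j] >= zz[i]) and np.any(zz[j] > zz[i]):
                    dominated = True
                    break
            if not dominated:
                nondom.append(i)
        for i in nondom:
            fronts[i] = front
        remaining = [i for i in remaining if i not in nondom]
    return fronts


class TestPareto:
    def test_three_point_example(self):
        z = np.array([[2.0, 2.0], [1.0, 3.0], [0.0, 0.0]])
        assert pareto_fronts(z, "up").tolist() == [1, 1, 2]

    def test_identical_points_share_a_front(self):
        z = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert pareto_fronts(z, "up").tolist() == [1, 1, 1]

    def test_strict_chain_gives_sequential_fronts(self):
        z = np.array([[5.0, 5.0], [4.0, 4.0], [3.0, 3.0], [2.0, 2.0]])
        assert pareto_fronts(z, "up").tolist() == [1, 2, 3, 4]

    def test_matches_brute_force_on_random_instances(self):
        """Front assignment equals the O(n^2) oracle on random instances."""
        rng = np.random.default_rng(9)
        for trial in range(30):
            n = int(rng.integers(3, 60))
            d = int(rng.integers(2, 4))
            z = rng.normal(0, 1, size=(n, d))
            assert pareto_fronts(z, "up").tolist() == _brute_force_fronts(z).tolist()
            assert pareto_fronts(z, "down").tolist() == _brute_force_fronts(
                z, maximize=False).tolist()

    def test_orientation_symmetry_under_negation(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1, size=(40, 3))
        assert pareto_fronts(z, "up").tolist() == pareto_fronts(-z, "down").tolist()

    def test_missing_objectives_compared_pairwise(self):
        # gene 0 has no enhancer objective; domination uses shared columns
        z = np.array([[2.0, np.nan, 2.0], [1.0, 0.0, 1.0], [3.0, 1.0, 3.0]])
        fronts = pareto_fronts(z, "up")
        assert fronts[2] == 1  # dominates both on shared objectives
        assert fronts[0] == 2 and fronts[1] == 3


class TestParetoRank:
    def test_ranking_orders_by_front_then_sum(self):
        table = pd.DataFrame(
            {"z_prom": [2.0, 1.0, 0.0], "z_rna": [2.0, 3.0, 0.0]},
            index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        )
        out = pareto_rank(table)
        assert out.loc["gC", "front_up"] == 2
        assert out.loc["gA", "rank_up"] == 1  # front 1, larger sum
        assert out.loc["gC", "rank_down"] == 1

    def test_genes_without_accessibility_dropped(self):
        table = pd.DataFrame(
            {"z_prom": [1.0, np.nan, 0.5], "z_rna": [1.0, 2.0, 0.5]},
            index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        )
        out = pareto_rank(table)
        assert "gB" not in out.index and len(out) == 2

    def test_all_incomplete_rejected(self):
        table = pd.DataFrame({"z_prom": [np.nan], "z_rna": [1.0]},
                             index=pd.Index(["gA"], name="gene_id"))
        with pytest.raises(ValueError):
            pareto_rank(table)


class TestIntegrateAndEnrich:
    def test_front_planted_set_tops_the_up_ranking(self):
        rng = np.random.default_rng(11)
        n = 80
        genes = [f"g{i:03d}" for i in range(n)]
        z = rng.normal(0, 1, size=(n, 2))
        z[:10] += 4.0  # planted block dominates in the up orientation
        table = pd.DataFrame({"z_prom": z[:, 0], "z_rna": z[:, 1]},
                             index=pd.Index(genes, name="gene_id"))
        ranked = pareto_rank(table)
        sets = GeneSetCollection(sets={"PLANTED": genes[:10],
                                       "RANDOM": list(rng.choice(genes, 10, replace=False))})
        rows = integrate_and_enrich(ranked, sets)
        up = rows[rows["orientation"] == "up"].set_index("set")
        assert up.loc["PLANTED", "p"] < 1e-4
        assert up.loc["PLANTED", "p"] < up.loc["RANDOM", "p"]

    def test_empty_set_collection_gives_empty_output(self):
        table = pd.DataFrame({"z_prom": [1.0, 0.0, 2.0], "z_rna": [1.0, 0.0, 2.0]},
                             index=pd.Index(["a", "b", "c"], name="gene_id"))
        rows = integrate_and_enrich(pareto_rank(table), GeneSetCollection())
        assert rows.empty


class TestDrugOverlap:
    def _network(self, edges):
        drugs = sorted({d for d, _ in edges})
        meta = pd.DataFrame({"phase": ["1"] * len(drugs)},
                            index=pd.Index(drugs, name="drug_id"))
        return DrugTargetNetwork(edges=edges, drug_meta=meta)

    def test_intersection_semantics(self):
        cats = {"promoter-up": {"A", "B"}, "promoter-down": set(),
                "enhancer-up": set(), "enhancer-down": set()}
        net = self._network([("d1", "A"), ("d2", "C")])
        hits = drug_target_overlap(cats, net)
        assert len(hits) == 1
        assert hits.iloc[0]["gene_id"] == "A" and hits.iloc[0]["drugs"] == "d1"

    def test_multi_drug_gene_listed_once(self):
        cats = {"promoter-up": {"A"}, "promoter-down": set(),
                "enhancer-up": set(), "enhancer-down": set()}
        net = self._network([("d1", "A"), ("d2", "A"), ("d3", "A")])
        hits = drug_target_overlap(cats, net)
        assert len(hits) == 1 and hits.iloc[0]["n_drugs"] == 3

    def test_empty_network_empty_hits(self):
        cats = {"promoter-up": {"A"}, "promoter-down": set(),
                "enhancer-up": set(), "enhancer-down": set()}
        assert drug_target_overlap(cats, self._network([])).empty

    def test_categorize_uses_peak_direction(self):
        records = pd.DataFrame(
            {"chosen_peak_category": ["promoter", "enhancer"],
             "peak_log2fc": [1.5, -0.7]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        cats = categorize_genes(records)
        assert cats["promoter-up"] == {"gA"}
        assert cats["enhancer-down"] == {"gB"}
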