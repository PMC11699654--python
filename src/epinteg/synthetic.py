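"""Synthetic paired RNA/ATAC experiments with known ground truth.

The generator emulates a patient-derived neuron study design: one control
condition (NDC) plus three case conditions, three replicates each,
negative-binomial counts at both the gene (RNA) and peak (ATAC) level.
A configured fraction of genes is differentially expressed with a planted
log2 fold change; a configured fraction of those is *concordant*, meaning
the gene's promoter peak (and linked enhancer peak, if any) carries an
accessibility shift of the same sign and magnitude. Planted transcription
factors shift their target genes coherently. Every planted signal is
recorded in a :class:`GroundTruth` so downstream stages can be scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    VariantRecord,
    write_counts,
    write_gene_models_gtf,
    write_intervals_bed,
    write_sample_sheet,
    write_variants,
)

logger = logging.getLogger("epinteg")

# Two synthetic chromosomes; gene spacing 20 kb guarantees the >= 10 kb
# contract and leaves room for enhancer and distal peak templates.
_CHROMS = ("chrS1", "chrS2")
_CHROM_LEN = 250_000_000
_GENE_SPACING = 20_000


@dataclass
class SimulationConfig:
    """Parameters of the paired-experiment simulation.

    Defaults reproduce the emulated study design: a control plus three
    case conditions with three replicates each, moderate overdispersion,
    10% differentially expressed genes at |log2FC| = 2 and 80% chromatin
    concordance.
    """

    n_genes: int = 2000
    n_conditions: int = 4  # control + 3 cases
    n_replicates: int = 3
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.2
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_logfc: float = 2.0
    concordance: float = 0.8
    enhancer_fraction: float = 0.5
    distal_fraction: float = 0.25
    n_tfs: int = 20
    targets_per_tf: int = 15
    planted_tf_activity: float = 0.0
    n_variants_in_da: int = 20
    variant_high_p_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("de_fraction", "concordance", "enhancer_fraction",
                     "distal_fraction", "variant_high_p_fraction", "lib_size_cv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2 (control + cases)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @property
    def conditions(self) -> list[str]:
        return ["NDC"] + [f"FAD{i}" for i in range(1, self.n_conditions)]


@dataclass
class GroundTruth:
    """Planted-signal record of one simulated experiment.

    ``genes``: gene_id, is_de, is_concordant, true_log2fc (case vs control;
    identical across case conditions), tf (planting TF or "").
    ``peaks``: peak_id, category, gene_id, is_da, true_log2fc.
    ``tfs``: tf_id, activity_sign (0 when no activity planted).
    ``variants`` (set by :func:`simulate_variants`): rsid, in_da_peak.
    ``regulons``: the simulated TF regulon table (tf, target, mode_sign, weight).
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame
    tfs: pd.DataFrame
    regulons: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fixed spawn keys per component so streams stay independent
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


def simulate_gene_models(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[GeneModel], list[GenomicInterval], pd.DataFrame, list[GenomicInterval]]:
    """Lay out genes, promoter peak templates, enhancers and distal peaks.

    Genes alternate between two synthetic chromosomes at 20 kb spacing
    with alternating strands. Each gene receives one peak template
    centred on its TSS (always inside the promoter window); a configured
    fraction receives a linked distal enhancer 7 kb downstream of the TSS
    (>= 5 kb from every TSS); a pool of distal peaks 13 kb downstream
    overlaps nothing.

    Returns ``(gene_models, enhancer_intervals, link_table, peak_templates)``.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 0)
    n_per_chrom = (config.n_genes + 1) // 2
    if 10_000 + n_per_chrom * _GENE_SPACING > _CHROM_LEN:
        max_genes = 2 * ((_CHROM_LEN - 10_000) // _GENE_SPACING)
        raise ValueError(
            f"cannot place {config.n_genes} genes with >= 10 kb spacing; "
            f"request at most {max_genes}"
        )

    genes: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    links: list[tuple[str, str]] = []

    has_enh = rng.random(config.n_genes) < config.enhancer_fraction
    has_distal = rng.random(config.n_genes) < config.distal_fraction

    for i in range(config.n_genes):
        chrom = _CHROMS[i % 2]
        slot = i // 2
        tss = 10_000 + slot * _GENE_SPACING
        strand = "+" if (i // 2) % 2 == 0 else "-"
        gid = f"G{i:05d}"
        genes.append(GeneModel(gid, chrom, tss, strand))
        # promoter template peak, centred on the TSS
        peaks.append(GenomicInterval(chrom, tss - 250, tss + 250, ".", f"P_{gid}"))
        if has_enh[i]:
            eid = f"E_{gid}"
            enhancers.append(GenomicInterval(chrom, tss + 7000, tss + 7500, ".", eid))
            peaks.append(GenomicInterval(chrom, tss + 7050, tss + 7450, ".", f"PE_{gid}"))
            links.append((eid, gid))
        if has_distal[i]:
            peaks.append(
                GenomicInterval(chrom, tss + 13_000, tss + 13_500, ".", f"D_{gid}")
            )

    link_table = pd.DataFrame(links, columns=["enhancer_id", "gene_id"])
    return genes, enhancers, link_table, peaks


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _baseline_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    # log2-normal baseline (mean 5, sd 2 in log2) spanning the dynamic range
    q = np.exp2(rng.normal(5.0, 2.0, size=n))
    return q / q.sum()


def _library_sizes(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))


def simulate_paired_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Simulate RNA and ATAC count matrices with planted differentials.

    Counts are negative binomial with mean ``lib_s * q_g * 2**x_gc`` where
    ``x_gc`` is the planted condition effect: 0 in the control, +-de_logfc
    for DE genes in every case condition, plus coherent TF-driven shifts.
    Concordant DE genes carry the same shift on their promoter peak and on
    their linked enhancer peak.
    """
    genes, enhancers, link_table, peak_templates = simulate_gene_models(config)
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    conditions = config.conditions
    n_cases = len(conditions) - 1

    rng_plant = _rng(config.seed, 1)
    n_de = int(round(config.de_fraction * n_genes))
    if config.de_fraction > 0 and n_de < 1:
        warnings.warn("de_fraction * n_genes < 1; planting zero DE genes")
        n_de = 0
    de_idx = rng_plant.choice(n_genes, size=n_de, replace=False)
    de_sign = rng_plant.choice([-1.0, 1.0], size=n_de)
    concordant = rng_plant.random(n_de) < config.concordance

    gene_lfc = np.zeros(n_genes)
    gene_lfc[de_idx] = de_sign * config.de_logfc
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    is_conc = np.zeros(n_genes, dtype=bool)
    is_conc[de_idx[concordant]] = True

    # TF regulons over non-DE genes so planted activity is not confounded
    rng_tf = _rng(config.seed, 3)
    non_de = np.setdiff1d(np.arange(n_genes), de_idx)
    tf_rows: list[tuple[str, str, int, float]] = []
    tf_signs = np.zeros(config.n_tfs, dtype=int)
    tf_shift = np.zeros(n_genes)
    planting = config.planted_tf_activity != 0
    gene_tf = np.array([""] * n_genes, dtype=object)
    for t in range(config.n_tfs):
        k = min(config.targets_per_tf, len(non_de))
        targets = rng_tf.choice(non_de, size=k, replace=False)
        modes = rng_tf.choice([-1, 1], size=k)
        weights = rng_tf.uniform(0.5, 1.0, size=k)
        tf_id = f"TF{t:03d}"
        for g, m, w in zip(targets, modes, weights):
            tf_rows.append((tf_id, gene_ids[g], int(m), float(w)))
        if planting:
            s = int(rng_tf.choice([-1, 1]))
            tf_signs[t] = s
            tf_shift[targets] += s * modes * config.planted_tf_activity
            gene_tf[targets] = tf_id
    regulon_table = pd.DataFrame(tf_rows, columns=["tf", "target", "mode_sign", "weight"])

    gene_effect = gene_lfc + tf_shift  # identical in every case condition

    # peak-level planted shifts
    peak_ids = [p.id for p in peak_templates]
    peak_cat = []
    peak_gene = []
    peak_lfc = np.zeros(len(peak_templates))
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for j, p in enumerate(peak_templates):
        kind, gid = p.id.split("_", 1)
        cat = {"P": "promoter", "PE": "enhancer", "D": "distal"}[kind]
        peak_cat.append(cat)
        peak_gene.append(gid if cat != "distal" else "")
        gi = gene_pos[gid]
        if cat in ("promoter", "enhancer") and is_conc[gi]:
            peak_lfc[j] = gene_lfc[gi]

    sample_names = [f"{c}_r{r+1}" for c in conditions for r in range(config.n_replicates)]
    cond_of = {s: s.rsplit("_r", 1)[0] for s in sample_names}
    rep_of = {s: int(s.rsplit("_r", 1)[1]) for s in sample_names}
    cond_idx = np.array([conditions.index(cond_of[s]) for s in sample_names])

    def _counts(stream: int, n_feat: int, planted: np.ndarray) -> np.ndarray:
        rng = _rng(config.seed, stream)
        q = _baseline_abundance(rng, n_feat)
        libs = _library_sizes(rng, len(sample_names), config.lib_size_mean, config.lib_size_cv)
        # effect applies in every case condition, none in control
        effect = np.where(cond_idx[None, :] == 0, 0.0, planted[:, None])
        mu = libs[None, :] * q[:, None] * np.exp2(effect)
        return _nb_draw(rng, mu, config.nb_dispersion)

    rna = _counts(1_000, n_genes, gene_effect)
    atac = _counts(2_000, len(peak_templates), peak_lfc)

    def _matrix(values: np.ndarray, index: list[str]) -> CountMatrix:
        df = pd.DataFrame(values, index=index, columns=sample_names)
        return CountMatrix(df, dict(cond_of), dict(rep_of))

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_de": is_de,
                "is_concordant": is_conc,
                "true_log2fc": gene_lfc,
                "true_total_log2fc": gene_effect,  # includes TF-driven shifts
                "tf": gene_tf,
            }
        ),
        peaks=pd.DataFrame(
            {
                "peak_id": peak_ids,
                "category": peak_cat,
                "gene_id": peak_gene,
                "is_da": peak_lfc != 0,
                "true_log2fc": peak_lfc,
            }
        ),
        tfs=pd.DataFrame({"tf_id": [f"TF{t:03d}" for t in range(config.n_tfs)],
                          "activity_sign": tf_signs}),
        regulons=regulon_table,
    )
    # stash the genome layout for fixture writing
    truth.genes.attrs["n_cases"] = n_cases
    return _matrix(rna, gene_ids), _matrix(atac, peak_ids), truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def simulate_variants(
    config: SimulationConfig,
    truth: GroundTruth,
    peak_templates: list[GenomicInterval],
) -> list[VariantRecord]:
    """Place variants inside truth-DA peaks and an equal number outside.

    ``n_variants_in_da`` variants land at the midpoint of distinct DA
    peaks; the same number land in inter-peak gaps. A
    ``variant_high_p_fraction`` of each group receives assoc_p > 0.05 to
    exercise the association-p filter. Updates ``truth.variants``.
    """
    rng = _rng(config.seed, 4)
    da_ids = truth.peaks.loc[truth.peaks["is_da"], "peak_id"].tolist()
    by_id = {p.id: p for p in peak_templates}
    n_in = min(config.n_variants_in_da, len(da_ids))
    if n_in < config.n_variants_in_da:
        logger.warning("only %d DA peaks available for %d requested in-DAR variants",
                       len(da_ids), config.n_variants_in_da)
    chosen = rng.choice(len(da_ids), size=n_in, replace=False) if n_in else []
    records: list[VariantRecord] = []
    flags: list[bool] = []
    for k, idx in enumerate(chosen):
        p = by_id[da_ids[int(idx)]]
        pos = (p.start + p.end) // 2
        records.append(VariantRecord(f"rs{100000 + k}", p.chrom, pos, 0.0))
        flags.append(True)
    # outside: midway through the 20 kb gene slots, 15.75 kb after a TSS,
    # clear of promoter windows, enhancers and distal templates
    for k in range(n_in):
        chrom = _CHROMS[k % 2]
        pos = 10_000 + (k // 2) * _GENE_SPACING + 15_750
        records.append(VariantRecord(f"rs{200000 + k}", chrom, pos, 0.0))
        flags.append(False)
    n_total = len(records)
    high_p = rng.random(n_total) < config.variant_high_p_fraction
    out: list[VariantRecord] = []
    for rec, hp in zip(records, high_p):
        p_val = float(rng.uniform(0.06, 0.9)) if hp else float(rng.uniform(0.0, 0.05))
        out.append(VariantRecord(rec.rsid, rec.chrom, rec.pos, p_val))
    truth.variants = pd.DataFrame(
        {"rsid": [r.rsid for r in out], "in_da_peak": flags,
         "assoc_p": [r.assoc_p for r in out]}
    )
    return out


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------


def write_fixture_set(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a full experiment and write every input the pipeline reads.

    Returns a name -> path map of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, enhancers, link_table, peak_templates = simulate_gene_models(config)
    rna, atac, truth = simulate_paired_experiment(config)
    variants = simulate_variants(config, truth, peak_templates)

    paths = {
        "rna_counts": outdir / "rna_counts.tsv",
        "atac_counts": outdir / "atac_counts.tsv",
        "samples": outdir / "samples.tsv",
        "peaks_bed": outdir / "peaks.bed",
        "enhancers_bed": outdir / "enhancers.bed",
        "genes_gtf": outdir / "genes.gtf",
        "links": outdir / "enhancer_links.tsv",
        "regulons": outdir / "regulons.tsv",
        "variants": outdir / "variants.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "drug_targets": outdir / "drug_targets.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_peaks": outdir / "truth_peaks.tsv",
        "truth_tfs": outdir / "truth_tfs.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
    }
    write_counts(rna, paths["rna_counts"])
    write_counts(atac, paths["atac_counts"])
    write_sample_sheet(rna, paths["samples"])
    write_intervals_bed(peak_templates, paths["peaks_bed"])
    write_intervals_bed(enhancers, paths["enhancers_bed"])
    write_gene_models_gtf(genes, paths["genes_gtf"])
    link_table.to_csv(paths["links"], sep="\t", index=False)
    truth.regulons.to_csv(paths["regulons"], sep="\t", index=False)

    # gene sets: one per planted signal class plus random decoys
    rng = _rng(config.seed, 5)
    gene_ids = truth.genes["gene_id"].to_numpy()
    de_up = truth.genes.query("is_de and true_log2fc > 0")["gene_id"].tolist()
    de_down = truth.genes.query("is_de and true_log2fc < 0")["gene_id"].tolist()
    with open(paths["gene_sets"], "w") as fh:
        if len(de_up) >= 2:
            fh.write("\t".join(["PLANTED_UP", "planted upregulated genes", *de_up]) + "\n")
        if len(de_down) >= 2:
            fh.write("\t".join(["PLANTED_DOWN", "planted downregulated genes", *de_down]) + "\n")
        for k in range(10):
            members = rng.choice(gene_ids, size=min(20, len(gene_ids)), replace=False)
            fh.write("\t".join([f"RANDOM{k:02d}", "random decoy set", *members]) + "\n")

    # drug-target network: each synthetic drug targets a few random genes
    rows = []
    n_drugs = 30
    for d in range(n_drugs):
        targets = rng.choice(gene_ids, size=min(5, len(gene_ids)), replace=False)
        for g in targets:
            rows.append((f"DRUG{d:03d}", g, str(rng.integers(1, 4)), "synthetic"))
    pd.DataFrame(rows, columns=["drug_id", "gene_id", "phase", "class"]).drop_duplicates(
        subset=["drug_id", "gene_id"]
    ).to_csv(paths["drug_targets"], sep="\t", index=False)
    write_variants(variants, paths["variants"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
    truth.tfs.to_csv(paths["truth_tfs"], sep="\t", index=False)
    truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    return paths
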