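"""Transcription-factor activity scoring.

Three statistics:

* **Regulon activity (NES)** — a weighted, mode-signed sum of per-target
  signed gene scores, standardized so that independent N(0,1) target
  scores give a standard normal null: ``nes = sum(w*s*z) / sqrt(sum(w^2))``.
* **Directional motif z-score** — the magnitude of a motif activity
  z-score signed by the product of (a) the sign of the motif-target
  Pearson correlation and (b) the direction of the targets' expression
  change (sign of the mean target log2FC).
* **Activator/repressor classification** — the sign of the Pearson
  correlation between a TF's per-sample expression and the mean
  accessibility change over its motif-bearing peaks, with a minimum |r|
  threshold below which the mode stays undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("epinteg")


@dataclass
class Regulon:
    """A TF with its weighted, mode-signed target set."""

    tf_id: str
    targets: list[tuple[str, int, float]]  # (gene_id, mode_sign, weight)

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"regulon {self.tf_id}: empty target set")
        genes = [g for g, _, _ in self.targets]
        if len(set(genes)) != len(genes):
            raise ValueError(f"regulon {self.tf_id}: duplicate targets")
        if all(w == 0 for _, _, w in self.targets):
            raise ValueError(f"regulon {self.tf_id}: all weights zero")
        for _, s, w in self.targets:
            if s not in (-1, 1):
                raise ValueError(f"regulon {self.tf_id}: mode_sign must be +-1")
            if w < 0:
                raise ValueError(f"regulon {self.tf_id}: negative weight")


def regulons_from_table(table: pd.DataFrame) -> list[Regulon]:
    """Build Regulon objects from a (tf, target, mode_sign, weight) table."""
    out = []
    for tf_id, sub in table.groupby("tf", sort=True):
        targets = [(str(r.target), int(r.mode_sign), float(r.weight))
                   for r in sub.itertuples()]
        out.append(Regulon(str(tf_id), targets))
    return out


def regulon_activity(gene_scores: pd.Series, regulon: Regulon,
                     min_targets: int = 3) -> float | None:
    """Normalized enrichment score of one regulon over signed gene scores.

    ``nes = sum_i(w_i * s_i * z_i) / sqrt(sum_i(w_i^2))`` over the targets
    present in the score universe; under independent N(0,1) scores this
    is N(0,1). Returns None (with a warning) when fewer than
    ``min_targets`` targets are scored.
    """
    rows = [(s, w, gene_scores[g]) for g, s, w in regulon.targets if g in gene_scores.index]
    if len(rows) < min_targets:
        logger.warning("regulon %s: only %d usable targets (< %d); skipped",
                       regulon.tf_id, len(rows), min_targets)
        return None
    s = np.array([r[0] for r in rows], dtype=float)
    w = np.array([r[1] for r in rows], dtype=float)
    z = np.array([r[2] for r in rows], dtype=float)
    return float(np.sum(w * s * z) / np.sqrt(np.sum(w**2)))


def score_regulons(gene_scores: pd.Series, regulons: list[Regulon],
                   min_targets: int = 3) -> pd.DataFrame:
    """NES and nominal normal p for every regulon with enough targets."""
    rows = []
    universe = set(gene_scores.index)
    for reg in regulons:
        nes = regulon_activity(gene_scores, reg, min_targets)
        if nes is None:
            continue
        n_used = sum(1 for g, _, _ in reg.targets if g in universe)
        rows.append({"tf_id": reg.tf_id, "nes": nes,
                     "p": 2 * float(stats.norm.sf(abs(nes))), "n_targets": n_used})
    return pd.DataFrame(rows, columns=["tf_id", "nes", "p", "n_targets"])


def directional_zscore(motif_z: float, r: float, target_direction: int) -> float | None:
    """Sign a motif activity magnitude by correlation and target direction.

    ``directional_z = sign(r) * motif_z * d`` where ``motif_z >= 0`` is
    the motif's activity z magnitude, ``r`` the motif-target Pearson
    correlation, and ``d`` (+1/-1) the direction of the targets' mean
    expression change. r = 0 leaves the direction undetermined (None).
    """
    if motif_z < 0:
        raise ValueError("motif_z is a magnitude; must be >= 0")
    if target_direction not in (-1, 1):
        raise ValueError("target_direction must be -1 or +1")
    if r == 0:
        logger.warning("zero motif-target correlation; direction undetermined")
        return None
    return float(np.sign(r)) * motif_z * target_direction


def classify_tf_mode(tf_expression: np.ndarray,
                     target_accessibility_change: np.ndarray,
                     min_abs_r: float = 0.3) -> tuple[str, float]:
    """Classify a TF as activator or repressor from paired samples.

    Pearson-correlates the TF's per-sample expression with the mean
    accessibility change of its motif-bearing peaks over the same
    samples. ``r >= min_abs_r`` -> activator; ``r <= -min_abs_r`` ->
    repressor; otherwise undetermined. Returns ``(mode, r)``.
    """
    x = np.asarray(tf_expression, dtype=float)
    y = np.asarray(target_accessibility_change, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in TF expression or accessibility; undetermined")
        return "undetermined", np.nan
    r = float(stats.pearsonr(x, y).statistic)
    if r >= min_abs_r:
        return "activator", r
    if r <= -min_abs_r:
        return "repressor", r
    return "undetermined", r
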