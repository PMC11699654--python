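"""Rank- and set-based enrichment statistics.

Three tests:

* **CERNO** — a Fisher-style combination of relative ranks,
  ``S = -2 * sum(ln(R_g / N))`` over a gene set, referred to a chi-square
  with 2k degrees of freedom; the effect size is the rank AUC.
* **Hypergeometric over-representation** with an explicit background
  universe.
* **RRHO** — rank-rank hypergeometric overlap maps between two signed
  ranked lists, in the four-quadrant (up-up / down-down / up-down /
  down-up) construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io_formats import GeneSetCollection


@dataclass
class RankedList:
    """Features ordered strongest-first with the score that ranked them."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self):
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Rank by decreasing score, ties broken by id."""
        df = scores.rename("score").rename_axis("id").reset_index()
        df = df.sort_values(["score", "id"], ascending=[False, True])
        return cls(list(df["id"]), df["score"].to_numpy())

    @property
    def n(self) -> int:
        return len(self.ids)

    def ranks_of(self, members: list[str]) -> np.ndarray:
        """1-based ranks of the members present in the list."""
        pos = {g: i + 1 for i, g in enumerate(self.ids)}
        return np.array(sorted(pos[g] for g in members if g in pos))


# ---------------------------------------------------------------------------
# CERNO
# ---------------------------------------------------------------------------


def cerno_test(ranked: RankedList, sets: GeneSetCollection,
               min_size: int = 5) -> pd.DataFrame:
    """CERNO rank test of every gene set against one ranked list.

    Set members are intersected with the ranked universe; sets smaller
    than ``min_size`` after intersection are dropped. Per set:
    ``S = -2 * sum(ln(rank / N))``, p from chi-square with df = 2k, and
    AUC from the Mann-Whitney U of set against non-set ranks. q is BH
    over the tested sets.
    """
    if ranked.n == 0:
        raise ValueError("empty ranked universe")
    n = ranked.n
    rows = []
    for name, members in sets.items():
        r = ranked.ranks_of(members)
        k = r.size
        if k < min_size:
            continue
        s = -2.0 * np.sum(np.log(r / n))
        df = 2 * k
        p = float(stats.chi2.sf(s, df))
        if k < n:
            u = k * (n - k) + k * (k + 1) / 2.0 - r.sum()
            auc = u / (k * (n - k))
        else:
            auc = 0.5
        rows.append({"set": name, "k": k, "statistic": s, "df": df,
                     "p": p, "effect": auc})
    out = pd.DataFrame(rows, columns=["set", "k", "statistic", "df", "p", "effect"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------


def hypergeom_test(k: int, set_size: int, n_selected: int,
                   universe: int) -> tuple[float, float]:
    """One-sided over-representation test.

    ``k`` hits of a set of ``set_size`` within ``n_selected`` draws from a
    universe of ``universe`` genes. Returns ``(p, ratio)`` with
    ``p = P(X >= k)`` under Hypergeometric(universe, set_size,
    n_selected) and ``ratio = (k / n_selected) / (set_size / universe)``.
    """
    if not (0 <= k <= min(set_size, n_selected) <= universe):
        raise ValueError(
            f"inconsistent counts: k={k}, K={set_size}, n={n_selected}, N={universe}"
        )
    if set_size == 0 or n_selected == 0:
        raise ValueError("set and selection must be non-empty")
    p = float(stats.hypergeom.sf(k - 1, universe, set_size, n_selected))
    ratio = (k / n_selected) / (set_size / universe)
    return min(p, 1.0), ratio


def hypergeom_enrichment(selected: set[str], sets: GeneSetCollection,
                         background: set[str], min_size: int = 5) -> pd.DataFrame:
    """Hypergeometric test of every gene set against a selected gene list.

    Both the selection and the set members are intersected with the
    explicit ``background`` universe first.
    """
    sel = selected & background
    n_univ = len(background)
    if n_univ == 0:
        raise ValueError("empty background universe")
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        big_k = len(in_bg)
        if big_k < min_size:
            continue
        k = len(sel & in_bg)
        p, ratio = hypergeom_test(k, big_k, len(sel), n_univ) if sel else (1.0, 0.0)
        rows.append({"set": name, "k": big_k, "statistic": float(k), "df": np.nan,
                     "p": p, "effect": ratio})
    out = pd.DataFrame(rows, columns=["set", "k", "statistic", "df", "p", "effect"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# RRHO
# ---------------------------------------------------------------------------


def _quadrant_map(ids_a: list[str], ids_b: list[str], step: int) -> np.ndarray:
    """Signed -log10 hypergeometric map for one quadrant.

    ``ids_a`` / ``ids_b`` are the quadrant's features ordered by
    decreasing |score| in each list; the universe for the hypergeometric
    is their union. Entry (i, j) compares the top-(i+1)*step of A with the
    top-(j+1)*step of B; positive for over-representation of the overlap,
    negative for under-representation.
    """
    union = sorted(set(ids_a) | set(ids_b))
    n = len(union)
    if n == 0:
        return np.zeros((0, 0))
    thr_a = list(range(step, len(ids_a) + 1, step)) or [len(ids_a)]
    thr_b = list(range(step, len(ids_b) + 1, step)) or [len(ids_b)]
    out = np.zeros((len(thr_a), len(thr_b)))
    set_b_prefix: dict[int, set[str]] = {}
    for j, tb in enumerate(thr_b):
        set_b_prefix[j] = set(ids_b[:tb])
    for i, ta in enumerate(thr_a):
        top_a = set(ids_a[:ta])
        for j, tb in enumerate(thr_b):
            k = len(top_a & set_b_prefix[j])
            over = float(stats.hypergeom.sf(k - 1, n, ta, tb))
            under = float(stats.hypergeom.cdf(k, n, ta, tb))
            if over <= under:
                out[i, j] = -np.log10(max(over, 1e-300))
            else:
                out[i, j] = np.log10(max(under, 1e-300))
    return out


def rrho_map(list_a: RankedList, list_b: RankedList,
             step: int | None = None) -> dict[str, np.ndarray]:
    """Four-quadrant rank-rank hypergeometric overlap maps.

    Both lists must carry signed scores over the identical universe.
    Features are split by score sign in each list; within each of the
    quadrants ``up_up``, ``down_down``, ``up_down``, ``down_up`` the two
    sign classes are ordered by decreasing |score| and compared on a
    ``step`` grid of top-list thresholds (default ``max(1, N // 50)``).
    Map entries are signed -log10 hypergeometric p-values (+ over-, -
    under-representation).
    """
    if set(list_a.ids) != set(list_b.ids):
        diff = set(list_a.ids) ^ set(list_b.ids)
        raise ValueError(f"universes differ; symmetric difference: {sorted(diff)[:10]}")
    if step is None:
        step = max(1, list_a.n // 50)
    if step < 1:
        raise ValueError("step must be >= 1")

    def split(rl: RankedList) -> dict[str, list[str]]:
        up = [(i, s) for i, s in zip(rl.ids, rl.scores) if s >= 0]
        dn = [(i, s) for i, s in zip(rl.ids, rl.scores) if s < 0]
        return {
            "up": [i for i, _ in sorted(up, key=lambda t: (-abs(t[1]), t[0]))],
            "down": [i for i, _ in sorted(dn, key=lambda t: (-abs(t[1]), t[0]))],
        }

    a, b = split(list_a), split(list_b)
    return {
        "up_up": _quadrant_map(a["up"], b["up"], step),
        "down_down": _quadrant_map(a["down"], b["down"], step),
        "up_down": _quadrant_map(a["up"], b["down"], step),
        "down_up": _quadrant_map(a["down"], b["up"], step),
    }
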