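"""Chance-corrected agreement between classification methods.

Two binary (or Q-category) classifiers applied to the same subjects yield a
Q x Q contingency table.  Raw agreement p_o (the diagonal fraction) is
inflated by chance; both statistics here correct it as
(p_o - p_e) / (1 - p_e), differing in the chance term:

* Cohen's kappa: p_e = sum_q (row_q/n)(col_q/n) — the product of the two
  classifiers' marginals.  Kappa is notoriously sensitive to prevalence:
  when nearly everyone is positive, p_e approaches 1 and kappa collapses
  even at high raw agreement (the "kappa paradox").
* Gwet's AC1: p_e = (1/(Q-1)) sum_q pi_q (1 - pi_q) with pi_q the average
  of the two marginals.  At extreme prevalence pi_q(1-pi_q) is small, so
  AC1 stays close to the raw agreement.

Verbal interpretation uses the conventional Landis-Koch bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AgreementResult:
    statistic: str            # "kappa" or "AC1"
    estimate: float
    p_observed: float
    p_expected: float
    se: float
    ci_low: float
    ci_high: float
    band: str
    n: int


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if t.sum() < 2:
        raise ValueError("need at least 2 rated subjects")
    return t


def crosstab(labels_a, labels_b, categories=None) -> np.ndarray:
    """Q x Q contingency table of two per-subject label vectors."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    cat = list(categories)
    tab = np.zeros((len(cat), len(cat)))
    lookup = {c: i for i, c in enumerate(cat)}
    for x, y in zip(a, b):
        tab[lookup[x], lookup[y]] += 1
    return tab


def landis_koch_band(estimate: float) -> str:
    """Verbal agreement label: negative none, then slight/fair/moderate/
    substantial/almost perfect in steps of 0.2 (upper edges inclusive)."""
    if not -1.0 - 1e-12 <= estimate <= 1.0 + 1e-12:
        raise ValueError("agreement estimate must lie in [-1, 1]")
    if estimate < 0:
        return "no agreement"
    for upper, label in [(0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
                         (0.80, "substantial"), (1.00, "almost perfect")]:
        if estimate <= upper:
            return label
    return "almost perfect"


def _wald_ci(est: float, se: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.975)
    return max(est - z * se, -1.0), min(est + z * se, 1.0)


def cohens_kappa(table) -> AgreementResult:
    """Cohen's kappa with the standard asymptotic (Fleiss-Cohen-Everitt) SE
    and a Wald 95% CI clipped to [-1, 1]."""
    t = _as_table(table)
    n = t.sum()
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if 1.0 - p_e <= 0:
        raise ZeroDivisionError("degenerate marginals: p_e = 1, kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss, Cohen & Everitt (1969) large-sample variance
    a = sum(
        p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2
        for i in range(len(row))
    )
    b = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(len(row))
        for j in range(len(row))
        if i != j
    )
    c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (a + b - c) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = _wald_ci(kappa, se)
    return AgreementResult("kappa", float(kappa), p_o, p_e, se, lo, hi,
                           landis_koch_band(kappa), int(n))


def _ac1_point(t: np.ndarray):
    n = t.sum()
    p = t / n
    q = t.shape[0]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pi = (row + col) / 2.0
    p_o = float(np.trace(p))
    p_e = float(np.sum(pi * (1 - pi)) / (q - 1))
    if 1.0 - p_e <= 0:
        raise ZeroDivisionError("degenerate marginals: p_e = 1, AC1 undefined")
    return p_o, p_e, (p_o - p_e) / (1.0 - p_e), pi


def _ac1_closed_form_se(t: np.ndarray) -> float:
    """Gwet's two-rater conditional variance via the per-item linearization."""
    n = int(t.sum())
    q = t.shape[0]
    p_o, p_e, ac1, pi = _ac1_point(t)
    items = []
    for i in range(q):
        for j in range(q):
            cnt = int(round(t[i, j]))
            if cnt == 0:
                continue
            o_ij = 1.0 if i == j else 0.0
            pi_item = np.zeros(q)
            pi_item[i] += 0.5
            pi_item[j] += 0.5
            pe_item = float(np.sum(pi_item * (1 - pi)) / (q - 1))
            g_item = (o_ij - p_e) / (1 - p_e)
            g_star = g_item - 2 * (1 - ac1) * (pe_item - p_e) / (1 - p_e)
            items.append((g_star, cnt))
    vals = np.repeat([v for v, _ in items], [c for _, c in items])
    var = float(np.sum((vals - vals.mean()) ** 2)) / (n * (n - 1))
    return float(np.sqrt(max(var, 0.0)))


def _ac1_bootstrap_se(t: np.ndarray, n_boot: int, rng) -> float:
    n = int(t.sum())
    q = t.shape[0]
    flat = (t / n).ravel()
    ests = np.empty(n_boot)
    for b in range(n_boot):
        counts = rng.multinomial(n, flat).reshape(q, q)
        ests[b] = _ac1_point(counts.astype(float))[2]
    return float(ests.std(ddof=1))


def gwets_ac1(table, se_method: str = "closed_form", n_boot: int = 1000,
              seed=None) -> AgreementResult:
    """Gwet's AC1 with closed-form SE (default) or bootstrap fallback."""
    t = _as_table(table)
    p_o, p_e, ac1, _ = _ac1_point(t)
    if se_method == "closed_form":
        se = _ac1_closed_form_se(t)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        se = _ac1_bootstrap_se(t, n_boot, rng)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    lo, hi = _wald_ci(ac1, se)
    return AgreementResult("AC1", float(ac1), p_o, p_e, se, lo, hi,
                           landis_koch_band(ac1), int(t.sum()))


BINARY_METHOD_COLUMNS = ["method1", "method2_binary", "method3", "method4"]


def pairwise_agreement(matrix: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Kappa and AC1 with CIs for every pair of binary method calls.

    ``matrix`` is a classification matrix (one row per subject); the graded
    method enters through its merged binary column.  Returns one row per
    (pair, statistic) with estimate, CI bounds and Landis-Koch band.
    """
    columns = columns or BINARY_METHOD_COLUMNS
    if len(matrix) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for a, b in combinations(columns, 2):
        tab = crosstab(
            matrix[a].astype(int).to_numpy(),
            matrix[b].astype(int).to_numpy(),
            categories=[0, 1],
        )
        for res in (cohens_kappa(tab), gwets_ac1(tab)):
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "statistic": res.statistic,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "band": res.band,
                    "p_observed": res.p_observed,
                    "p_expected": res.p_expected,
                }
            )
    return pd.DataFrame(rows)
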