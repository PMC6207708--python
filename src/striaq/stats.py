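"""Group statistics: ROC discrimination, t-tests, method agreement, motor
regression, and paired-difference bias summaries.

Conventions follow the study design: controls are the positive (high-SUR)
class in ROC analyses, UPDRS-III is log-transformed before linear
regression on SUR, and the significance threshold is p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "SIGNIFICANCE_ALPHA",
    "ROCResult",
    "RegressionResult",
    "auc_mann_whitney",
    "welch_ttest",
    "welch_ttest_from_stats",
    "chi_square_2x2",
    "spearman",
    "fit_log_updrs",
    "fit_sigmoid",
    "paired_difference",
    "pathway_agreement",
]

#: study-wide significance threshold
SIGNIFICANCE_ALPHA = 0.01


@dataclass
class ROCResult:
    """Empirical ROC curve with its Mann-Whitney AUC.

    The curve starts at (0,0), ends at (1,1) and is monotone; its
    trapezoidal area equals the rank-based AUC (ties contribute half) to
    floating-point precision, which is asserted at construction.
    """

    auc: float
    curve: np.ndarray  # (n_points, 2) of (FPR, TPR)
    positive_class: str
    n_pos: int
    n_neg: int

    def __post_init__(self):
        c = np.asarray(self.curve, dtype=float)
        if not (np.allclose(c[0], [0, 0]) and np.allclose(c[-1], [1, 1])):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(c, axis=0) < -1e-12):
            raise ValueError("ROC curve must be monotone nondecreasing")
        area = float(np.trapezoid(c[:, 1], c[:, 0]))
        if abs(area - self.auc) > 1e-12:
            raise ValueError(f"curve area {area} inconsistent with AUC {self.auc}")


def auc_mann_whitney(pos_scores, neg_scores,
                     positive_class: str = "control") -> ROCResult:
    """Empirical AUC: fraction of (pos, neg) pairs with pos > neg, ties half.

    Computed from midranks (identical to exhaustive pair enumeration), with
    the ROC curve built by sweeping a threshold over the distinct scores.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.flatnonzero(np.diff(scores) != 0)
    idx = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(labels)[idx]
    fp = np.cumsum(1 - labels)[idx]
    curve = np.column_stack([
        np.concatenate([[0.0], fp / neg.size]),
        np.concatenate([[0.0], tp / pos.size]),
    ])
    return ROCResult(float(auc), curve, positive_class, pos.size, neg.size)


def welch_ttest(x, y, pooled: bool = False) -> dict:
    """Two-sided independent t-test; Welch by default, pooled by flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if pooled:
        t, p = sps.ttest_ind(x, y, equal_var=True)
        return {"t": float(t), "df": float(x.size + y.size - 2), "p": float(p)}
    return welch_ttest_from_stats(x.size, x.mean(), x.std(ddof=1),
                                  y.size, y.mean(), y.std(ddof=1))


def welch_ttest_from_stats(n1: int, mean1: float, sd1: float,
                           n2: int, mean2: float, sd2: float) -> dict:
    """Welch test from summary statistics (closed form)."""
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return {"t": 0.0, "df": float(n1 + n2 - 2), "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def chi_square_2x2(counts) -> dict:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    assert dof == 1
    return {"chi2": float(chi2), "p": float(p)}


def spearman(x, y) -> dict:
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


@dataclass
class RegressionResult:
    kind: str
    params: dict
    r_squared: float
    n: int

    def __post_init__(self):
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("R^2 outside [0, 1]")
        self.r_squared = float(np.clip(self.r_squared, 0.0, 1.0))
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


def fit_log_updrs(sur, updrs3) -> RegressionResult:
    """OLS of log-UPDRS-III on SUR; returns slope, intercept and R^2.

    Natural log of max(UPDRS-III, 1); the log base only rescales the slope.
    """
    sur = np.asarray(sur, dtype=float)
    u = np.asarray(updrs3, dtype=float)
    if sur.size != u.size or sur.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(sur) == 0:
        raise ValueError("degenerate predictor: SUR is constant")
    logu = np.log(np.maximum(u, 1.0))
    res = sps.linregress(sur, logu)
    return RegressionResult(
        "log_linear",
        {"slope": float(res.slope), "intercept": float(res.intercept),
         "p": float(res.pvalue)},
        float(res.rvalue ** 2), sur.size)


def _sigmoid(logu, L, k, x0):
    return L / (1.0 + np.exp(np.clip(k * (logu - x0), -500, 500)))


def fit_sigmoid(sur, updrs3) -> RegressionResult:
    """Least-squares sigmoid SUR = L / (1 + exp(k (log UPDRS-III - x0))).

    Bounded fits from a deterministic grid of starting points; reports the
    best solution's pseudo-R^2 (1 - SSres/SStot). With k > 0 the fitted SUR
    decreases with motor severity.
    """
    sur = np.asarray(sur, dtype=float)
    u = np.asarray(updrs3, dtype=float)
    if sur.size != u.size or sur.size < 5:
        raise ValueError("need paired samples with n >= 5")
    logu = np.log(np.maximum(u, 1.0))
    smax = sur.max()
    if smax <= 0:
        raise ValueError("sigmoid fit needs positive response values")
    lo, hi = [1e-6, -20.0, logu.min() - 5.0], [5.0 * smax + 1e-6, 20.0, logu.max() + 5.0]
    sst = float(((sur - sur.mean()) ** 2).sum())
    best = None
    mid = float(np.median(logu))
    for L0 in (smax, 1.5 * smax):
        for k0 in (-2.0, -0.5, 0.0, 0.5, 2.0):
            x0s = np.clip([mid], lo[2], hi[2])
            try:
                sol = optimize.least_squares(
                    lambda p: _sigmoid(logu, *p) - sur,
                    x0=[L0, k0, float(x0s[0])], bounds=(lo, hi),
                    method="trf", max_nfev=500)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("sigmoid fit failed from every starting point")
    ssr = float(2 * best.cost)
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return RegressionResult(
        "sigmoid",
        {"L": float(best.x[0]), "k": float(best.x[1]), "x0": float(best.x[2])},
        max(0.0, r2), sur.size)


_PAIR_KEYS = ["subject_id", "roi", "side_label", "phase"]


def paired_difference(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-row SUR difference (b - a) with the baseline (a) value.

    Tables must contain the same (subject, ROI, laterality, phase) rows;
    mismatches raise with the missing keys listed. The output supports
    bias-versus-level plots (difference against the reference method).
    """
    keys = [k for k in _PAIR_KEYS if k in table_a.columns and k in table_b.columns]
    if "subject_id" not in keys or "roi" not in keys:
        raise ValueError("tables need at least subject_id and roi columns")
    a = table_a[keys + ["sur"]].rename(columns={"sur": "baseline"})
    b = table_b[keys + ["sur"]].rename(columns={"sur": "sur_b"})
    merged = a.merge(b, on=keys, how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        missing = bad[keys].to_records(index=False).tolist()
        raise ValueError(f"mismatched rows between tables: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    out = merged.drop(columns="_merge")
    out["diff"] = out["sur_b"] - out["baseline"]
    return out.drop(columns="sur_b")


def pathway_agreement(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-(roi, side_label, phase) Spearman correlation between two methods."""
    d = paired_difference(table_a, table_b)
    d["method_b"] = d["baseline"] + d["diff"]
    group_cols = [c for c in ("roi", "side_label", "phase") if c in d.columns]
    rows = []
    for key, g in d.groupby(group_cols):
        res = spearman(g["baseline"], g["method_b"])
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_cols, key), rho=res["rho"], p=res["p"],
                         n=len(g)))
    return pd.DataFrame(rows)
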