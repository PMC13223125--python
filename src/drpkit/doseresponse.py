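"""4PL dose-response fitting and prediction-vs-experiment agreement.

Viability follows the four-parameter logistic model

    v(c) = B + (T - B) / (1 + (c / IC50)^h)

with the top asymptote fixed at T = 100 (vehicle-normalized percent
viability), bottom B constrained to [0, 100], IC50 in uM, and Hill slope
h (negative for inhibitory curves). Fits use nonlinear least squares
with multi-start over log-spaced IC50 initial values. Normalized AUC is
the trapezoid of v/100 over log10 concentration divided by the log-range
span: 1 is complete resistance, 0 full sensitivity.

The agreement analysis compares continuous model sensitivity scores with
measured IC50s: binary confusion metrics from both thresholds, Spearman
rank correlations (exact permutation p for small n), and a Mann-Whitney
U test of IC50 between predicted groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import four_pl

TOP = 100.0


@dataclass
class DoseResponseFit:
    ic50_uM: float
    hill: float
    bottom: float
    top: float = TOP
    r_squared: float = float("nan")
    normalized_auc: float = float("nan")
    converged: bool = True
    degenerate: bool = False
    replicate: Optional[int] = None


def fit_4pl(
    concentrations: Sequence[float],
    viability: Sequence[float],
    n_starts: int = 7,
) -> DoseResponseFit:
    """Fit the 4PL model (T fixed at 100, 0 <= B <= 100) by least squares.

    Requires >= 4 distinct concentrations. Multi-start over log-spaced
    IC50 initial values spanning the tested range; the best
    sum-of-squares fit wins. A flat response (zero variance) is returned
    flagged as degenerate: parameters are unidentifiable but the AUC path
    remains valid.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")

    auc = normalized_auc(c, v)
    if np.allclose(v, v[0]):
        return DoseResponseFit(
            ic50_uM=float("nan"), hill=float("nan"),
            bottom=float(np.clip(v[0], 0, 100)), r_squared=float("nan"),
            normalized_auc=auc, converged=False, degenerate=True,
        )

    def model(cc, log_ic50, hill, bottom):
        return four_pl(cc, 10.0**log_ic50, hill, bottom, top=TOP)

    bounds = ([np.log10(c.min()) - 3, -10.0, 0.0],
              [np.log10(c.max()) + 3, 10.0, 100.0])
    best = None
    for log_start in np.linspace(np.log10(c.min()), np.log10(c.max()), n_starts):
        try:
            popt, _ = optimize.curve_fit(
                model, c, v, p0=[log_start, -1.0, 0.0], bounds=bounds,
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = v - model(c, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return DoseResponseFit(
            ic50_uM=float("nan"), hill=float("nan"), bottom=float("nan"),
            r_squared=float("nan"), normalized_auc=auc, converged=False,
        )
    sse, (log_ic50, hill, bottom) = best
    sst = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return DoseResponseFit(
        ic50_uM=float(10.0**log_ic50), hill=float(hill), bottom=float(bottom),
        r_squared=r2, normalized_auc=auc,
    )


def normalized_auc(
    concentrations: Sequence[float], viability: Sequence[float]
) -> float:
    """Trapezoid of viability/100 over log10 c, scaled by the log10 span."""
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    order = np.argsort(c)
    c, v = c[order], v[order]
    if np.unique(c).size < 2:
        raise ValueError("AUC needs at least two distinct concentrations")
    x = np.log10(c)
    area = np.trapezoid(v / 100.0, x)
    return float(area / (x[-1] - x[0]))


# ---------------------------------------------------------------------------
# Agreement analysis
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float
    spearman_rho_ic50: float
    spearman_p_ic50: float
    spearman_rho_auc: Optional[float]
    spearman_p_auc: Optional[float]
    mannwhitney_u: float
    mannwhitney_p: float
    mean_ic50_predicted_sensitive: float
    mean_ic50_predicted_resistant: float
    undefined_metrics: list[str] = field(default_factory=list)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Standard confusion-derived rates; undefined ratios become NaN."""
    def ratio(num, den):
        return num / den if den else float("nan")

    total = tp + fp + tn + fn
    denom = math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "accuracy": ratio(tp + tn, total),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "mcc": (tp * tn - fp * fn) / denom if denom else float("nan"),
    }


def exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided permutation p-value for Spearman's rho (n <= 8)."""
    base = np.arange(1, n + 1, dtype=float)
    count = 0
    total = 0
    for perm in itertools.permutations(base):
        r = stats.pearsonr(base, np.array(perm)).statistic
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= 8 and not _has_ties(x) and not _has_ties(y):
        p = exact_spearman_p(rho, len(x))
    else:
        p = float(res.pvalue)
    return rho, p


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < len(x)


def agreement(
    scores: Sequence[float],
    ic50s: Sequence[float],
    aucs: Optional[Sequence[float]] = None,
    score_threshold: float = 0.5,
    ic50_threshold_uM: float = 1.0,
) -> AgreementReport:
    """Compare model sensitivity scores against measured IC50s.

    Predicted-sensitive means score above ``score_threshold``;
    experimentally sensitive means IC50 strictly below the threshold.
    U is reported as min(U1, U2) with an exact p for group sizes <= 10.
    Confusion metrics whose denominators vanish are NaN and listed in
    ``undefined_metrics``.
    """
    scores = np.asarray(scores, dtype=float)
    ic50s = np.asarray(ic50s, dtype=float)
    if scores.size != ic50s.size or scores.size < 3:
        raise ValueError("need aligned score/IC50 vectors with n >= 3")
    pred = scores > score_threshold
    actual = ic50s < ic50_threshold_uM
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    conf = confusion_metrics(tp, fp, tn, fn)
    undefined = [k for k, v in conf.items() if math.isnan(v)]

    rho_ic50, p_ic50 = _spearman(scores, ic50s)
    rho_auc = p_auc = None
    if aucs is not None:
        rho_auc, p_auc = _spearman(scores, np.asarray(aucs, dtype=float))

    g_sens = ic50s[pred]
    g_res = ic50s[~pred]
    if g_sens.size and g_res.size:
        n1, n2 = g_sens.size, g_res.size
        method = "exact" if max(n1, n2) <= 10 else "auto"
        res = stats.mannwhitneyu(g_sens, g_res, alternative="two-sided",
                                 method=method)
        u1 = float(res.statistic)
        u = min(u1, n1 * n2 - u1)
        u_p = float(res.pvalue)
    else:
        u, u_p = float("nan"), float("nan")
        undefined.append("mannwhitney_u")

    return AgreementReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        spearman_rho_ic50=rho_ic50, spearman_p_ic50=p_ic50,
        spearman_rho_auc=rho_auc, spearman_p_auc=p_auc,
        mannwhitney_u=u, mannwhitney_p=u_p,
        mean_ic50_predicted_sensitive=float(g_sens.mean()) if g_sens.size else float("nan"),
        mean_ic50_predicted_resistant=float(g_res.mean()) if g_res.size else float("nan"),
        undefined_metrics=undefined,
        **conf,
    )


def boundary_margin_pct(ic50_uM: float, threshold_uM: float = 1.0) -> float:
    """Relative distance of an IC50 from the labeling boundary, percent."""
    return 100.0 * abs(ic50_uM - threshold_uM) / threshold_uM
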