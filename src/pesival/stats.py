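"""Discrimination, calibration and descriptive statistics.

The validation stack mirrors the classical risk-score workflow:

* univariate logistic regression of in-hospital death on each score;
* AUROC with its Hanley–McNeil standard error,
  ``SE^2 = (A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)) / (n_pos n_neg)``
  with ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)``;
* paired comparison of two AUROCs measured on the same cases,
  ``z = (A1-A2)/sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2)``, where the
  correlation term ``r`` is looked up, by bilinear interpolation, from a
  grid indexed by the average between-score correlation and the average
  area.  The grid is computed from the binormal ROC model (both scores
  jointly Gaussian within each outcome group), the model underlying the
  classical published lookup table;
* calibration tables of observed vs model-predicted mortality by score
  deciles or by distinct score values;
* Wald binomial confidence intervals (the convention that reproduces
  the reference proportions; Wilson available as an option);
* two-group comparisons with the conventional test-selection rules
  (chi-square vs Fisher by expected cell counts; t-test vs
  Mann–Whitney U by a Shapiro–Wilk normality gate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit
from scipy.stats import rankdata


# --------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    n: int

    def predict(self, scores) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(scores, dtype=float))


def fit_logistic(scores: Sequence[float], died: Sequence[bool]) -> LogisticFit:
    """Maximum-likelihood univariate logistic fit of death on score.

    Complete separation (or non-convergence) is reported through
    ``converged=False`` rather than an exception; a single-class outcome
    or constant score raises ``ValueError``.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(died, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and died must be 1-d and equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if np.ptp(x) == 0:
        raise ValueError("score is constant; no information for a logistic fit")
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except Exception:  # perfect separation raises in statsmodels
            return LogisticFit(np.nan, np.nan, converged=False, n=len(x))
    intercept, slope = result.params
    converged = bool(result.mle_retvals.get("converged", False))
    if not np.isfinite([intercept, slope]).all() or abs(slope) > 1e6:
        converged = False
    return LogisticFit(float(intercept), float(slope), converged, len(x))


# --------------------------------------------------------------------------
# AUROC and the paired comparison

@dataclass
class AurocResult:
    auc: float
    se: float
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], died: Sequence[bool]) -> AurocResult:
    """Tie-corrected rank AUROC with its Hanley–McNeil standard error.

    The AUROC is the probability that a random non-survivor scores above
    a random survivor, ties counted half: (concordant + ties/2) /
    (n_pos * n_neg), computed via midranks.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(died, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(x)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return AurocResult(float(auc), float(np.sqrt(max(var, 0.0))), n_pos, n_neg)


# correlation between two paired AUROC estimates, on a grid of
# (average between-score correlation, average area); computed from the
# binormal ROC model and frozen here for bilinear interpolation
_R_AREAS = np.array([0.5, 0.525, 0.55, 0.575, 0.6, 0.625, 0.65, 0.675, 0.7,
                     0.725, 0.75, 0.775, 0.8, 0.825, 0.85, 0.875, 0.9, 0.925,
                     0.95, 0.975, 0.99])
_R_CORRS = np.array([-1.0, -0.9, -0.8, -0.7, -0.6, -0.5, -0.4, -0.3, -0.2,
                     -0.1, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
_R_GRID = np.array([
    [-1.0000, -0.9977, -0.9907, -0.9791, -0.9629, -0.9421, -0.9167, -0.8868, -0.8523, -0.8133, -0.7698, -0.7218, -0.6694, -0.6125, -0.5510, -0.4847, -0.4134, -0.3363, -0.2518, -0.1552, -0.0836],
    [-0.8915, -0.8896, -0.8840, -0.8748, -0.8618, -0.8450, -0.8245, -0.8002, -0.7721, -0.7400, -0.7040, -0.6639, -0.6197, -0.5710, -0.5178, -0.4595, -0.3957, -0.3254, -0.2464, -0.1537, -0.0834],
    [-0.7859, -0.7845, -0.7801, -0.7727, -0.7624, -0.7491, -0.7327, -0.7132, -0.6905, -0.6645, -0.6350, -0.6020, -0.5653, -0.5244, -0.4792, -0.4290, -0.3732, -0.3103, -0.2382, -0.1509, -0.0828],
    [-0.6829, -0.6818, -0.6783, -0.6726, -0.6645, -0.6540, -0.6411, -0.6257, -0.6077, -0.5869, -0.5633, -0.5366, -0.5067, -0.4731, -0.4355, -0.3932, -0.3455, -0.2908, -0.2265, -0.1463, -0.0815],
    [-0.5819, -0.5810, -0.5784, -0.5740, -0.5678, -0.5597, -0.5498, -0.5378, -0.5238, -0.5076, -0.4891, -0.4680, -0.4442, -0.4173, -0.3868, -0.3522, -0.3125, -0.2663, -0.2107, -0.1391, -0.0791],
    [-0.4826, -0.4819, -0.4800, -0.4767, -0.4720, -0.4660, -0.4585, -0.4495, -0.4390, -0.4267, -0.4126, -0.3965, -0.3781, -0.3572, -0.3334, -0.3060, -0.2742, -0.2365, -0.1902, -0.1287, -0.0751],
    [-0.3846, -0.3841, -0.3827, -0.3803, -0.3770, -0.3727, -0.3673, -0.3608, -0.3532, -0.3443, -0.3340, -0.3222, -0.3087, -0.2932, -0.2754, -0.2547, -0.2304, -0.2011, -0.1645, -0.1143, -0.0688],
    [-0.2876, -0.2873, -0.2863, -0.2847, -0.2825, -0.2796, -0.2760, -0.2716, -0.2664, -0.2604, -0.2534, -0.2453, -0.2360, -0.2253, -0.2129, -0.1984, -0.1811, -0.1600, -0.1331, -0.0951, -0.0591],
    [-0.1913, -0.1911, -0.1906, -0.1896, -0.1883, -0.1866, -0.1844, -0.1818, -0.1787, -0.1751, -0.1709, -0.1660, -0.1603, -0.1538, -0.1461, -0.1371, -0.1263, -0.1129, -0.0955, -0.0702, -0.0452],
    [-0.0955, -0.0955, -0.0952, -0.0948, -0.0942, -0.0934, -0.0925, -0.0913, -0.0899, -0.0883, -0.0864, -0.0842, -0.0816, -0.0787, -0.0752, -0.0710, -0.0659, -0.0596, -0.0512, -0.0388, -0.0260],
    [0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000, 0.0000],
    [0.0955, 0.0955, 0.0953, 0.0950, 0.0945, 0.0939, 0.0932, 0.0923, 0.0912, 0.0899, 0.0884, 0.0866, 0.0846, 0.0822, 0.0793, 0.0758, 0.0716, 0.0661, 0.0587, 0.0470, 0.0340],
    [0.1913, 0.1912, 0.1909, 0.1903, 0.1895, 0.1885, 0.1872, 0.1856, 0.1837, 0.1815, 0.1789, 0.1758, 0.1722, 0.1679, 0.1628, 0.1566, 0.1489, 0.1389, 0.1252, 0.1030, 0.0776],
    [0.2876, 0.2874, 0.2870, 0.2863, 0.2853, 0.2839, 0.2823, 0.2802, 0.2778, 0.2749, 0.2715, 0.2675, 0.2628, 0.2572, 0.2505, 0.2423, 0.2321, 0.2187, 0.1999, 0.1691, 0.1324],
    [0.3846, 0.3844, 0.3839, 0.3831, 0.3820, 0.3805, 0.3786, 0.3764, 0.3736, 0.3704, 0.3665, 0.3620, 0.3566, 0.3502, 0.3425, 0.3331, 0.3212, 0.3056, 0.2833, 0.2460, 0.2001],
    [0.4826, 0.4824, 0.4819, 0.4811, 0.4800, 0.4784, 0.4765, 0.4742, 0.4714, 0.4680, 0.4640, 0.4593, 0.4538, 0.4471, 0.4391, 0.4292, 0.4166, 0.4000, 0.3760, 0.3348, 0.2827],
    [0.5819, 0.5818, 0.5813, 0.5805, 0.5794, 0.5780, 0.5762, 0.5740, 0.5713, 0.5681, 0.5643, 0.5598, 0.5545, 0.5481, 0.5404, 0.5308, 0.5186, 0.5022, 0.4783, 0.4367, 0.3822],
    [0.6829, 0.6828, 0.6824, 0.6817, 0.6808, 0.6795, 0.6779, 0.6760, 0.6737, 0.6709, 0.6676, 0.6637, 0.6591, 0.6535, 0.6467, 0.6382, 0.6273, 0.6127, 0.5911, 0.5526, 0.5009],
    [0.7859, 0.7858, 0.7855, 0.7850, 0.7843, 0.7834, 0.7822, 0.7807, 0.7790, 0.7769, 0.7744, 0.7714, 0.7679, 0.7636, 0.7584, 0.7518, 0.7434, 0.7320, 0.7149, 0.6841, 0.6415],
    [0.8915, 0.8914, 0.8912, 0.8910, 0.8906, 0.8900, 0.8894, 0.8886, 0.8876, 0.8864, 0.8850, 0.8833, 0.8813, 0.8789, 0.8759, 0.8722, 0.8674, 0.8608, 0.8509, 0.8326, 0.8067],
    [1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000, 1.0000],
])


def auroc_correlation(avg_corr: float, avg_area: float) -> float:
    """Correlation ``r`` between two paired AUROC estimates, by bilinear
    interpolation on the binormal-model grid.

    ``avg_corr`` is the mean of the between-score correlations within
    non-survivors and within survivors; ``avg_area`` the mean of the two
    areas (reflected to >= 0.5 — the term is symmetric in A vs 1-A).
    """
    rho = float(np.clip(avg_corr, -1.0, 1.0))
    area = float(np.clip(max(avg_area, 1.0 - avg_area), _R_AREAS[0], _R_AREAS[-1]))
    i = int(np.clip(np.searchsorted(_R_CORRS, rho) - 1, 0, len(_R_CORRS) - 2))
    j = int(np.clip(np.searchsorted(_R_AREAS, area) - 1, 0, len(_R_AREAS) - 2))
    t = (rho - _R_CORRS[i]) / (_R_CORRS[i + 1] - _R_CORRS[i])
    u = (area - _R_AREAS[j]) / (_R_AREAS[j + 1] - _R_AREAS[j])
    g = _R_GRID
    return float(
        (1 - t) * (1 - u) * g[i, j]
        + t * (1 - u) * g[i + 1, j]
        + (1 - t) * u * g[i, j + 1]
        + t * u * g[i + 1, j + 1]
    )


@dataclass
class PairedAurocComparison:
    delta: float
    z: float
    p_value: float
    r: float


def compare_auroc_paired(
    a: AurocResult,
    b: AurocResult,
    score_corr_pos: float,
    score_corr_neg: float,
) -> PairedAurocComparison:
    """Two-sided z-test for a difference of AUROCs measured on the same
    cases, with the paired correlation term from the binormal grid.

    Antisymmetric in its two score arguments: swapping negates ``z`` and
    leaves ``p`` unchanged.  With ``r = 0`` it reduces to the unpaired
    two-sample z-test.
    """
    if (a.n_pos, a.n_neg) != (b.n_pos, b.n_neg):
        raise ValueError("paired comparison requires identical case groups")
    avg_corr = (score_corr_pos + score_corr_neg) / 2.0
    avg_area = (a.auc + b.auc) / 2.0
    r = auroc_correlation(avg_corr, avg_area)
    delta = a.auc - b.auc
    var = a.se**2 + b.se**2 - 2.0 * r * a.se * b.se
    if var <= 0:
        z = 0.0 if delta == 0 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return PairedAurocComparison(float(delta), float(z), p, r)


def paired_auroc_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    died: Sequence[bool],
    corr_method: str = "pearson",
) -> PairedAurocComparison:
    """Convenience wrapper: AUROCs plus within-outcome-group score
    correlations from the raw paired scores, then the z-test."""
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    y = np.asarray(died, dtype=bool)
    corr = {"pearson": sps.pearsonr, "kendall": sps.kendalltau}[corr_method]

    def _corr(mask):
        if mask.sum() < 2 or np.ptp(xa[mask]) == 0 or np.ptp(xb[mask]) == 0:
            return 0.0
        return float(corr(xa[mask], xb[mask])[0])

    return compare_auroc_paired(
        roc_auc(xa, y), roc_auc(xb, y), _corr(y), _corr(~y)
    )


# --------------------------------------------------------------------------
# calibration

@dataclass
class CalibrationBin:
    label: str
    n: int
    observed: float
    predicted: float


@dataclass
class CalibrationTable:
    bins: list[CalibrationBin]

    @property
    def total_n(self) -> int:
        return sum(b.n for b in self.bins)


def calibration_table(
    fit: LogisticFit,
    scores: Sequence[float],
    died: Sequence[bool],
    binning: str = "deciles",
) -> CalibrationTable:
    """Observed vs model-predicted mortality by score stratum.

    ``deciles`` bins by score quantiles (duplicate quantile edges are
    merged, so heavily tied scores yield fewer than ten bins, each score
    value staying in one bin); ``distinct-values`` bins by exact score
    value — the convention for the few-valued simplified scores.
    """
    if not fit.converged:
        raise ValueError("calibration requires a converged logistic fit")
    x = np.asarray(scores, dtype=float)
    y = np.asarray(died, dtype=float)
    predicted = fit.predict(x)
    frame = pd.DataFrame({"score": x, "died": y, "pred": predicted})
    if binning == "deciles":
        frame["bin"] = pd.qcut(frame["score"], 10, duplicates="drop")
    elif binning == "distinct-values":
        frame["bin"] = frame["score"]
    else:
        raise ValueError(f"unknown binning mode {binning!r}")
    bins = []
    for label, group in frame.groupby("bin", observed=True, sort=True):
        bins.append(
            CalibrationBin(
                label=str(label),
                n=int(len(group)),
                observed=float(group["died"].mean()),
                predicted=float(group["pred"].mean()),
            )
        )
    return CalibrationTable(bins)


# --------------------------------------------------------------------------
# proportions and group comparisons

def binomial_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Binomial proportion with its confidence interval.

    Wald by default — ``p ± z sqrt(p(1-p)/n)`` truncated to [0, 1] —
    which is the convention the reference proportions were printed
    under; ``method="wilson"`` gives the score interval.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    p = k / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    if method == "wald":
        half = z * np.sqrt(p * (1.0 - p) / n)
        return p, max(0.0, p - half), min(1.0, p + half)
    if method == "wilson":
        denom = 1.0 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        return p, max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    kind: str,
) -> GroupTestResult:
    """Two-group comparison with conventional test selection.

    ``categorical``: inputs are binary flags; chi-square on the 2x2
    table with the Yates continuity correction (the convention the
    reference group comparisons were computed under), switching to
    Fisher's exact test when any expected cell count is below 5.  ``continuous``: t-test
    when a Shapiro–Wilk test (alpha 0.05) does not reject normality in
    either group, Mann–Whitney U otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "categorical":
        table = np.array(
            [
                [np.sum(a == 1), np.sum(a == 0)],
                [np.sum(b == 1), np.sum(b == 0)],
            ],
            dtype=float,
        )
        expected = sps.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = sps.fisher_exact(table)
            return GroupTestResult("fisher", float("nan"), float(p))
        if table[:, 0].sum() in (0, table.sum()):
            # degenerate: flag constant across everyone
            return GroupTestResult("chi-square", 0.0, 1.0)
        stat, p, _, _ = sps.chi2_contingency(table, correction=True)
        return GroupTestResult("chi-square", float(stat), float(p))
    if kind == "continuous":
        normal = all(
            len(np.unique(g)) > 1 and sps.shapiro(g).pvalue > 0.05 for g in (a, b)
        )
        if normal:
            stat, p = sps.ttest_ind(a, b)
            return GroupTestResult("t-test", float(stat), float(p))
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupTestResult("mann-whitney", float(stat), float(p))
    raise ValueError(f"unknown comparison kind {kind!r}")
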