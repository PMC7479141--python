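"""Instrument-strength and pleiotropy diagnostics, directionality filtering,
and the model-selection logic that routes each analysis.

Covers the variance explained by a variant (with a liability-scale
transform for binary traits), the F-statistic F = R^2 (n - 2) / (1 - R^2)
with the conventional weak-instrument flag at F < 10, Steiger
directionality filtering, Cochran's Q / I^2 heterogeneity, the I^2_GX
statistic gauging regression dilution in MR-Egger, the Rucker
model-selection sequence (Q vs Q'), and the instrument-count router that
decides which estimators run for a given instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import _arrays, _ivw_core, _orient
from .summary_io import HarmonizedPair

__all__ = [
    "HeterogeneityResult",
    "RuckerDecision",
    "SteigerVerdict",
    "InstrumentStrength",
    "variant_r2",
    "liability_r2",
    "f_statistic",
    "steiger_filter",
    "cochran_q",
    "rucker_framework",
    "i2_gx",
    "route_analysis",
    "WEAK_F_THRESHOLD",
]

WEAK_F_THRESHOLD = 10.0


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    i_squared: float  # percent in [0, 100]


@dataclass
class RuckerDecision:
    """Model choice between IVW fixed, IVW random and MR-Egger.

    ``q_ivw`` is Cochran's Q about the IVW fit (df = k-1); ``q_rucker`` is
    the Egger residual heterogeneity Q' (df = k-2).  A significant Q - Q'
    (chi-square, 1 df, scaled by the residual overdispersion Q'/(k-2) when
    above 1) indicates unbalanced horizontal pleiotropy and favours Egger;
    otherwise a significant Q favours IVW random effects.
    """

    q_ivw: HeterogeneityResult
    q_rucker: HeterogeneityResult | None
    q_minus_qprime_p: float | None
    egger_intercept_p: float | None
    selected_model: str  # ivw_fixed | ivw_random | egger


@dataclass
class SteigerVerdict:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    direction: str  # exposure_to_outcome | outcome_to_exposure
    p_steiger: float
    keep: bool


@dataclass
class InstrumentStrength:
    r2: float
    f_stat: float
    n: int

    @property
    def weak_flag(self) -> bool:
        return self.f_stat < WEAK_F_THRESHOLD


def variant_r2(beta: float, se: float, maf: float, n: int) -> float:
    """Variance of a continuous trait explained by one variant.

    r2 = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se^2 * 2 n f(1-f)); the allele
    frequency cancels in this parametrization, so r2 depends only on the
    z-ratio beta/se and n — a documented property of the formula.
    """
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must lie in (0, 1), got {maf}")
    if n <= 2:
        raise ValueError("n must exceed 2")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    den = num + se**2 * 2.0 * n * maf * (1.0 - maf)
    if den == 0:
        return 0.0
    return num / den


def liability_r2(r2_observed: float, prevalence: float, case_fraction: float) -> float:
    """Transform an observed-scale R^2 for a binary trait to the liability scale.

    multiplier = K^2 (1-K)^2 / (z^2 P (1-P)) where K is the population
    prevalence, P the analyzed case fraction and z the standard-normal
    density at the threshold quantile Phi^{-1}(1-K).
    """
    K, P = prevalence, case_fraction
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("prevalence and case_fraction must lie strictly in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    multiplier = K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))
    return r2_observed * multiplier


def f_statistic(r2: float, n: int) -> InstrumentStrength:
    """Instrument strength F = R^2 (n - 2) / (1 - R^2); weak when F < 10."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    f = r2 * (n - 2) / (1.0 - r2)
    return InstrumentStrength(r2=r2, f_stat=f, n=n)


def steiger_filter(
    pair: HarmonizedPair, r2_x: float, n_x: int, r2_y: float, n_y: int,
    alpha: float = 0.05,
) -> SteigerVerdict:
    """Directionality verdict for one variant.

    The explained variances are converted to correlations and compared with
    a two-sample Fisher z-test (independent cohorts, so the SEs add).  The
    variant is dropped only when the outcome R^2 significantly exceeds the
    exposure R^2 (p < alpha), i.e. when reverse causation is the better
    explanation of the variant's associations.
    """
    r2_x = min(max(r2_x, 0.0), 1.0 - 1e-15)
    r2_y = min(max(r2_y, 0.0), 1.0 - 1e-15)
    z_x = np.arctanh(np.sqrt(r2_x))
    z_y = np.arctanh(np.sqrt(r2_y))
    se = np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    z = (z_x - z_y) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "exposure_to_outcome" if r2_x >= r2_y else "outcome_to_exposure"
    keep = not (direction == "outcome_to_exposure" and p < alpha)
    return SteigerVerdict(pair.variant_id, r2_x, r2_y, direction, p, keep)


def cochran_q(
    pairs: Sequence[HarmonizedPair], beta_hat: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q over per-variant ratio estimates about ``beta_hat``.

    Q = sum w_j (ratio_j - beta_hat)^2 with w_j = beta_x_j^2 / se_y_j^2;
    df = k - 1, p from the chi-square upper tail, and
    I^2 = max(0, (Q - df)/Q) * 100.  When ``beta_hat`` is omitted the IVW
    fixed-effects estimate is used (the usual definition).
    """
    if len(pairs) < 2:
        raise ValueError("cochran_q requires >= 2 instruments")
    bx, _, by, sy, _ = _arrays(pairs)
    if beta_hat is None:
        beta_hat, _, _ = _ivw_core(bx, by, sy)
    w = bx**2 / sy**2
    ratios = by / bx
    q = float(np.sum(w * (ratios - beta_hat) ** 2))
    df = len(pairs) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(Q=q, df=df, p=p, i_squared=i2)


def _egger_qprime(pairs: Sequence[HarmonizedPair]) -> tuple[float, float]:
    """(Q', egger intercept p) from the oriented weighted Egger fit."""
    from .estimators import egger

    slope, intercept = egger(pairs)
    bx, sx, by, sy = _orient(*_arrays(pairs)[:4])
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ by)
    resid = by - X @ coef
    return float(np.sum(w * resid**2)), intercept.p


def rucker_framework(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> RuckerDecision:
    """Model selection between IVW fixed/random and MR-Egger.

    Q p >= alpha selects IVW fixed effects; a significant Q with a
    non-significant Q - Q' (chi-square, 1 df) selects IVW random effects
    (at least balanced pleiotropy); a significant Q - Q' selects Egger
    (unbalanced pleiotropy).  With only two instruments Egger is not
    identifiable and the choice reduces to fixed vs random on Q alone.
    """
    if len(pairs) < 2:
        raise ValueError("rucker_framework requires >= 2 instruments")
    q_ivw = cochran_q(pairs)
    if len(pairs) < 3:
        model = "ivw_fixed" if q_ivw.p >= alpha else "ivw_random"
        return RuckerDecision(q_ivw, None, None, None, model)

    q_prime_val, intercept_p = _egger_qprime(pairs)
    df_prime = len(pairs) - 2
    q_rucker = HeterogeneityResult(
        Q=q_prime_val, df=df_prime, p=float(stats.chi2.sf(q_prime_val, df_prime)),
        i_squared=max(0.0, (q_prime_val - df_prime) / q_prime_val) * 100.0
        if q_prime_val > 0 else 0.0,
    )
    diff = max(0.0, q_ivw.Q - q_prime_val)  # intercept cannot increase weighted RSS
    # scale by the residual overdispersion so the 1-df test judges whether the
    # intercept explains heterogeneity beyond the random-effects level; the
    # unscaled difference rejects almost surely whenever balanced pleiotropy
    # inflates Q and Q' jointly
    diff_scaled = diff / max(1.0, q_prime_val / df_prime)
    q_diff_p = float(stats.chi2.sf(diff_scaled, 1))

    if q_ivw.p >= alpha:
        model = "ivw_fixed"
    elif q_diff_p >= alpha:
        model = "ivw_random"
    else:
        model = "egger"
    return RuckerDecision(q_ivw, q_rucker, q_diff_p, intercept_p, model)


def i2_gx(pairs: Sequence[HarmonizedPair]) -> float:
    """I^2_GX (percent): weak-instrument risk within MR-Egger.

    Q_GX = sum (beta_x_j - weighted mean)^2 / se_x_j^2 on orientation-
    standardized exposure betas with weights 1/se_x^2;
    I^2_GX = max(0, (Q_GX - (k-1)) / Q_GX) * 100.  Values well above 95%
    indicate low risk of regression dilution.  Pairs with se_x = 0 (e.g.
    the transformed pairs of the unweighted MR) are ineligible and excluded.
    """
    kept = [p for p in pairs if p.se_x > 0]
    if len(kept) < 2:
        raise ValueError("i2_gx requires >= 2 pairs with positive se_x")
    bx, sx, _, _ = _orient(*_arrays(kept)[:4])
    w = 1.0 / sx**2
    mean = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum((bx - mean) ** 2 / sx**2))
    if q_gx == 0:
        return 0.0
    return max(0.0, (q_gx - (len(kept) - 1)) / q_gx) * 100.0


def route_analysis(k: int) -> list[str]:
    """Analysis plan as a function of the instrument count.

    One instrument: Wald ratio, Steiger filtering and F-statistics only.
    Two: IVW fixed and random with Q / I^2 and the unweighted MR.  Three or
    more adds Egger, the Rucker framework, weighted median and mode,
    MR-Lasso and I^2_GX; four or more additionally enables MR-PRESSO.
    Pure in k so the routing table is exhaustively checkable.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return []
    if k == 1:
        return ["wald", "steiger", "f_statistic"]
    plan = ["ivw_fe", "ivw_re", "cochran_q", "i_squared", "unweighted"]
    if k >= 3:
        plan += ["egger", "rucker", "weighted_median", "weighted_mode",
                 "lasso", "i2_gx"]
    if k >= 4:
        plan.append("presso")
    return plan
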