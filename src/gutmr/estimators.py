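"""Two-sample Mendelian-randomization estimators on harmonized variant pairs.

Every estimator consumes :class:`~gutmr.summary_io.HarmonizedPair` objects,
i.e. allele-aligned quadruples (beta_x, se_x, beta_y, se_y), and returns an
:class:`MREstimate`.  The palette covers:

* Wald ratio (single instrument), first-order delta SE;
* inverse-variance weighted (IVW) fixed and multiplicative random effects,
  equivalent to a zero-intercept weighted regression of beta_y on beta_x
  with weights 1/se_y^2;
* MR-Egger: the same regression with a free intercept; the slope is the
  causal estimate, the intercept the average directional pleiotropy;
* weighted median and weighted mode, consistent when a majority
  (respectively plurality) of instruments is valid; bootstrap SEs;
* "unweighted" MR: exposure betas replaced by their sign (+/-1) and
  exposure SEs by zero, guarding against unit differences between source
  studies, with Cochran's Q recomputed on the transformed pairs;
* MR-Lasso: per-variant intercepts under an L1 penalty, with a
  heterogeneity stopping rule selecting the penalty, and post-selection
  IVW on the variants judged valid;
* MR-PRESSO: simulation-based global heterogeneity test, per-variant
  outlier test, distortion test and outlier-corrected IVW (requires >= 4
  instruments).

The random-effects flavour is multiplicative overdispersion with the scale
floored at 1, so a random-effects SE never undercuts the fixed-effects one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import HarmonizedPair

__all__ = [
    "MREstimate",
    "PressoResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "unweighted_mr",
    "mr_lasso",
    "mr_presso",
]

_MIN_K = {
    "wald": 1, "ivw_fe": 2, "ivw_re": 2, "egger_slope": 3, "egger_intercept": 3,
    "weighted_median": 3, "weighted_mode": 3, "unweighted_fe": 2,
    "unweighted_re": 2, "lasso": 3, "presso": 4,
}


@dataclass
class MREstimate:
    """A causal-effect estimate with its method tag and effects model."""

    method: str
    beta: float
    se: float
    p: float
    k_snps: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in _MIN_K:
            raise ValueError(f"unknown method {self.method!r}")
        if self.k_snps < _MIN_K[self.method]:
            raise ValueError(
                f"{self.method} requires >= {_MIN_K[self.method]} instruments, "
                f"got {self.k_snps}"
            )

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return (self.beta - half, self.beta + half)


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_p: float
    per_snp_outlier_p: dict[str, float]
    outlier_set: list[str]
    distortion_p: float | None
    corrected: MREstimate | None
    n_sim: int
    seed: int
    outlier_alpha: float = 0.05


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_x for p in pairs], dtype=float)
    sx = np.array([p.se_x for p in pairs], dtype=float)
    by = np.array([p.beta_y for p in pairs], dtype=float)
    sy = np.array([p.se_y for p in pairs], dtype=float)
    ids = [p.variant_id for p in pairs]
    return bx, sx, by, sy, ids


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate beta_y / beta_x.

    The SE is the first-order delta approximation se_y / |beta_x|, which
    ignores exposure-side uncertainty (standard for large exposure GWAS).
    """
    if pair.beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    beta = pair.beta_y / pair.beta_x
    se = pair.se_y / abs(pair.beta_x)
    return MREstimate("wald", beta, se, _normal_p(beta, se), 1,
                      notes=[pair.variant_id])


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Zero-intercept WLS of by on bx with weights 1/sy^2; returns (beta, fixed se, Q)."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all exposure betas are zero; IVW is degenerate")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(pairs: Sequence[HarmonizedPair], model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate over >= 2 instruments.

    ``model="random"`` applies multiplicative overdispersion: the fixed SE is
    scaled by max(1, sqrt(Q / (k - 1))), never shrinking below the fixed SE.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    if len(pairs) < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for one")
    bx, _, by, sy, _ = _arrays(pairs)
    beta, se, q = _ivw_core(bx, by, sy)
    method = "ivw_fe"
    if model == "random":
        se *= max(1.0, np.sqrt(q / (len(pairs) - 1)))
        method = "ivw_re"
    return MREstimate(method, beta, se, _normal_p(beta, se), len(pairs))


def _orient(bx, sx, by, sy):
    """Flip pairs so every exposure beta is non-negative (Egger preprocessing)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, sx, by * sign, sy


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression with a free intercept.

    Pairs are oriented so beta_x >= 0 first.  Returns (slope, intercept)
    estimates; the intercept's p-value below 0.05 indicates unbalanced
    horizontal pleiotropy.  SEs come from the weighted regression, inflated
    by max(1, sqrt(Q' / (k - 2))) (multiplicative random effects).
    """
    if len(pairs) < 3:
        raise ValueError("egger requires >= 3 instruments")
    bx, sx, by, sy = _orient(*_arrays(pairs)[:4])
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure betas equal after orientation; collinear")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    q_prime = float(np.sum(w * resid**2))
    k = len(pairs)
    scale = max(1.0, np.sqrt(q_prime / (k - 2)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov)) * scale
    slope = MREstimate("egger_slope", float(coef[1]), float(se_slope),
                       _normal_p(coef[1], se_slope), k)
    intercept = MREstimate("egger_intercept", float(coef[0]), float(se_int),
                           _normal_p(coef[0], se_int), k)
    return slope, intercept


def _ratios_weights(bx, by, sy):
    ratios = by / bx
    weights = bx**2 / sy**2
    return ratios, weights / weights.sum()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0  # midpoint cumulative sums
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, bx.size))
    by_star = rng.normal(by, sy, size=(n_boot, by.size))
    estimates = np.array([
        point_fn(bx_star[b], by_star[b]) for b in range(n_boot)
    ])
    return float(np.std(estimates, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonizedPair], n_boot: int = 5000, seed: int = 0
) -> MREstimate:
    """Weighted-median causal estimate, valid when > 50% of weight is valid.

    Per-variant ratio estimates are ordered and the estimate is the linear
    interpolation of the ordered ratios at cumulative standardized weight
    0.5 (midpoint cumulative sums), with weights beta_x^2 / se_y^2.  The SE
    is a seeded parametric bootstrap over (beta_x, beta_y).
    """
    if len(pairs) < 3:
        raise ValueError("weighted_median requires >= 3 instruments")
    bx, sx, by, sy, _ = _arrays(pairs)
    ratios, weights = _ratios_weights(bx, by, sy)
    beta = _weighted_median_point(ratios, weights)

    def point(bx_s, by_s):
        r, w = _ratios_weights(bx_s, by_s, sy)
        return _weighted_median_point(r, w)

    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _normal_p(beta, se), len(pairs))


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return factor * 0.9 * spread * len(ratios) ** (-0.2)


def _weighted_mode_point(ratios, weights, bandwidth_factor) -> float:
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    if h == 0 or not np.isfinite(h):
        return float(ratios[0])  # all ratios identical
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    pairs: Sequence[HarmonizedPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode causal estimate, valid when a plurality is valid.

    The estimate is the argmax over a 512-point grid of a normal-kernel
    weighted density of the ratio estimates; bandwidth follows the modified
    Silverman rule 0.9 * min(sd, IQR/1.349) * k^(-1/5) scaled by
    ``bandwidth_factor``.  Bootstrap SE as in :func:`weighted_median`.
    """
    if len(pairs) < 3:
        raise ValueError("weighted_mode requires >= 3 instruments")
    bx, sx, by, sy, _ = _arrays(pairs)
    ratios, weights = _ratios_weights(bx, by, sy)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)

    def point(bx_s, by_s):
        r, w = _ratios_weights(bx_s, by_s, sy)
        return _weighted_mode_point(r, w, bandwidth_factor)

    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return MREstimate("weighted_mode", beta, se, _normal_p(beta, se), len(pairs))


def unweighted_mr(
    pairs: Sequence[HarmonizedPair], model: str = "fixed"
) -> MREstimate:
    """IVW after replacing every exposure beta by its sign (+/-1, SE = 0).

    Equal weighting of the instruments guards against relative-abundance
    effect sizes carrying different implicit units across source studies.
    Cochran's Q is recomputed on the transformed pairs for the random-effects
    scale; pairs with beta_x = 0 cannot be signed and are excluded.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    kept = [p for p in pairs if p.beta_x != 0]
    if len(kept) < len(pairs):
        dropped = [p.variant_id for p in pairs if p.beta_x == 0]
    else:
        dropped = []
    if len(kept) < 2:
        raise ValueError("unweighted_mr requires >= 2 instruments with beta_x != 0")
    bx, _, by, sy, _ = _arrays(kept)
    signs = np.sign(bx)
    beta, se, q = _ivw_core(signs, by, sy)
    method = "unweighted_fe"
    if model == "random":
        se *= max(1.0, np.sqrt(q / (len(kept) - 1)))
        method = "unweighted_re"
    notes = [f"excluded (beta_x=0): {v}" for v in dropped]
    return MREstimate(method, beta, se, _normal_p(beta, se), len(kept), notes=notes)


def mr_lasso(
    pairs: Sequence[HarmonizedPair],
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
) -> MREstimate:
    """MR-Lasso: L1-penalized per-variant intercepts with post-selection IVW.

    The model is beta_y_j = theta * beta_x_j + alpha_j with weights
    1/se_y_j^2 and penalty lambda * sum |alpha_j|.  The grid runs from
    lambda_max (the smallest penalty zeroing every alpha) down to
    lambda_max * 1e-3 in ``n_lambda`` log-spaced steps.  Traversing from the
    largest penalty down, the first lambda whose valid set (alpha_j = 0,
    >= 2 variants) passes Cochran's Q at the 95% chi-square point is
    selected (heterogeneity stopping rule); the estimate is the IVW
    fixed-effects fit on that valid set.
    """
    if len(pairs) < 3:
        raise ValueError("mr_lasso requires >= 3 instruments")
    bx, _, by, sy, ids = _arrays(pairs)
    w = 1.0 / sy**2
    theta_ivw, _, _ = _ivw_core(bx, by, sy)
    lam_max = float(np.max(w * np.abs(by - theta_ivw * bx)))
    if lam_max == 0:
        est = ivw(pairs, model="fixed")
        return MREstimate("lasso", est.beta, est.se, est.p, len(pairs),
                          notes=["perfect fit; all instruments valid"])
    if lambda_grid is None:
        lambda_grid = np.geomspace(lam_max * 1.0001, lam_max * 1e-3, n_lambda)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    for lam in lambda_grid:
        alpha = np.zeros_like(bx)
        theta = theta_ivw
        for _ in range(500):
            resid = by - theta * bx
            alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - lam / w, 0.0)
            theta_new = float(np.sum(w * bx * (by - alpha_new)) / np.sum(w * bx**2))
            if np.max(np.abs(alpha_new - alpha)) < 1e-12 and abs(theta_new - theta) < 1e-12:
                alpha, theta = alpha_new, theta_new
                break
            alpha, theta = alpha_new, theta_new
        valid = np.abs(alpha) < 1e-9
        if valid.sum() < 2:
            continue
        bxv, byv, syv = bx[valid], by[valid], sy[valid]
        beta, se, q = _ivw_core(bxv, byv, syv)
        df = int(valid.sum()) - 1
        if q <= stats.chi2.ppf(0.95, df):
            excluded = [ids[j] for j in np.flatnonzero(~valid)]
            notes = [f"lambda={lam:.6g}"] + [f"invalid: {v}" for v in excluded]
            return MREstimate("lasso", beta, se, _normal_p(beta, se),
                              int(valid.sum()), notes=notes)
    raise ValueError(
        "mr_lasso: no penalty yields >= 2 valid instruments with acceptable "
        "heterogeneity"
    )


def mr_lasso_intercepts(
    pairs: Sequence[HarmonizedPair], lam: float
) -> np.ndarray:
    """Per-variant lasso intercepts at a fixed penalty (diagnostic helper)."""
    bx, _, by, sy, _ = _arrays(pairs)
    w = 1.0 / sy**2
    theta, _, _ = _ivw_core(bx, by, sy)
    alpha = np.zeros_like(bx)
    for _ in range(500):
        resid = by - theta * bx
        alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - lam / w, 0.0)
        theta_new = float(np.sum(w * bx * (by - alpha_new)) / np.sum(w * bx**2))
        if np.max(np.abs(alpha_new - alpha)) < 1e-12 and abs(theta_new - theta) < 1e-12:
            return alpha_new
        alpha, theta = alpha_new, theta_new
    return alpha


def _loo_estimates(bx, by, sy):
    """Leave-one-out IVW fixed-effects estimate for each instrument."""
    w = 1.0 / sy**2
    num, den = w * bx * by, w * bx**2
    tot_num, tot_den = num.sum(), den.sum()
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

    Global test: each instrument's squared residual about its leave-one-out
    IVW prediction is summed and compared to ``n_sim`` parametric
    simulations drawn at the leave-one-out fit (beta_x* ~ N(beta_x, se_x),
    beta_y* ~ N(theta_-j * beta_x, se_y)); the global p is the fraction of
    simulated RSS at least as large as observed.  Outlier test: each
    instrument's simulated residual distribution yields a per-variant p,
    Bonferroni-corrected over k.  Distortion test: the shift between the
    all-instrument and outlier-corrected estimates is compared to random
    removals of the same size.  Requires >= 4 instruments.
    """
    if len(pairs) < 4:
        raise ValueError("mr_presso requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy, ids = _arrays(pairs)
    k = len(pairs)

    theta_loo = _loo_estimates(bx, by, sy)
    obs_resid2 = (by - theta_loo * bx) ** 2
    obs_rss = float(obs_resid2.sum())

    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    w = 1.0 / sy**2
    num = w * bx_star * by_star
    den = w * bx_star**2
    theta_loo_star = (num.sum(axis=1, keepdims=True) - num) / \
                     (den.sum(axis=1, keepdims=True) - den)
    sim_resid2 = (by_star - theta_loo_star * bx_star) ** 2
    sim_rss = sim_resid2.sum(axis=1)

    global_p = float(np.mean(sim_rss >= obs_rss))
    per_snp_raw = np.mean(sim_resid2 >= obs_resid2[None, :], axis=0)
    per_snp_p = {ids[j]: float(per_snp_raw[j]) for j in range(k)}
    outliers = [ids[j] for j in range(k)
                if min(1.0, per_snp_raw[j] * k) < outlier_alpha]

    corrected = None
    distortion_p = None
    if outliers:
        keep = [p for p in pairs if p.variant_id not in outliers]
        theta_all, _, _ = _ivw_core(bx, by, sy)
        if len(keep) >= 2:
            base = ivw(keep, model="fixed")
            corrected = MREstimate(
                "presso", base.beta, base.se, base.p, k,
                notes=[f"outliers removed: {outliers}",
                       f"instruments retained: {len(keep)}"])
            obs_shift = abs(corrected.beta - theta_all)
        elif len(keep) == 1:
            beta = keep[0].beta_y / keep[0].beta_x
            se = keep[0].se_y / abs(keep[0].beta_x)
            corrected = MREstimate("presso", beta, se, _normal_p(beta, se), k,
                                   notes=[f"outliers removed: {outliers}",
                                          "single instrument remained"])
            obs_shift = abs(beta - theta_all)
        else:
            obs_shift = np.inf
        n_out = len(outliers)
        shifts = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(k, size=n_out, replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            if mask.sum() == 0:
                shifts[b] = np.inf
                continue
            theta_b, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
            shifts[b] = abs(theta_b - theta_all)
        distortion_p = float(np.mean(shifts >= obs_shift))

    return PressoResult(
        global_rss_p=global_p, per_snp_outlier_p=per_snp_p,
        outlier_set=outliers, distortion_p=distortion_p, corrected=corrected,
        n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha,
    )
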