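"""Phenome-wide association scan of dosage-coded variants against many outcomes.

Genotypes are coded 0/1/2 with 2 = the abundance-increasing allele.  Each
(variant, outcome) pair is fitted as ``outcome ~ dose + covariates`` —
ordinary least squares for continuous outcomes and logistic regression
(IRLS) for binary ones — with a two-sided Wald test on the dose coefficient
against the standard normal (the biobank-scale design the scan emulates
makes the normal reference appropriate; small-sample tests use the same
reference).  Binary outcomes with prevalence <= 1% are excluded up front,
and multiple testing is controlled by Bonferroni over the full
(variants x outcomes) grid.

The linear fits use a Frisch–Waugh–Lovell projection: covariates are
residualized out of the outcome and every dosage column once, after which
each per-variant fit is a simple regression.  This is algebraically
identical to the full OLS fit (coefficient, SE and p) and lets one scan
hundreds of variants without refitting the covariate block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScanConfig",
    "AssociationResult",
    "prevalence_filter",
    "scan",
    "sex_interaction_scan",
    "bonferroni_threshold",
    "results_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Scan settings: covariate adjustment, significance level, filters."""

    alpha: float = 0.05
    n_pcs: int = 30
    prevalence_floor: float = 0.01
    sex_col: str = "sex"
    max_iter: int = 50
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")


@dataclass
class AssociationResult:
    """Wald-test summary for one (variant, outcome) fit."""

    variant_id: str
    outcome_id: str
    outcome_type: str
    beta: float
    se: float
    p: float
    n: int
    n_cases: int | None = None
    converged: bool = True
    note: str = ""


def results_frame(results) -> pd.DataFrame:
    """Long-format scan output (variant, outcome, beta, se, p, n, ...)."""
    return pd.DataFrame(
        [{
            "variant_id": r.variant_id, "outcome_id": r.outcome_id,
            "outcome_type": r.outcome_type, "beta": r.beta, "se": r.se,
            "p": r.p, "n": r.n, "n_cases": r.n_cases,
            "converged": r.converged, "note": r.note,
        } for r in results]
    )


def bonferroni_threshold(n_snps: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / (n_snps * n_outcomes)."""
    if n_snps < 1 or n_outcomes < 1:
        raise ValueError("n_snps and n_outcomes must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (n_snps * n_outcomes)


def prevalence_filter(
    outcomes: pd.DataFrame, floor: float = 0.01
) -> list[str]:
    """Binary outcomes retained when the case fraction strictly exceeds ``floor``.

    The case fraction is computed among non-missing entries; all-missing
    outcomes are excluded with a log entry.  The default floor of 1% is
    inclusive on the exclusion side: a prevalence of exactly 1% is excluded.
    """
    retained = []
    for col in outcomes.columns:
        y = outcomes[col].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        if not mask.any():
            logger.info("prevalence_filter: %s is all-missing; excluded", col)
            continue
        prevalence = y[mask].mean()
        if prevalence > floor:
            retained.append(col)
    return retained


def _check_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Design block [1, covariates]; raises naming collinear columns."""
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column that does not raise the rank
        bad = []
        base = X[:, :1]
        for j, name in enumerate(covariates.columns):
            cand = np.column_stack([base, X[:, j + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return X


def _linear_scan_one_outcome(
    G: np.ndarray, y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-variant OLS of y on [dose, X] via the FWL projection."""
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
    resid = y_res[:, None] - G_res * beta
    df = len(y) - X.shape[1] - 1
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / gg)
    return beta, se, gg


def scan(
    genotypes: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: ScanConfig | None = None,
) -> list[AssociationResult]:
    """Fit outcome ~ dose + covariates for every (variant, outcome) pair.

    ``genotypes`` is samples x variants (dosages 0/1/2), ``outcomes`` samples
    x outcomes (binary outcomes coded 0/1; anything else is treated as
    continuous), ``covariates`` samples x covariates.  Missing data are
    handled complete-case per pair.  Monomorphic variants are flagged and
    carry no estimate; logistic non-convergence or separation is flagged but
    the result retained.
    """
    config = config or ScanConfig()
    if covariates is None:
        covariates = pd.DataFrame(index=genotypes.index)
    if not (len(genotypes) == len(outcomes) == len(covariates)):
        raise ValueError("genotypes, outcomes, covariates must be row-aligned")
    _check_covariates(covariates)

    results: list[AssociationResult] = []
    G_all = genotypes.to_numpy(dtype=float)
    C_all = covariates.to_numpy(dtype=float)

    for outcome_id in outcomes.columns:
        y_all = outcomes[outcome_id].to_numpy(dtype=float)
        observed = np.unique(y_all[~np.isnan(y_all)])
        binary = observed.size <= 2 and np.isin(observed, [0.0, 1.0]).all()
        outcome_type = "binary" if binary else "continuous"

        row_ok = ~np.isnan(y_all) & ~np.isnan(C_all).any(axis=1)
        complete_cols = ~np.isnan(G_all[row_ok]).any(axis=0)

        if binary or not complete_cols.all():
            # per-variant fits (complete-case masks differ or IRLS needed)
            for j, variant_id in enumerate(genotypes.columns):
                g = G_all[:, j]
                mask = row_ok & ~np.isnan(g)
                results.append(_fit_one(
                    variant_id, outcome_id, outcome_type,
                    g[mask], y_all[mask], C_all[mask], config,
                ))
        else:
            mask = row_ok
            G = G_all[mask]
            y = y_all[mask]
            X = np.column_stack([np.ones(mask.sum()), C_all[mask]])
            beta, se, gg = _linear_scan_one_outcome(G, y, X)
            var_g = G.var(axis=0)
            for j, variant_id in enumerate(genotypes.columns):
                if var_g[j] == 0:
                    results.append(AssociationResult(
                        variant_id, outcome_id, outcome_type,
                        np.nan, np.nan, np.nan, int(mask.sum()),
                        converged=False, note="monomorphic",
                    ))
                    continue
                z = beta[j] / se[j]
                p = 2.0 * stats.norm.sf(abs(z))
                results.append(AssociationResult(
                    variant_id, outcome_id, outcome_type,
                    float(beta[j]), float(se[j]), float(max(p, 5e-324)),
                    int(mask.sum()),
                ))
    return results


def _fit_one(
    variant_id: str,
    outcome_id: str,
    outcome_type: str,
    g: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    config: ScanConfig,
    interaction: np.ndarray | None = None,
) -> AssociationResult:
    n = len(y)
    n_cases = int(y.sum()) if outcome_type == "binary" else None
    if n == 0 or g.var() == 0:
        return AssociationResult(
            variant_id, outcome_id, outcome_type, np.nan, np.nan, np.nan,
            n, n_cases, converged=False, note="monomorphic" if n else "no data",
        )
    cols = [np.ones(n), g]
    if interaction is not None:
        cols.append(interaction)
    X = np.column_stack(cols + [C]) if C.size else np.column_stack(cols)
    target = 2 if interaction is not None else 1
    try:
        if outcome_type == "binary":
            model = sm.GLM(y, X, family=sm.families.Binomial())
            fit = model.fit(maxiter=config.max_iter, tol=config.tol)
            converged = bool(fit.converged) and np.isfinite(fit.bse[target]) \
                and fit.bse[target] < 1e3
            note = "" if converged else "non-convergence or separation"
        else:
            fit = sm.OLS(y, X).fit()
            converged, note = True, ""
    except Exception as exc:  # separation / singular design
        return AssociationResult(
            variant_id, outcome_id, outcome_type, np.nan, np.nan, np.nan,
            n, n_cases, converged=False, note=str(exc),
        )
    beta = float(fit.params[target])
    se = float(fit.bse[target])
    z = beta / se if se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return AssociationResult(
        variant_id, outcome_id, outcome_type, beta, se,
        max(p, 5e-324) if np.isfinite(p) else p, n, n_cases, converged, note,
    )


def sex_interaction_scan(
    genotypes: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    config: ScanConfig | None = None,
) -> list[AssociationResult]:
    """Wald test on the dose x sex interaction for every (variant, outcome).

    Sex stays in the model as a main effect; the reported coefficient, SE
    and p belong to the interaction term.  A single-sex sample (or a dose
    column constant within a sex stratum) is non-estimable and flagged.
    """
    config = config or ScanConfig()
    if config.sex_col not in covariates.columns:
        raise ValueError(f"covariates must contain a {config.sex_col!r} column")
    sex = covariates[config.sex_col].to_numpy(dtype=float)
    if np.unique(sex[~np.isnan(sex)]).size < 2:
        raise ValueError("single-sex sample: interaction is not estimable")

    other = covariates.to_numpy(dtype=float)
    G_all = genotypes.to_numpy(dtype=float)
    results: list[AssociationResult] = []
    for outcome_id in outcomes.columns:
        y_all = outcomes[outcome_id].to_numpy(dtype=float)
        observed = np.unique(y_all[~np.isnan(y_all)])
        binary = observed.size <= 2 and np.isin(observed, [0.0, 1.0]).all()
        outcome_type = "binary" if binary else "continuous"
        for j, variant_id in enumerate(genotypes.columns):
            g = G_all[:, j]
            mask = ~np.isnan(y_all) & ~np.isnan(g) & ~np.isnan(other).any(axis=1)
            gm, ym, sm_, Cm = g[mask], y_all[mask], sex[mask], other[mask]
            strata_var = [gm[sm_ == v].var() if (sm_ == v).any() else 0.0
                          for v in np.unique(sm_)]
            if any(v == 0 for v in strata_var):
                results.append(AssociationResult(
                    variant_id, outcome_id, outcome_type,
                    np.nan, np.nan, np.nan, int(mask.sum()),
                    converged=False, note="dose constant within a sex stratum",
                ))
                continue
            results.append(_fit_one(
                variant_id, outcome_id, outcome_type, gm, ym, Cm, config,
                interaction=gm * sm_,
            ))
    return results
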