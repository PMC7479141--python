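"""Synthetic cohorts with the statistical structure two-sample MR assumes.

The generator emulates the study design the pipeline targets: biallelic
genotypes at stated minor-allele frequencies, a latent continuous
"relative abundance" exposure driven by instrument effects plus shared
confounding, continuous and liability-threshold binary outcomes with a
configurable causal effect, balanced or directional horizontal pleiotropy,
weak instruments, winner's curse and reverse causation — split into
non-overlapping exposure and outcome samples.  Every draw is deterministic
given the root seed, which expands to per-purpose child streams (genotypes,
noise, pleiotropy) so adding one component does not perturb the others.

The exposure is modelled as a single continuous latent trait per taxon, not
a compositional community: the estimators consume per-taxon summary
statistics in relative-abundance units, so the scalar latent trait is the
minimal faithful structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import scan as scan_mod
from .summary_io import InstrumentRecord, OutcomeStat

__all__ = [
    "ScenarioConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "to_two_sample",
    "scenario_presets",
    "synthetic_instrument_table",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class ScenarioConfig:
    """Generating truth for one two-sample scenario."""

    n_exposure_sample: int = 20_000
    n_outcome_sample: int = 20_000
    m_instruments: int = 25
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_range: tuple[float, float] = (0.1, 0.4)  # instrument effect sizes
    causal_effect: float = 0.3
    pleiotropy: str = "none"  # none | balanced | directional | correlated
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outcome_type: str = "continuous"  # continuous | binary
    prevalence: float = 0.1
    reverse_causation: bool = False
    exposure_noise_sd: float = 1.0
    confounder_effect: float = 0.3
    n_confounders: int = 2
    include_age_sex: bool = True
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.m_instruments <= 0:
            raise ValueError("m_instruments must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        if self.pleiotropy not in ("none", "balanced", "directional", "correlated"):
            raise ValueError(f"unknown pleiotropy kind {self.pleiotropy!r}")
        if self.outcome_type == "binary" and not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1) for binary outcomes")


@dataclass
class SyntheticCohort:
    """Individual-level data plus the generating truth, for recovery testing."""

    genotypes: pd.DataFrame          # samples x variants, dosages 0/1/2
    exposure: pd.Series              # latent relative abundance
    outcome: pd.Series
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.exposure)


def _draw_shared(config: ScenarioConfig):
    """Parameters shared by the exposure and outcome cohorts (same seed)."""
    rng = np.random.default_rng(config.seed)
    maf = rng.uniform(*config.maf_range, size=config.m_instruments)
    gamma = rng.uniform(*config.gamma_range, size=config.m_instruments)
    if config.pleiotropy == "none":
        alpha = np.zeros(config.m_instruments)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy != "balanced" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, size=config.m_instruments)
        if config.pleiotropy == "correlated":
            # violate InSIDE: pleiotropy proportional to instrument strength
            alpha = alpha + 0.5 * config.pleiotropy_mean * (gamma - gamma.mean())
    return maf, gamma, alpha


def simulate_cohort(config: ScenarioConfig, sample: str = "exposure") -> SyntheticCohort:
    """Generate one cohort (the ``"exposure"`` or ``"outcome"`` sample).

    Genotypes are i.i.d. Binomial(2, maf); the exposure is
    X = sum_j gamma_j G_j + confounder load + N(0, sd^2); the continuous
    outcome is Y = theta X + sum_j alpha_j G_j + confounder load + N(0, 1).
    Binary outcomes threshold the continuous liability at the empirical
    quantile matching the configured prevalence.  With
    ``reverse_causation`` the instruments act on the outcome and the
    exposure is downstream (Y = sum_j gamma_j G_j + noise; X = theta Y +
    noise), so the variants' exposure associations are entirely mediated by
    the outcome.  The two samples use disjoint child seeds of the same
    root, sharing maf/gamma/alpha but no individuals.
    """
    if sample not in ("exposure", "outcome"):
        raise ValueError("sample must be 'exposure' or 'outcome'")
    maf, gamma, alpha = _draw_shared(config)
    n = config.n_exposure_sample if sample == "exposure" else config.n_outcome_sample
    offset = 1 if sample == "exposure" else 2
    child = np.random.default_rng([config.seed, offset])
    rng_geno = np.random.default_rng(child.integers(2**31))
    rng_noise = np.random.default_rng(child.integers(2**31))
    rng_cov = np.random.default_rng(child.integers(2**31))

    G = rng_geno.binomial(2, maf, size=(n, config.m_instruments)).astype(float)
    variant_ids = [f"rs{100000 + j}" for j in range(config.m_instruments)]
    prefix = "E" if sample == "exposure" else "O"
    index = pd.Index([f"{prefix}{i:06d}" for i in range(n)], name="sample_id")
    genotypes = pd.DataFrame(G, columns=variant_ids, index=index)

    cov_cols = {}
    conf_load_x = np.zeros(n)
    conf_load_y = np.zeros(n)
    if config.include_age_sex:
        cov_cols["age"] = rng_cov.uniform(40, 70, size=n)
        cov_cols["sex"] = rng_cov.integers(0, 2, size=n).astype(float)
    for c in range(config.n_confounders):
        u = rng_cov.normal(size=n)
        cov_cols[f"pc{c + 1}"] = u
        conf_load_x = conf_load_x + config.confounder_effect * u
        conf_load_y = conf_load_y + config.confounder_effect * u
    covariates = pd.DataFrame(cov_cols, index=index)

    theta = config.causal_effect
    if config.reverse_causation:
        liability = G @ gamma + conf_load_y + rng_noise.normal(size=n)
        exposure = theta * liability + conf_load_x + \
            rng_noise.normal(scale=config.exposure_noise_sd, size=n)
    else:
        exposure = G @ gamma + conf_load_x + \
            rng_noise.normal(scale=config.exposure_noise_sd, size=n)
        liability = theta * exposure + G @ alpha + conf_load_y + \
            rng_noise.normal(size=n)

    if config.outcome_type == "binary":
        cut = np.quantile(liability, 1.0 - config.prevalence)
        outcome = (liability > cut).astype(float)
    else:
        outcome = liability

    truth = {
        "theta": theta, "gamma": gamma, "alpha": alpha, "maf": maf,
        "seed": config.seed, "sample": sample, "config": config,
    }
    return SyntheticCohort(
        genotypes=genotypes,
        exposure=pd.Series(exposure, index=index, name="exposure"),
        outcome=pd.Series(outcome, index=index, name="outcome"),
        covariates=covariates,
        truth=truth,
    )


def _variant_metadata(config: ScenarioConfig, maf: np.ndarray):
    """Deterministic synthetic chromosome/position/allele/taxonomy labels."""
    rng = np.random.default_rng([config.seed, 99])
    m = config.m_instruments
    chromosomes = [str(1 + j % 22) for j in range(m)]
    # far apart so synthetic variants never fall in one clumping window
    positions = [1_000_000 + 10_000_000 * (j // 22) for j in range(m)]
    alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(m)]
    families = [f"Family{chr(65 + j % 5)}" for j in range(m)]
    genera = [f"Genus{chr(65 + j % 10)}" for j in range(m)]
    return chromosomes, positions, alleles, families, genera


def to_two_sample(
    exposure_cohort: SyntheticCohort,
    outcome_cohort: SyntheticCohort,
    significance_threshold: float | None = None,
    study: str = "synthetic",
) -> tuple[list[InstrumentRecord], list[OutcomeStat]]:
    """Summarize a cohort pair into instrument and outcome tables.

    Runs the association scan of genotypes against the exposure in sample 1
    (yielding instrument records with synthetic taxonomy labels) and against
    the outcome in sample 2 (yielding outcome statistics).  Passing
    ``significance_threshold`` applies the genome-wide inclusion filter to
    the instrument side.  The two cohorts must not share sample identifiers.
    """
    overlap = exposure_cohort.genotypes.index.intersection(outcome_cohort.genotypes.index)
    if len(overlap):
        raise ValueError(f"two-sample design violated: {len(overlap)} shared samples")
    config: ScenarioConfig = exposure_cohort.truth["config"]
    maf = exposure_cohort.truth["maf"]
    chroms, positions, alleles, families, genera = _variant_metadata(config, maf)

    exp_results = scan_mod.scan(
        exposure_cohort.genotypes, exposure_cohort.exposure.to_frame(),
    )
    out_results = scan_mod.scan(
        outcome_cohort.genotypes, outcome_cohort.outcome.to_frame(),
    )

    eaf = exposure_cohort.genotypes.mean(axis=0).to_numpy() / 2.0
    instruments: list[InstrumentRecord] = []
    for j, res in enumerate(exp_results):
        if not res.converged:
            continue
        rec = InstrumentRecord(
            variant_id=res.variant_id, chromosome=chroms[j], position=positions[j],
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(eaf[j]), beta_exposure=res.beta, se_exposure=res.se,
            p_exposure=res.p, n_exposure=res.n,
            taxon_family=families[j], taxon_genus=genera[j],
            effect_unit="relative_abundance", study=study,
        )
        instruments.append(rec)
    if significance_threshold is not None:
        instruments = [r for r in instruments if r.p_exposure < significance_threshold]

    out_eaf = outcome_cohort.genotypes.mean(axis=0).to_numpy() / 2.0
    outcome_stats: list[OutcomeStat] = []
    for j, res in enumerate(out_results):
        if not res.converged:
            continue
        outcome_stats.append(OutcomeStat(
            variant_id=res.variant_id,
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(out_eaf[j]), beta_outcome=res.beta, se_outcome=res.se,
            p_outcome=res.p, n_outcome=res.n, n_cases=res.n_cases,
            outcome_type=res.outcome_type, outcome_id="outcome",
        ))
    return instruments, outcome_stats


def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named generating scenarios exercising each failure mode of interest.

    * ``valid_instruments`` — all MR assumptions hold under the
      strong-instrument idealization the estimators' validity conditions
      require (F well above 10, exposure betas precise relative to their
      spread); every estimator should recover the causal effect.  The
      instruments are the designed set: no in-sample significance
      selection, which is the ``winners_curse`` scenario's failure mode.
    * ``balanced_pleiotropy`` — zero-mean per-variant direct effects:
      heterogeneity without bias (random-effects territory).
    * ``directional_pleiotropy`` — nonzero-mean direct effects: IVW biased
      in the planted direction, the Egger intercept picks it up.
    * ``weak_instruments`` — small instrument effects in a small discovery
      sample (F near 10).
    * ``winners_curse`` — instrument effects estimated in the same sample
      used to select them, inflating the exposure betas and attenuating
      two-sample estimates toward the null.
    * ``reverse_causation`` — the outcome drives the exposure; Steiger
      filtering should remove most instruments.
    """
    base = dict(n_exposure_sample=20_000, n_outcome_sample=20_000,
                m_instruments=25, causal_effect=0.3,
                gamma_range=(0.15, 0.9))
    return {
        "valid_instruments": ScenarioConfig(**base, name="valid_instruments"),
        "balanced_pleiotropy": ScenarioConfig(
            **base, pleiotropy="balanced", pleiotropy_sd=0.1,
            name="balanced_pleiotropy"),
        "directional_pleiotropy": ScenarioConfig(
            **base, pleiotropy="directional", pleiotropy_mean=0.1,
            pleiotropy_sd=0.05, name="directional_pleiotropy"),
        "weak_instruments": ScenarioConfig(
            n_exposure_sample=2_000, n_outcome_sample=20_000, m_instruments=25,
            causal_effect=0.3, gamma_range=(0.02, 0.06), name="weak_instruments"),
        "winners_curse": ScenarioConfig(
            n_exposure_sample=5_000, n_outcome_sample=20_000, m_instruments=25,
            causal_effect=0.3, gamma_range=(0.09, 0.15), name="winners_curse"),
        "reverse_causation": ScenarioConfig(
            **base, reverse_causation=True, name="reverse_causation"),
    }


def synthetic_instrument_table(
    n_variants: int = 180,
    n_relative_abundance: int = 169,
    seed: int = 0,
    n_studies: int = 6,
) -> list[InstrumentRecord]:
    """A synthetic harvest table mirroring a multi-study instrument pool.

    Generates ``n_variants`` records across ``n_studies`` source studies,
    exactly ``n_relative_abundance`` of which carry relative-abundance
    effect units (the remainder absolute abundance), with genome-wide
    significant p-values and mixed-depth taxonomy.  Synthetic stand-in for
    a published instrument harvest; no real variants are represented.
    """
    if n_relative_abundance > n_variants:
        raise ValueError("n_relative_abundance cannot exceed n_variants")
    rng = np.random.default_rng(seed)
    units = np.array(["relative_abundance"] * n_relative_abundance +
                     ["abundance"] * (n_variants - n_relative_abundance))
    rng.shuffle(units)
    records = []
    for j in range(n_variants):
        maf = float(rng.uniform(0.05, 0.5))
        beta = float(rng.normal(0, 0.5))
        beta = beta if abs(beta) > 0.05 else 0.25
        n = int(rng.integers(500, 3000))
        p = float(10 ** rng.uniform(-30, np.log10(4.9e-8)))
        depth = rng.integers(1, 4)
        family = f"Family{chr(65 + j % 8)}"
        genus = f"Genus{chr(65 + j % 16)}" if depth >= 2 else None
        species = f"species_{j % 24}" if depth == 3 else None
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        records.append(InstrumentRecord(
            variant_id=f"rs{200000 + j}", chromosome=str(1 + j % 22),
            position=int(1_000_000 + 50_000 * j), effect_allele=ea,
            other_allele=oa, eaf=maf, beta_exposure=beta,
            se_exposure=abs(beta) / 6.0, p_exposure=p, n_exposure=n,
            taxon_family=family, taxon_genus=genus, taxon_species=species,
            effect_unit=str(units[j]), study=f"study_{j % n_studies}",
        ))
    return records
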