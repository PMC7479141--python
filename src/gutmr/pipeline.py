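"""End-to-end orchestration: scan -> instrument selection -> harmonization ->
Steiger filtering -> routed MR -> diagnostics -> conditional GRS.

A run consumes either summary-statistic tables or a named synthetic
scenario, executes every stage with per-stage in/out counts, and writes
plain tab-separated reports plus a machine-readable manifest (JSON with
SHA-256 checksums) into the output directory.  MR results are tiered as
``bonferroni_significant`` (p below 0.05 over the number of followed-up
analyses), ``suggestive`` (p < 0.05 but above that Bonferroni bar) or
``null``.  The exit status of a run reflects validation only, never the
scientific outcome.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from . import grs as grs_mod
from . import instruments as instr
from . import simulate as sim
from . import summary_io as sio

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized into the run's provenance."""

    output_dir: str = "gutmr_run"
    # input: either a synthetic preset or explicit tables
    preset: str | None = "valid_instruments"
    instrument_table: str | None = None
    outcome_table: str | None = None
    ld_table: str | None = None
    # thresholds
    significance_threshold: float = instr.GENOME_WIDE_P
    mr_alpha: float = 0.05
    steiger_alpha: float = 0.05
    intercept_alpha: float = 0.05
    clump_r2: float = instr.CLUMP_R2
    clump_window_bp: int = instr.CLUMP_WINDOW_BP
    palindromic_eaf_window: float = sio.PALINDROMIC_EAF_WINDOW
    pooling_levels: tuple[str, ...] = ("family", "genus")
    steiger_enabled: bool = True
    run_grs: bool = True
    exempt_studies: tuple[str, ...] = ()
    # randomness
    seed: int = 0
    n_boot: int = 1000
    n_sim_presso: int = 1000

    def __post_init__(self) -> None:
        for name in ("mr_alpha", "steiger_alpha", "intercept_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.preset is None and (self.instrument_table is None
                                    or self.outcome_table is None):
            raise ValueError("either a preset or both input tables are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pooling_levels" in raw:
            raw["pooling_levels"] = tuple(raw["pooling_levels"])
        if "exempt_studies" in raw:
            raw["exempt_studies"] = tuple(raw["exempt_studies"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pooling_levels"] = list(self.pooling_levels)
        d["exempt_studies"] = list(self.exempt_studies)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _steiger_stage(pairs, instruments_by_id, outcome_by_id, alpha):
    kept, verdict_rows = [], []
    for pair in pairs:
        rec = instruments_by_id[pair.variant_id]
        out = outcome_by_id[pair.variant_id]
        maf = rec.eaf if rec.eaf is not None else 0.5
        maf = min(max(maf, 1e-6), 1 - 1e-6)
        if maf > 0.5:
            maf = 1.0 - maf
        r2_x = diag.variant_r2(rec.beta_exposure, rec.se_or_reconstructed(),
                               maf, rec.n_exposure)
        o_maf = out.eaf if out.eaf is not None else maf
        o_maf = min(max(o_maf, 1e-6), 1 - 1e-6)
        if o_maf > 0.5:
            o_maf = 1.0 - o_maf
        r2_y = diag.variant_r2(out.beta_outcome, out.se_outcome, o_maf,
                               out.n_outcome)
        if out.outcome_type == "binary" and out.n_cases:
            case_fraction = out.n_cases / out.n_outcome
            r2_y = diag.liability_r2(r2_y, case_fraction, case_fraction)
        v = diag.steiger_filter(pair, r2_x, rec.n_exposure, r2_y,
                                out.n_outcome, alpha=alpha)
        verdict_rows.append({
            "variant_id": v.variant_id, "r2_exposure": v.r2_exposure,
            "r2_outcome": v.r2_outcome, "direction": v.direction,
            "p_steiger": v.p_steiger, "keep": v.keep,
        })
        if v.keep:
            kept.append(pair)
    return kept, pd.DataFrame(verdict_rows)


def _run_estimators(pairs, config: RunConfig, exposure_label, level):
    """Execute the routed analysis plan for one instrument set."""
    k = len(pairs)
    plan = diag.route_analysis(k)
    rows, diag_row = [], {"exposure_label": exposure_label, "level": level,
                          "k_snps": k}

    def add(estimate: est.MREstimate, model=""):
        rows.append({
            "exposure_label": exposure_label, "level": level,
            "method": estimate.method, "model": model, "beta": estimate.beta,
            "se": estimate.se, "p": estimate.p, "k_snps": estimate.k_snps,
        })

    if "wald" in plan:
        add(est.wald_ratio(pairs[0]))
    if "ivw_fe" in plan:
        add(est.ivw(pairs, "fixed"), "fixed")
        add(est.ivw(pairs, "random"), "random")
        add(est.unweighted_mr(pairs, "fixed"), "fixed")
        add(est.unweighted_mr(pairs, "random"), "random")
        het = diag.cochran_q(pairs)
        diag_row.update({"Q": het.Q, "Q_df": het.df, "Q_p": het.p,
                         "I2": het.i_squared})
    if "egger" in plan:
        slope, intercept = est.egger(pairs)
        add(slope)
        add(intercept)
        decision = diag.rucker_framework(pairs, alpha=config.mr_alpha)
        diag_row.update({
            "Qprime": decision.q_rucker.Q, "Qprime_p": decision.q_rucker.p,
            "QmQp_p": decision.q_minus_qprime_p,
            "egger_intercept": intercept.beta,
            "egger_intercept_p": intercept.p,
            "selected_model": decision.selected_model,
            "I2_GX": diag.i2_gx(pairs),
        })
        add(est.weighted_median(pairs, n_boot=config.n_boot, seed=config.seed))
        add(est.weighted_mode(pairs, n_boot=config.n_boot, seed=config.seed))
        try:
            add(est.mr_lasso(pairs))
        except ValueError as exc:
            logger.warning("%s/%s: mr_lasso failed: %s", exposure_label, level, exc)
    elif "ivw_fe" in plan:
        decision = diag.rucker_framework(pairs, alpha=config.mr_alpha)
        diag_row["selected_model"] = decision.selected_model
    if "presso" in plan:
        presso = est.mr_presso(pairs, n_sim=config.n_sim_presso,
                               seed=config.seed)
        diag_row.update({
            "presso_global_p": presso.global_rss_p,
            "presso_outliers": ";".join(presso.outlier_set) or ".",
        })
        if presso.corrected is not None:
            add(presso.corrected)
    return rows, diag_row


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write reports; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    cohorts = None

    # ------------------------------------------------------------------ input
    if config.preset is not None:
        presets = sim.scenario_presets()
        if config.preset not in presets:
            raise ValueError(f"unknown preset {config.preset!r}; "
                             f"choose from {sorted(presets)}")
        scenario = sim.replace(presets[config.preset], seed=config.seed)
        exposure_cohort = sim.simulate_cohort(scenario, "exposure")
        outcome_cohort = sim.simulate_cohort(scenario, "outcome")
        cohorts = (exposure_cohort, outcome_cohort)
        instruments, outcome_stats = sim.to_two_sample(
            exposure_cohort, outcome_cohort)
    else:
        instruments = sio.read_instrument_table(config.instrument_table)
        outcome_stats = sio.read_outcome_table(config.outcome_table)
    counts["instruments_in"] = len(instruments)
    counts["outcome_stats_in"] = len(outcome_stats)

    ld = (instr.read_ld_table(config.ld_table)
          if config.ld_table else instr.LDView())

    # ------------------------------------------------------- instrument stage
    records = instr.significance_filter(instruments,
                                        config.significance_threshold)
    counts["after_significance_filter"] = len(records)
    records = instr.dedup_lowest_level(records)
    counts["after_dedup"] = len(records)
    records = instr.clump(records, ld=ld, r2_threshold=config.clump_r2,
                          window_bp=config.clump_window_bp,
                          exempt_studies=config.exempt_studies)
    counts["after_within_study_clump"] = len(records)
    sio.write_instrument_table(records, out / "instruments_selected.tsv")

    sets = []
    for level in config.pooling_levels:
        sets.extend(instr.pool_by_taxon(records, level, ld=ld,
                                        r2_threshold=config.clump_r2,
                                        window_bp=config.clump_window_bp))
    counts["instrument_sets"] = len(sets)
    instr.instrument_set_manifest(sets).to_csv(
        out / "instrument_sets.tsv", sep="\t", index=False)

    # ------------------------------------------------ harmonize + steiger + MR
    outcome_by_id = {o.variant_id: o for o in outcome_stats}
    instruments_by_id = {r.variant_id: r for r in records}
    mr_rows, diag_rows, audit_frames, steiger_frames = [], [], [], []
    n_followup = 0
    for s in sets:
        pairs, audit = sio.harmonize_tables(
            s.members, outcome_stats,
            palindromic_eaf_window=config.palindromic_eaf_window)
        audit.insert(0, "exposure_label", s.exposure_label)
        audit.insert(1, "level", s.pooling_level)
        audit_frames.append(audit)
        if config.steiger_enabled:
            pairs, verdicts = _steiger_stage(
                pairs, instruments_by_id, outcome_by_id, config.steiger_alpha)
            if not verdicts.empty:
                verdicts.insert(0, "exposure_label", s.exposure_label)
                verdicts.insert(1, "level", s.pooling_level)
                steiger_frames.append(verdicts)
        if not pairs:
            diag_rows.append({"exposure_label": s.exposure_label,
                              "level": s.pooling_level, "k_snps": 0,
                              "note": "no instruments after filtering"})
            continue
        n_followup += 1
        rows, diag_row = _run_estimators(pairs, config, s.exposure_label,
                                         s.pooling_level)
        mr_rows.extend(rows)
        diag_rows.append(diag_row)

    mr = pd.DataFrame(mr_rows)
    if not mr.empty:
        bar = config.mr_alpha / max(n_followup, 1)
        mr["tier"] = np.select(
            [mr["p"] < bar, mr["p"] < config.mr_alpha],
            ["bonferroni_significant", "suggestive"], default="null")
    mr.to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
    pd.DataFrame(diag_rows).to_csv(out / "mr_diagnostics.tsv", sep="\t",
                                   index=False)
    pd.concat(audit_frames, ignore_index=True).to_csv(
        out / "harmonization_audit.tsv", sep="\t", index=False)
    if steiger_frames:
        pd.concat(steiger_frames, ignore_index=True).to_csv(
            out / "steiger_verdicts.tsv", sep="\t", index=False)
    counts["mr_followup_analyses"] = n_followup
    counts["mr_estimates"] = len(mr)

    # ------------------------------------------------------------- GRS stage
    if config.run_grs and cohorts is not None:
        _, outcome_cohort = cohorts
        fam = {r.variant_id: r.taxon_family for r in records
               if r.taxon_family is not None
               and r.variant_id in outcome_cohort.genotypes.columns}
        profiles = grs_mod.build_grs(outcome_cohort.genotypes, fam)
        grs_mod.grs_matrix(profiles).to_csv(out / "grs_matrix.tsv", sep="\t")
        cond_rows = []
        for variant_id in sorted(fam)[:5]:  # illustrative conditional fits
            res = grs_mod.conditional_scan(
                outcome_cohort.genotypes, variant_id, outcome_cohort.outcome,
                outcome_cohort.covariates, profiles)
            cond_rows.append({
                "variant_id": variant_id, "beta": res.beta, "se": res.se,
                "p": res.p, "n": res.n,
            })
        pd.DataFrame(cond_rows).to_csv(out / "grs_conditional.tsv", sep="\t",
                                       index=False)
        counts["grs_families"] = len(profiles)

    # --------------------------------------------------------------- manifest
    outputs = sorted(p for p in out.glob("*.tsv"))
    manifest = {
        "config": config.to_dict(),
        "counts": counts,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("pipeline complete: %s", counts)
    return out
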