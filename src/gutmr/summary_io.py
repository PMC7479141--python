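"""Reading, validation and harmonization of GWAS summary-statistic tables.

Instrument tables carry one row per variant with exposure-side effect sizes
(in relative-abundance units per effect allele), taxonomy at family/genus/
species level, and a source-study label.  Outcome tables carry the matching
outcome-side statistics from a phenome-wide scan.  Tables are tab-separated
UTF-8 text with a header; "." or an empty field denotes a missing value.

Harmonization aligns the outcome effect to the exposure's effect allele,
resolving allele swaps (sign flip) and strand flips (complement), and drops
palindromic (A/T, C/G) variants whose allele frequency is too close to 0.5
to orient reliably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstrumentRecord",
    "OutcomeStat",
    "HarmonizedPair",
    "SummaryFormatError",
    "SummaryValidationError",
    "read_instrument_table",
    "write_instrument_table",
    "read_outcome_table",
    "write_outcome_table",
    "harmonize",
    "harmonize_tables",
    "se_from_p",
    "p_from_se",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
EFFECT_UNITS = ("relative_abundance", "abundance", "other")

#: default half-width of the allele-frequency window around 0.5 inside which
#: palindromic variants cannot be oriented and are dropped
PALINDROMIC_EAF_WINDOW = 0.08


class SummaryFormatError(ValueError):
    """A table is structurally malformed (e.g. a mandatory column is absent)."""


class SummaryValidationError(ValueError):
    """A row violates a type invariant (e.g. non-positive standard error)."""


@dataclass
class InstrumentRecord:
    """One variant's exposure-side summary statistics plus taxonomy and provenance."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta_exposure: float
    se_exposure: float | None
    p_exposure: float
    n_exposure: int
    taxon_family: str | None = None
    taxon_genus: str | None = None
    taxon_species: str | None = None
    effect_unit: str = "relative_abundance"
    study: str = ""
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in VALID_ALLELES:
            raise SummaryValidationError(
                f"{self.variant_id}: effect_allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise SummaryValidationError(
                f"{self.variant_id}: other_allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.position < 1:
            raise SummaryValidationError(f"{self.variant_id}: position must be >= 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryValidationError(f"{self.variant_id}: eaf outside [0, 1]")
        if self.se_exposure is not None and self.se_exposure <= 0:
            raise SummaryValidationError(
                f"{self.variant_id}: se_exposure must be > 0 when present"
            )
        if not (0.0 < self.p_exposure <= 1.0):
            raise SummaryValidationError(f"{self.variant_id}: p_exposure outside (0, 1]")
        if self.n_exposure <= 0:
            raise SummaryValidationError(f"{self.variant_id}: n_exposure must be positive")
        if self.effect_unit not in EFFECT_UNITS:
            raise SummaryValidationError(
                f"{self.variant_id}: effect_unit {self.effect_unit!r} not one of {EFFECT_UNITS}"
            )
        # taxonomy must form a chain: species implies genus implies family
        if self.taxon_species is not None and self.taxon_genus is None:
            raise SummaryValidationError(
                f"{self.variant_id}: species assignment without genus"
            )
        if self.taxon_genus is not None and self.taxon_family is None:
            raise SummaryValidationError(
                f"{self.variant_id}: genus assignment without family"
            )

    @property
    def taxon_level(self) -> str | None:
        """Deepest taxonomic level available for this record."""
        if self.taxon_species is not None:
            return "species"
        if self.taxon_genus is not None:
            return "genus"
        if self.taxon_family is not None:
            return "family"
        return None

    def taxon_at(self, level: str) -> str | None:
        return {
            "family": self.taxon_family,
            "genus": self.taxon_genus,
            "species": self.taxon_species,
        }[level]

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def se_or_reconstructed(self) -> float:
        """se_exposure, reconstructed from (beta, p) when the source omits it."""
        if self.se_exposure is not None:
            return self.se_exposure
        return se_from_p(self.beta_exposure, self.p_exposure)


@dataclass
class OutcomeStat:
    """Outcome-side summary statistics for one variant from the phenome scan."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    n_outcome: int
    n_cases: int | None = None
    outcome_type: str = "continuous"
    outcome_id: str = ""

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SummaryValidationError(f"{self.variant_id}: alleles must be A/C/G/T")
        if self.se_outcome <= 0:
            raise SummaryValidationError(f"{self.variant_id}: se_outcome must be > 0")
        if self.outcome_type not in ("continuous", "binary"):
            raise SummaryValidationError(
                f"{self.variant_id}: outcome_type must be continuous or binary"
            )
        if self.n_cases is not None and self.n_cases > self.n_outcome:
            raise SummaryValidationError(f"{self.variant_id}: n_cases exceeds n_outcome")

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effect quadruple for one variant."""

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    harmonization_action: str = "unchanged"

    @property
    def retained(self) -> bool:
        return not self.harmonization_action.startswith("dropped")


# ---------------------------------------------------------------------------
# table IO

_INSTRUMENT_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta_exposure", "se_exposure", "p_exposure", "n_exposure",
    "taxon_family", "taxon_genus", "taxon_species", "effect_unit", "study",
]
_INSTRUMENT_MANDATORY = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "beta_exposure", "p_exposure", "n_exposure",
]
_OUTCOME_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf", "beta_outcome",
    "se_outcome", "p_outcome", "n_outcome", "n_cases", "outcome_type",
    "outcome_id",
]
_OUTCOME_MANDATORY = [
    "variant_id", "effect_allele", "other_allele", "beta_outcome",
    "se_outcome", "p_outcome", "n_outcome",
]

# common GWAS export header dialects mapped onto the canonical names
_SYNONYMS = {
    "snp": "variant_id", "rsid": "variant_id", "markername": "variant_id",
    "chr": "chromosome", "chrom": "chromosome",
    "pos": "position", "bp": "position", "base_pair_location": "position",
    "ea": "effect_allele", "a1": "effect_allele", "allele1": "effect_allele",
    "oa": "other_allele", "a2": "other_allele", "nea": "other_allele",
    "allele2": "other_allele",
    "freq": "eaf", "effect_allele_frequency": "eaf", "maf": "eaf",
    "beta": "beta_exposure", "effect": "beta_exposure",
    "se": "se_exposure", "stderr": "se_exposure",
    "p": "p_exposure", "pval": "p_exposure", "p_value": "p_exposure",
    "n": "n_exposure", "samplesize": "n_exposure",
}


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _missing(cell: str) -> bool:
    return cell == "" or cell == "."


def _parse(cell: str, kind, row: int, column: str):
    if _missing(cell):
        return None
    try:
        return kind(cell)
    except (TypeError, ValueError):
        raise SummaryValidationError(
            f"row {row}: cannot parse {column}={cell!r} as {kind.__name__}"
        ) from None


def read_instrument_table(path) -> list[InstrumentRecord]:
    """Read and validate a tab-separated instrument table.

    Raises :class:`SummaryFormatError` when a mandatory column is missing and
    :class:`SummaryValidationError` (naming the offending row) when a cell
    cannot be parsed or violates a type invariant.
    """
    df = _read_tsv(path)
    rename = {c: _SYNONYMS.get(c.lower(), c.lower()) for c in df.columns}
    df = df.rename(columns=rename)
    for col in _INSTRUMENT_MANDATORY:
        if col not in df.columns:
            raise SummaryFormatError(f"missing mandatory column: {col}")
    extra_cols = [c for c in df.columns if c not in _INSTRUMENT_COLUMNS]

    records: list[InstrumentRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        try:
            rec = InstrumentRecord(
                variant_id=r["variant_id"],
                chromosome=str(r["chromosome"]),
                position=_parse(r["position"], int, i, "position"),
                effect_allele=r["effect_allele"],
                other_allele=r["other_allele"],
                eaf=_parse(r.get("eaf", "."), float, i, "eaf"),
                beta_exposure=_parse(r["beta_exposure"], float, i, "beta_exposure"),
                se_exposure=_parse(r.get("se_exposure", "."), float, i, "se_exposure"),
                p_exposure=_parse(r["p_exposure"], float, i, "p_exposure"),
                n_exposure=_parse(r["n_exposure"], int, i, "n_exposure"),
                taxon_family=r.get("taxon_family") or None if not _missing(r.get("taxon_family", ".")) else None,
                taxon_genus=r.get("taxon_genus") or None if not _missing(r.get("taxon_genus", ".")) else None,
                taxon_species=r.get("taxon_species") or None if not _missing(r.get("taxon_species", ".")) else None,
                effect_unit=r.get("effect_unit", "relative_abundance") if not _missing(r.get("effect_unit", ".")) else "relative_abundance",
                study=r.get("study", "") if not _missing(r.get("study", ".")) else "",
                extra={c: r[c] for c in extra_cols},
            )
        except SummaryValidationError as exc:
            raise SummaryValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_instrument_table(records: Iterable[InstrumentRecord], path) -> None:
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extra})
    columns = _INSTRUMENT_COLUMNS + extra_cols
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id, "chromosome": r.chromosome,
            "position": r.position, "effect_allele": r.effect_allele,
            "other_allele": r.other_allele, "eaf": _fmt(r.eaf),
            "beta_exposure": _fmt(r.beta_exposure), "se_exposure": _fmt(r.se_exposure),
            "p_exposure": _fmt(r.p_exposure), "n_exposure": r.n_exposure,
            "taxon_family": _fmt(r.taxon_family), "taxon_genus": _fmt(r.taxon_genus),
            "taxon_species": _fmt(r.taxon_species), "effect_unit": r.effect_unit,
            "study": r.study,
        }
        row.update({c: r.extra.get(c, ".") for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_outcome_table(path) -> list[OutcomeStat]:
    df = _read_tsv(path)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    for col in _OUTCOME_MANDATORY:
        if col not in df.columns:
            raise SummaryFormatError(f"missing mandatory column: {col}")
    stats_out: list[OutcomeStat] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        try:
            stat = OutcomeStat(
                variant_id=r["variant_id"],
                effect_allele=r["effect_allele"],
                other_allele=r["other_allele"],
                eaf=_parse(r.get("eaf", "."), float, i, "eaf"),
                beta_outcome=_parse(r["beta_outcome"], float, i, "beta_outcome"),
                se_outcome=_parse(r["se_outcome"], float, i, "se_outcome"),
                p_outcome=_parse(r["p_outcome"], float, i, "p_outcome"),
                n_outcome=_parse(r["n_outcome"], int, i, "n_outcome"),
                n_cases=_parse(r.get("n_cases", "."), int, i, "n_cases"),
                outcome_type=r.get("outcome_type", "continuous") if not _missing(r.get("outcome_type", ".")) else "continuous",
                outcome_id=r.get("outcome_id", "") if not _missing(r.get("outcome_id", ".")) else "",
            )
        except SummaryValidationError as exc:
            raise SummaryValidationError(f"row {i}: {exc}") from None
        stats_out.append(stat)
    return stats_out


def write_outcome_table(stats_in: Iterable[OutcomeStat], path) -> None:
    rows = []
    for s in stats_in:
        rows.append({
            "variant_id": s.variant_id, "effect_allele": s.effect_allele,
            "other_allele": s.other_allele, "eaf": _fmt(s.eaf),
            "beta_outcome": _fmt(s.beta_outcome), "se_outcome": _fmt(s.se_outcome),
            "p_outcome": _fmt(s.p_outcome), "n_outcome": s.n_outcome,
            "n_cases": _fmt(s.n_cases), "outcome_type": s.outcome_type,
            "outcome_id": s.outcome_id,
        })
    pd.DataFrame(rows, columns=_OUTCOME_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization

def harmonize(
    exposure: InstrumentRecord,
    outcome: OutcomeStat,
    palindromic_eaf_window: float = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedPair:
    """Align the outcome effect to the exposure's effect allele.

    Allele swaps flip the outcome beta's sign; strand flips (complement
    alleles) are treated as matching.  Palindromic variants are retained only
    when both allele frequencies fall outside ``0.5 ± palindromic_eaf_window``
    and sit on the same side of 0.5; otherwise they are dropped because the
    strand cannot be resolved.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    se_x = exposure.se_or_reconstructed()

    def pair(beta_y: float, action: str) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            beta_x=exposure.beta_exposure, se_x=se_x,
            beta_y=beta_y, se_y=outcome.se_outcome,
            harmonization_action=action,
        )

    ea, oa = exposure.effect_allele, exposure.other_allele
    oea, ooa = outcome.effect_allele, outcome.other_allele

    if exposure.is_palindromic() or outcome.is_palindromic():
        lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
        eafs = (exposure.eaf, outcome.eaf)
        if any(f is None for f in eafs):
            return pair(0.0, "dropped_palindromic")
        if any(lo <= f <= hi for f in eafs):
            return pair(0.0, "dropped_palindromic")
        if (exposure.eaf - 0.5) * (outcome.eaf - 0.5) <= 0:
            # discordant frequencies: outcome reported on the other strand
            # orientation; for a palindromic variant that is indistinguishable
            # from an allele swap, so drop conservatively
            return pair(0.0, "dropped_palindromic")
        if {oea, ooa} != {ea, oa}:
            return pair(0.0, "dropped_mismatch")
        return pair(outcome.beta_outcome, "unchanged")

    if (oea, ooa) == (ea, oa):
        return pair(outcome.beta_outcome, "unchanged")
    if (oea, ooa) == (oa, ea):
        return pair(-outcome.beta_outcome, "sign_flipped")
    # try the complementary strand
    cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
    if (cea, coa) == (ea, oa):
        return pair(outcome.beta_outcome, "unchanged")
    if (cea, coa) == (oa, ea):
        return pair(-outcome.beta_outcome, "sign_flipped")
    return pair(0.0, "dropped_mismatch")


def harmonize_tables(
    instruments: Sequence[InstrumentRecord],
    outcomes: Sequence[OutcomeStat],
    palindromic_eaf_window: float = PALINDROMIC_EAF_WINDOW,
) -> tuple[list[HarmonizedPair], pd.DataFrame]:
    """Harmonize matched tables; returns retained pairs plus a full audit log.

    The audit log has one row per exposure variant with the action taken;
    variants absent from the outcome table are logged as ``missing_outcome``.
    """
    by_id = {o.variant_id: o for o in outcomes}
    pairs: list[HarmonizedPair] = []
    audit_rows = []
    for rec in instruments:
        out = by_id.get(rec.variant_id)
        if out is None:
            audit_rows.append({"variant_id": rec.variant_id,
                               "harmonization_action": "missing_outcome"})
            continue
        p = harmonize(rec, out, palindromic_eaf_window)
        audit_rows.append({"variant_id": p.variant_id,
                           "harmonization_action": p.harmonization_action})
        if p.retained:
            pairs.append(p)
    audit = pd.DataFrame(audit_rows, columns=["variant_id", "harmonization_action"])
    return pairs, audit


# ---------------------------------------------------------------------------
# p-value / standard-error conversion

def se_from_p(beta: float, p: float) -> float:
    """Standard error implied by an effect size and its two-sided p-value.

    ``se = |beta| / z`` where ``z`` is the two-sided standard-normal quantile
    of ``p``.  Needed because some source studies report p without SE, and
    both I²_GX and the bootstrap SEs require an exposure-side SE.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if beta == 0:
        raise ValueError("beta must be nonzero to reconstruct a standard error")
    z = stats.norm.isf(p / 2.0)
    return abs(beta) / z


def p_from_se(beta: float, se: float) -> float:
    """Two-sided normal p-value for an effect size and standard error."""
    if se <= 0:
        raise ValueError("se must be positive")
    return 2.0 * stats.norm.sf(abs(beta) / se)
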