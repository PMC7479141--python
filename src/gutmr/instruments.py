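"""Instrument assembly: significance filtering, LD clumping, taxonomic pooling.

Implements the selection funnel used to turn a harvest of microbiome-GWAS
variants into per-bacterium instrument sets: the genome-wide inclusion
threshold (P < 5e-8), greedy LD clumping at r^2 < 0.005 within a 5 Mb window
(within study per bacterium at the lowest taxonomic level, then between
studies per pooled taxon), deduplication of identical associations reported
at several taxonomic ranks, the relative-abundance unit filter, and pooling
of species/genus records up to a requested rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .summary_io import InstrumentRecord

__all__ = [
    "LDView",
    "InstrumentSet",
    "significance_filter",
    "clump",
    "dedup_lowest_level",
    "pool_by_taxon",
    "read_ld_table",
    "GENOME_WIDE_P",
    "CLUMP_R2",
    "CLUMP_WINDOW_BP",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.005
CLUMP_WINDOW_BP = 5_000_000

_LEVEL_DEPTH = {"family": 1, "genus": 2, "species": 3}


class LDView:
    """Symmetric pairwise-r^2 lookup over a set of covered variants.

    Pairs absent from the map (or involving uncovered variants) are treated
    as r^2 = 0.  ``same_signal_radius`` enables a distance-only fallback:
    variants within that many base pairs on the same chromosome are treated
    as r^2 = 1 when no measured value is available (disabled by default).
    """

    def __init__(
        self,
        r2: Mapping[tuple[str, str], float] | None = None,
        same_signal_radius: int = 0,
    ) -> None:
        self._r2: dict[frozenset, float] = {}
        self.coverage: set[str] = set()
        self.same_signal_radius = same_signal_radius
        if r2:
            for (a, b), value in r2.items():
                self.add(a, b, value)

    def add(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {value}")
        self._r2[frozenset((a, b))] = value
        self.coverage.update((a, b))

    def r2(self, a: str, b: str, distance_bp: int | None = None) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key in self._r2:
            return self._r2[key]
        if (
            distance_bp is not None
            and self.same_signal_radius > 0
            and distance_bp <= self.same_signal_radius
        ):
            return 1.0
        return 0.0

    def covers(self, a: str) -> bool:
        return a in self.coverage


def read_ld_table(path) -> LDView:
    """Read a tab-separated (variant_a, variant_b, r2) table into an LDView."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    view = LDView()
    for row in df.itertuples(index=False):
        view.add(str(row.variant_a), str(row.variant_b), float(row.r2))
    return view


@dataclass
class InstrumentSet:
    """Clumped instruments for one exposure (a taxon at a given rank)."""

    exposure_label: str
    pooling_level: str
    members: list[InstrumentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]


def significance_filter(
    records: Iterable[InstrumentRecord], threshold: float = GENOME_WIDE_P
) -> list[InstrumentRecord]:
    """Retain records with p_exposure strictly below the inclusion threshold."""
    return [r for r in records if r.p_exposure < threshold]


def _sort_key(record: InstrumentRecord):
    # deterministic greedy order: best p first, ties broken by genomic
    # coordinates then identifier so results are platform-independent
    return (record.p_exposure, record.chromosome, record.position, record.variant_id)


def clump(
    records: Sequence[InstrumentRecord],
    ld: LDView | None = None,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    group_key: Callable[[InstrumentRecord], object] | None = None,
    exempt_studies: Iterable[str] = (),
) -> list[InstrumentRecord]:
    """Greedy LD clumping within groups of records.

    Within each group (default: the taxon at the record's lowest available
    level, per study) records are sorted ascending by p; the best remaining
    record is retained and any record on the same chromosome within
    ``window_bp`` (inclusive) AND with r^2 >= ``r2_threshold`` against it is
    discarded.  Studies in ``exempt_studies`` bypass clumping entirely
    (a twin-study harvest is not a GWAS and is taken forward unclumped).
    """
    if ld is None:
        ld = LDView()
    if group_key is None:
        group_key = lambda r: (r.study, r.taxon_level, r.taxon_at(r.taxon_level) if r.taxon_level else None)
    exempt = set(exempt_studies)

    retained: list[InstrumentRecord] = []
    groups: dict[object, list[InstrumentRecord]] = {}
    for r in records:
        if r.study in exempt:
            retained.append(r)
        else:
            groups.setdefault(group_key(r), []).append(r)

    for _, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        candidates = sorted(members, key=_sort_key)
        while candidates:
            best = candidates.pop(0)
            retained.append(best)
            survivors = []
            for other in candidates:
                same_chrom = other.chromosome == best.chromosome
                distance = abs(other.position - best.position) if same_chrom else None
                within = same_chrom and distance <= window_bp
                if within and ld.r2(best.variant_id, other.variant_id, distance) >= r2_threshold:
                    continue  # clumped away
                if within and not (ld.covers(best.variant_id) and ld.covers(other.variant_id)):
                    logger.info(
                        "clump: no LD information for (%s, %s) at %d bp; retained (r2 treated as 0)",
                        best.variant_id, other.variant_id, distance,
                    )
                survivors.append(other)
            candidates = survivors

    # stable output order: keep the original record order
    index = {id(r): i for i, r in enumerate(records)}
    retained.sort(key=lambda r: index[id(r)])
    return retained


def dedup_lowest_level(records: Sequence[InstrumentRecord]) -> list[InstrumentRecord]:
    """Keep only the most differentiated taxonomic record per duplicated association.

    When the same (study, variant, effect size) appears at several taxonomic
    ranks within a study, the deepest rank (species > genus > family) is
    taken forward to reduce the multiple-testing burden.  Records with
    different effect sizes are distinct associations and are all kept.
    """
    best: dict[tuple, InstrumentRecord] = {}
    order: dict[tuple, int] = {}
    for i, r in enumerate(records):
        key = (r.study, r.variant_id, r.beta_exposure)
        depth = _LEVEL_DEPTH.get(r.taxon_level or "", 0)
        if key not in best or depth > _LEVEL_DEPTH.get(best[key].taxon_level or "", 0):
            best[key] = r
            order.setdefault(key, i)
    return [best[k] for k in sorted(order, key=order.get)]


def pool_by_taxon(
    records: Sequence[InstrumentRecord],
    level: str,
    ld: LDView | None = None,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> list[InstrumentSet]:
    """Pool instruments to a taxonomic rank and clump between studies.

    Only records whose effect sizes are in relative-abundance units are
    pooled (pooled estimation requires a common unit).  Records lacking an
    assignment at the requested rank are skipped with a log entry.  Within
    each pooled taxon a between-study clump is applied.
    """
    if level not in _LEVEL_DEPTH:
        raise ValueError(f"level must be one of {sorted(_LEVEL_DEPTH)}, got {level!r}")
    groups: dict[str, list[InstrumentRecord]] = {}
    for r in records:
        if r.effect_unit != "relative_abundance":
            logger.info("pool_by_taxon: %s excluded (effect_unit=%s)",
                        r.variant_id, r.effect_unit)
            continue
        name = r.taxon_at(level)
        if name is None:
            logger.info("pool_by_taxon: %s has no %s assignment; skipped",
                        r.variant_id, level)
            continue
        groups.setdefault(name, []).append(r)

    sets = []
    for name in sorted(groups):
        members = clump(
            groups[name], ld=ld, r2_threshold=r2_threshold, window_bp=window_bp,
            group_key=lambda r: name,  # between-study: one group per taxon
        )
        sets.append(InstrumentSet(exposure_label=name, pooling_level=level,
                                  members=members))
    return sets


def instrument_set_manifest(sets: Sequence[InstrumentSet]) -> pd.DataFrame:
    """One row per (exposure_label, level, variant_id) across instrument sets."""
    rows = [
        {"exposure_label": s.exposure_label, "level": s.pooling_level,
         "variant_id": m.variant_id, "study": m.study}
        for s in sets for m in s.members
    ]
    return pd.DataFrame(rows, columns=["exposure_label", "level", "variant_id", "study"])
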