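import numpy as np
import pytest

from gutmr.summary_io import HarmonizedPair, InstrumentRecord


def make_pairs(bx, by, sy, sx=None, prefix="rs"):
    """HarmonizedPair list from parallel arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    sx = np.broadcast_to(np.asarray(0.05 if sx is None else sx, dtype=float), bx.shape)
    return [
        HarmonizedPair(f"{prefix}{j}", float(bx[j]), float(sx[j]),
                       float(by[j]), float(sy[j]))
        for j in range(len(bx))
    ]


def make_record(variant_id="rs1", chromosome="1", position=1000, beta=0.2,
                se=0.03, p=1e-9, n=1000, family="FamilyA", genus=None,
                species=None, study="study_a", effect_unit="relative_abundance",
                eaf=0.3, ea="A", oa="G"):
    return InstrumentRecord(
        variant_id=variant_id, chromosome=chromosome, position=position,
        effect_allele=ea, other_allele=oa, eaf=eaf, beta_exposure=beta,
        se_exposure=se, p_exposure=p, n_exposure=n, taxon_family=family,
        taxon_genus=genus, taxon_species=species, effect_unit=effect_unit,
        study=study,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_pairs(rng, k, theta=0.3, outlier_idx=None, outlier_shift=0.0):
    """Summary-level pairs with homogeneous true ratios (optionally one outlier)."""
    bx_true = rng.uniform(0.2, 0.5, size=k)
    sx = np.full(k, 0.01)
    sy = rng.uniform(0.03, 0.08, size=k)
    bx = rng.normal(bx_true, sx)
    by = rng.normal(theta * bx_true, sy)
    if outlier_idx is not None:
        by[outlier_idx] += outlier_shift * bx_true[outlier_idx]
    return make_pairs(bx, by, sy, sx=sx)
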