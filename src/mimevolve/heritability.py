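"""Grandmother–granddaughter heritability estimation for a female-limited trait.

Because only females express the mimicry trait, parent–offspring regression
is impossible and heritability is estimated from second-degree relatives:
the phenotypic correlation ``r`` among grandmother–granddaughter pairs is
quadrupled, ``h² (or H²) = 4r``, since the expected phenotypic correlation
between an autosomal-trait grandmother and granddaughter is ``relatedness ×
heritability`` with relatedness 1/4.  Pairs through the mother's mother
(maternal lineage) estimate broad-sense H²; pairs through the father's
mother (paternal lineage) estimate narrow-sense h².

If the trait is in fact W-linked or organelle-encoded, the maternal-line
relatedness is 1 rather than 1/4, the maternal 4r estimate is inflated
fourfold (it can exceed 1), and the paternal estimate collapses to ~0;
:func:`apply_inheritance_correction` rescales accordingly.

Confidence intervals are percentile bootstrap (2.5/97.5) over resampled
grandmother clusters: all granddaughters of one grandmother enter or leave
a resample together, which respects the non-independence of pairs sharing
a grandmother.  Point estimates are never truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "GGPair",
    "HeritabilityEstimate",
    "GeneticCorrelationEstimate",
    "extract_gg_pairs",
    "estimate_heritability",
    "apply_inheritance_correction",
    "estimate_genetic_correlation",
]


@dataclass
class GGPair:
    """One grandmother–granddaughter pair with trait values.

    ``family_id`` is the grandmother's id and is the resampling cluster for
    the bootstrap.
    """

    grandmother_id: str
    granddaughter_id: str
    lineage: str  # "maternal" or "paternal"
    g_value: float
    d_value: float
    family_id: str


@dataclass
class HeritabilityEstimate:
    lineage: str
    trait: str
    n_pairs: int
    r: float
    estimate: float  # 4 r; H² for maternal pairs, h² for paternal pairs
    ci_low: float
    ci_high: float
    p_value: float
    boot_se: float
    correction_mode: str = "autosomal"
    corrected_estimate: float = 0.0

    def __post_init__(self) -> None:
        if self.correction_mode == "autosomal" and self.corrected_estimate == 0.0:
            self.corrected_estimate = self.estimate


@dataclass
class GeneticCorrelationEstimate:
    lineage: str
    n_pairs: int
    r_cross: float
    p_value: float
    direction_detail: dict[str, float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def _check_lineage(lineage: str) -> None:
    if lineage not in ("maternal", "paternal"):
        raise ValueError(f"lineage must be 'maternal' or 'paternal', got {lineage!r}")


def extract_gg_pairs(
    ped: Pedigree,
    lineage: str,
    trait: str = "white_rel",
    g_trait: Optional[str] = None,
    d_trait: Optional[str] = None,
) -> list[GGPair]:
    """All grandmother–granddaughter pairs of the given lineage with both
    trait values present.

    Maternal lineage: the grandmother is the mother of the granddaughter's
    mother; paternal: the mother of her father.  A grandmother with k
    measured granddaughters contributes k pairs sharing her ``family_id``.
    ``g_trait``/``d_trait`` allow cross-trait pairs (for genetic
    correlation); both default to ``trait``.
    """
    _check_lineage(lineage)
    g_trait = g_trait or trait
    d_trait = d_trait or trait
    pairs: list[GGPair] = []
    for ind in ped:
        if ind.sex != "F":
            continue
        d_value = getattr(ind, d_trait)
        if d_value is None:
            continue
        link = ped.mother(ind.id) if lineage == "maternal" else ped.father(ind.id)
        if link is None:
            continue
        gm = ped.mother(link.id)
        if gm is None or gm.sex != "F":
            continue
        g_value = getattr(gm, g_trait)
        if g_value is None:
            continue
        pairs.append(
            GGPair(
                grandmother_id=gm.id,
                granddaughter_id=ind.id,
                lineage=lineage,
                g_value=float(g_value),
                d_value=float(d_value),
                family_id=gm.id,
            )
        )
    return pairs


def _bootstrap_4r(
    g: np.ndarray,
    d: np.ndarray,
    families: list[str],
    fam_of_pair: list[str],
    n_boot: int,
    seed: Optional[int],
) -> np.ndarray:
    """Cluster bootstrap of 4r: grandmother clusters resampled with replacement.

    Per replicate, ``len(families)`` cluster indices are drawn uniformly and
    their pairs concatenated in sampled order; replicates with undefined
    correlation (zero variance) are NaN.
    """
    idx_by_fam = {f: np.flatnonzero(np.array(fam_of_pair) == f) for f in families}
    rng = np.random.default_rng(seed)
    n_fam = len(families)
    out = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, n_fam, size=n_fam)
        idx = np.concatenate([idx_by_fam[families[k]] for k in pick])
        gg, dd = g[idx], d[idx]
        if np.allclose(gg, gg[0]) or np.allclose(dd, dd[0]):
            out[i] = np.nan
        else:
            out[i] = 4.0 * float(np.corrcoef(gg, dd)[0, 1])
    return out


def estimate_heritability(
    pairs: Sequence[GGPair],
    lineage: str,
    trait: str = "white_rel",
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> HeritabilityEstimate:
    """The 4r heritability estimate with cluster-bootstrap CI and regression P.

    ``r`` is the Pearson correlation of (grandmother, granddaughter) trait
    values; the point estimate is exactly ``4r``.  The p-value is the slope
    F-test of the least-squares regression of granddaughter on grandmother
    values (computed as the equivalent two-sided slope t-test).  The 95% CI
    is the 2.5/97.5 percentile of 4r over ``n_boot`` resamples of
    grandmother clusters.
    """
    _check_lineage(lineage)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    g = np.array([p.g_value for p in pairs], float)
    d = np.array([p.d_value for p in pairs], float)
    if np.allclose(g, g[0]) or np.allclose(d, d[0]):
        raise ValueError("degenerate (zero-variance) trait values in pairs")
    r = float(np.corrcoef(g, d)[0, 1])
    p_value = float(stats.linregress(g, d).pvalue)
    families = list(dict.fromkeys(p.family_id for p in pairs))
    fam_of_pair = [p.family_id for p in pairs]
    boot = _bootstrap_4r(g, d, families, fam_of_pair, n_boot, seed)
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    return HeritabilityEstimate(
        lineage=lineage,
        trait=trait,
        n_pairs=len(pairs),
        r=r,
        estimate=4.0 * r,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        boot_se=float(np.nanstd(boot)),
    )


def apply_inheritance_correction(
    est: HeritabilityEstimate, mode: str
) -> HeritabilityEstimate:
    """Rescale the 4r estimate for the assumed inheritance architecture.

    ``autosomal``: unchanged (grandmother–granddaughter relatedness 1/4).
    ``w_or_organelle``: the maternal-line relatedness is 1, so the true
    heritability is 1/4 of the 4r value; the estimate and CI are divided
    by 4.
    """
    if mode == "autosomal":
        factor = 1.0
    elif mode == "w_or_organelle":
        factor = 0.25
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return HeritabilityEstimate(
        lineage=est.lineage,
        trait=est.trait,
        n_pairs=est.n_pairs,
        r=est.r,
        estimate=est.estimate,
        ci_low=est.ci_low * factor,
        ci_high=est.ci_high * factor,
        p_value=est.p_value,
        boot_se=est.boot_se,
        correction_mode=mode,
        corrected_estimate=est.estimate * factor,
    )


def estimate_genetic_correlation(
    ped: Pedigree,
    lineage: str,
    n_boot: int = 10000,
    seed: Optional[int] = None,
) -> GeneticCorrelationEstimate:
    """Cross-trait genetic correlation from grandmother–granddaughter pairs.

    Computes the two one-way cross correlations — grandmother white spot
    against granddaughter red spot, and grandmother red against
    granddaughter white — and summarises them as their arithmetic mean
    ``r_cross``.  The p-value is the pair-level significance test of
    ``r_cross`` (t = r·sqrt((n−2)/(1−r²)), the regression F-test at the
    pair level); a cluster-bootstrap CI of ``r_cross`` is attached.
    """
    _check_lineage(lineage)
    pairs_wr = extract_gg_pairs(ped, lineage, g_trait="white_rel", d_trait="red_rel")
    pairs_rw = extract_gg_pairs(ped, lineage, g_trait="red_rel", d_trait="white_rel")
    if len(pairs_wr) < 3 or len(pairs_rw) < 3:
        raise ValueError("need >= 3 pairs with both traits measured")

    def _corr(ps: Sequence[GGPair]) -> float:
        g = np.array([p.g_value for p in ps])
        d = np.array([p.d_value for p in ps])
        if np.allclose(g, g[0]) or np.allclose(d, d[0]):
            raise ValueError("degenerate trait values in cross pairs")
        return float(np.corrcoef(g, d)[0, 1])

    r_wr = _corr(pairs_wr)
    r_rw = _corr(pairs_rw)
    r_cross = (r_wr + r_rw) / 2.0
    n = min(len(pairs_wr), len(pairs_rw))
    if abs(r_cross) >= 1.0:
        p_value = 0.0
    else:
        t = r_cross * np.sqrt((n - 2) / (1.0 - r_cross**2))
        p_value = float(2.0 * stats.t.sf(abs(t), df=n - 2))

    # cluster bootstrap of the mean cross correlation
    families = list(dict.fromkeys(p.family_id for p in pairs_wr))
    fam_wr = np.array([p.family_id for p in pairs_wr])
    fam_rw = np.array([p.family_id for p in pairs_rw])
    gw = np.array([p.g_value for p in pairs_wr])
    dr = np.array([p.d_value for p in pairs_wr])
    gr = np.array([p.g_value for p in pairs_rw])
    dw = np.array([p.d_value for p in pairs_rw])
    idx_wr = {f: np.flatnonzero(fam_wr == f) for f in families}
    idx_rw = {f: np.flatnonzero(fam_rw == f) for f in families}
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, len(families), size=len(families))
        iw = np.concatenate([idx_wr[families[k]] for k in pick])
        ir = np.concatenate([idx_rw[families[k]] for k in pick])
        if gw[iw].std() == 0 or dr[iw].std() == 0 or gr[ir].std() == 0 or dw[ir].std() == 0:
            boot[i] = np.nan
            continue
        boot[i] = (
            float(np.corrcoef(gw[iw], dr[iw])[0, 1])
            + float(np.corrcoef(gr[ir], dw[ir])[0, 1])
        ) / 2.0
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    return GeneticCorrelationEstimate(
        lineage=lineage,
        n_pairs=n,
        r_cross=r_cross,
        p_value=p_value,
        direction_detail={"gm_white_gd_red": r_wr, "gm_red_gd_white": r_rw},
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )
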