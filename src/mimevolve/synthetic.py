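"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators:

* :func:`render_wing` — an idealised wing photograph (elliptical wing body on
  a saturated uniform background) with a white spot of known analysis-region
  area fraction, optional red spots (distinct or fused with the white spot),
  landmarks, and exact ground-truth masks.
* :func:`simulate_pedigree` — a three-generation laboratory breeding design
  started from wild-mated founder females, with a female-limited quantitative
  trait transmitted under autosomal, W-linked, or organelle inheritance.
* :func:`simulate_temporal_series` — a multi-decade specimen series whose
  mean trait follows a continuous piecewise-linear trend with a breakpoint
  year and era-specific residual standard deviations.

All masks are computed analytically (pixel-centre membership tests after
inverse rotation), so ground-truth area fractions are exact on the returned
rasters and rotation changes areas only through rasterisation.

The white spot is rendered as a two-tone texture (a base grey level with a
brighter speckle minority) rather than with additive symmetric noise.  The
mean − SD brightness rule presumes that the white-area brightness histogram
has its mass at its lower edge with a brighter tail — the regime in which
the rule reproduces visual counts on real photographs; a symmetric noise
model would place ~16% of white pixels below the threshold and make the
rule untestable.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .pedigree import Individual, Pedigree
from .spotquant import LandmarkPair, WingImage
from .trends import SpecimenRecord

__all__ = [
    "WingRenderSpec",
    "GroundTruth",
    "PedigreeSimSpec",
    "TemporalSimSpec",
    "MatingError",
    "render_wing",
    "simulate_pedigree",
    "simulate_temporal_series",
    "historical_series_spec",
    "pairs_with_correlation",
]

# Render palette.  Background is a saturated colour far from both the black
# wing body and the spots so that wing-mask recovery is unambiguous.
_BACKGROUND = np.array([0, 162, 255], float)
_WING_BODY = 26.0  # grey level of the black wing body
_WHITE_BASE = 246.0
_WHITE_SPECKLE = 254.0
_WHITE_SPECKLE_FRACTION = 0.25
_RED = np.array([200, 30, 30], float)


@dataclass
class WingRenderSpec:
    """Geometry and noise parameters for one rendered wing."""

    image_height: int = 256
    image_width: int = 320
    wing_center: tuple[float, float] = (159.5, 127.5)  # (x, y)
    wing_semi_x: float = 100.0
    wing_semi_y: float = 78.0
    target_white_fraction: float = 0.08
    n_red_spots: int = 4
    red_spot_radius: float = 9.0
    fused: bool = False
    rotation_deg: float = 0.0
    brightness_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_white_fraction <= 0.25):
            raise ValueError("target_white_fraction must lie in [0, 0.25]")
        if self.n_red_spots < 0 or self.red_spot_radius <= 0:
            raise ValueError("invalid red spot configuration")
        if self.brightness_noise_sd < 0:
            raise ValueError("brightness_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact masks, landmarks and area fractions for a rendered wing."""

    wing_mask: np.ndarray
    white_mask: np.ndarray
    red_mask: np.ndarray
    analysis_mask: np.ndarray
    landmark1: tuple[float, float]
    landmark2: tuple[float, float]
    true_white_fraction: float
    true_red_fraction: float


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def render_wing(spec: WingRenderSpec) -> tuple[WingImage, GroundTruth]:
    """Render a wing image and its exact ground truth.

    The white spot radius is calibrated by pixel counting so that the white
    fraction of the analysis region matches ``target_white_fraction`` to
    within rasterisation error (well inside 0.005).  Raises ``ValueError``
    naming the maximum attainable fraction when the request does not fit
    inside the wing outline.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.wing_center
    ax, ay = spec.wing_semi_x, spec.wing_semi_y
    theta = math.radians(spec.rotation_deg)

    # Unrotated-frame geometry: landmark 1 on the wing midline above the
    # spot, landmark 2 at the bottom tip of the outline ("tail").
    # landmark 1 sits on an integer row so the "at or below its row" rule
    # used downstream coincides exactly with the renderer's half-plane test
    lm1_u = np.array([cx, float(round(cy - 0.35 * ay))])
    lm2_u = np.array([cx, cy + ay])
    spot_center = np.array([cx, cy + 0.35 * ay])

    # Final-frame pixel centres, inverse-rotated into the unrotated frame.
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pivot = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    inv = _rot(-theta)
    u = inv[0, 0] * (xs - pivot[0]) + inv[0, 1] * (ys - pivot[1]) + pivot[0]
    v = inv[1, 0] * (xs - pivot[0]) + inv[1, 1] * (ys - pivot[1]) + pivot[1]

    wing = ((u - cx) / ax) ** 2 + ((v - cy) / ay) ** 2 <= 1.0
    if wing[0, :].any() or wing[-1, :].any() or wing[:, 0].any() or wing[:, -1].any():
        raise ValueError("wing outline touches the image border; enlarge the canvas")
    region = wing & (v >= lm1_u[1])
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("analysis region is empty")

    # Largest spot radius that keeps the circle inside the outline and below
    # the landmark-1 line (checked analytically on a dense ring of angles).
    def _fits(r: float) -> bool:
        if spot_center[1] - r < lm1_u[1]:
            return False
        ang = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        px = spot_center[0] + r * np.cos(ang)
        py = spot_center[1] + r * np.sin(ang)
        return bool(np.all(((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2 <= 1.0))

    lo, hi = 0.0, min(ax, ay)
    for _ in range(60):
        mid = (lo + hi) / 2
        if _fits(mid):
            lo = mid
        else:
            hi = mid
    r_max = lo

    d2 = (u - spot_center[0]) ** 2 + (v - spot_center[1]) ** 2
    if spec.target_white_fraction > 0:
        target_n = int(round(spec.target_white_fraction * n_region))
        d2_region = np.sort(d2[region])
        max_n = int(np.count_nonzero(d2_region <= r_max**2))
        if target_n > max_n:
            raise ValueError(
                f"target_white_fraction={spec.target_white_fraction:.4f} unattainable "
                f"inside the wing outline; maximum attainable is {max_n / n_region:.4f}"
            )
        if target_n < len(d2_region):
            r_spot2 = (d2_region[target_n - 1] + d2_region[target_n]) / 2.0 if target_n > 0 else -1.0
        else:
            r_spot2 = d2_region[-1] + 1.0
        white = region & (d2 <= r_spot2)
        r_spot = math.sqrt(max(r_spot2, 0.0))
    else:
        white = np.zeros_like(wing)
        r_spot = 0.0

    # Red spots on a ring around the white spot.  Unfused: centre distance
    # guarantees >= 1 background pixel of separation; fused: the circles are
    # tangent, so white and red adjoin with no black border between them.
    red = np.zeros_like(wing)
    if spec.n_red_spots > 0:
        rr = spec.red_spot_radius
        gap = 0.0 if spec.fused else 2.0
        dist = r_spot + rr + gap
        angles = np.linspace(0.0, 2 * np.pi, spec.n_red_spots, endpoint=False) + np.pi / 2
        for a in angles:
            ccx = spot_center[0] + dist * math.cos(a)
            ccy = spot_center[1] + dist * math.sin(a)
            red |= (u - ccx) ** 2 + (v - ccy) ** 2 <= rr**2
        red &= wing
        if spec.fused:
            white = white & ~red  # red scales overlay the fused boundary
        else:
            red &= ~white  # safety; disjoint by construction

    # Assemble the image.
    img = np.empty((h, w, 3), float)
    img[:] = _BACKGROUND
    body = wing & ~white & ~red
    img[body] = _WING_BODY
    img[red] = _RED
    img[white] = _WHITE_BASE
    if white.any():
        speckle = white & (rng.random((h, w)) < _WHITE_SPECKLE_FRACTION)
        img[speckle] = _WHITE_SPECKLE
    if spec.brightness_noise_sd > 0:
        noisy = body | red
        noise = rng.normal(0.0, spec.brightness_noise_sd, size=int(noisy.sum()))
        img[noisy] += noise[:, None]
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    fwd = _rot(theta)
    lm1 = fwd @ (lm1_u - pivot) + pivot
    lm2 = fwd @ (lm2_u - pivot) + pivot
    for p in (lm1, lm2):
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            raise ValueError("landmark rotated outside the image; enlarge the canvas")

    truth = GroundTruth(
        wing_mask=wing,
        white_mask=white,
        red_mask=red,
        analysis_mask=region,
        landmark1=(float(lm1[0]), float(lm1[1])),
        landmark2=(float(lm2[0]), float(lm2[1])),
        true_white_fraction=float((white & region).sum() / n_region),
        true_red_fraction=float((red & region).sum() / n_region),
    )
    return WingImage(pixels), truth


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


class MatingError(RuntimeError):
    """The no-shared-parents/grandparents mating rule cannot be satisfied."""


@dataclass
class PedigreeSimSpec:
    """A laboratory breeding design from wild-mated founder females.

    ``inheritance_mode`` controls transmission of the genetic value of the
    female-limited trait:

    * ``autosomal`` — offspring value = midparent + Mendelian segregation
      noise N(0, genetic_variance/2); founders and wild mates drawn from
      N(0, genetic_variance).
    * ``w_linked`` — daughters copy the mother's value exactly; males carry
      none (the W chromosome is female-specific).
    * ``organelle`` — every offspring copies the mother's value; only
      females express and, in this design, transmit it.

    A second, genetically independent trait (``red_rel``) is simulated with
    the same variance components, providing a pleiotropy-free null for
    cross-trait genetic correlation.
    """

    n_founder_females: int = 16
    n_generations: int = 3
    offspring_per_pair: int = 6
    inheritance_mode: str = "autosomal"
    trait_mean: float = 0.08
    red_trait_mean: float = 0.05
    genetic_variance: float = 2.5e-4
    environmental_variance: float = 2.5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inheritance_mode not in ("autosomal", "w_linked", "organelle"):
            raise ValueError(f"unknown inheritance_mode {self.inheritance_mode!r}")
        if self.genetic_variance < 0 or self.environmental_variance < 0:
            raise ValueError("variances must be >= 0")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.offspring_per_pair < 1:
            raise ValueError("offspring_per_pair must be >= 1")

    @property
    def true_heritability(self) -> float:
        tot = self.genetic_variance + self.environmental_variance
        return self.genetic_variance / tot if tot > 0 else 0.0


def _pair_up(
    ped: Pedigree,
    females: list[str],
    males: list[str],
    rng: np.random.Generator,
    generation: int,
) -> list[tuple[str, str]]:
    """Random monogamous pairing subject to disjoint {parents ∪ grandparents}."""
    anc = {i: ped.ancestors(i, 2) for i in females + males}
    best: list[tuple[str, str]] = []
    n_target = min(len(females), len(males))
    for _ in range(60):
        fs = list(females)
        ms = list(males)
        rng.shuffle(fs)
        rng.shuffle(ms)
        used: set[str] = set()
        pairs: list[tuple[str, str]] = []
        for f in fs:
            for m in ms:
                if m in used:
                    continue
                if anc[f] & anc[m]:
                    continue
                used.add(m)
                pairs.append((f, m))
                break
        if len(pairs) > len(best):
            best = pairs
        if len(best) == n_target:
            break
    if not best:
        lineages = len({next(iter(ped.ancestors(f, generation + 1)), f) for f in females})
        raise MatingError(
            f"mating rule unsatisfiable at generation {generation} "
            f"({lineages} independent lineages available)"
        )
    return best


def simulate_pedigree(spec: PedigreeSimSpec) -> Pedigree:
    """Simulate the breeding design; see :class:`PedigreeSimSpec`.

    Founder females (generation 0) are wild-caught and already mated; their
    wild mates appear as generation-0 males without parents.  Laboratory
    generations 1..n are produced by random monogamous pairing within a
    generation under the rule that mates share neither parents nor
    grandparents.  Female phenotypes are trait_mean + genetic value +
    N(0, environmental_variance); males carry no phenotype.
    """
    if spec.n_founder_females < 2:
        raise MatingError("at least 2 founder lineages are required")
    rng = np.random.default_rng(spec.seed)
    ped = Pedigree()
    gvals: dict[str, tuple[float, float]] = {}  # id -> (g_white, g_red)
    sg = math.sqrt(spec.genetic_variance)
    se = math.sqrt(spec.environmental_variance)
    mode = spec.inheritance_mode

    def _phenotype(ind: Individual) -> None:
        gw, gr = gvals[ind.id]
        ind.white_rel = spec.trait_mean + gw + rng.normal(0.0, se)
        ind.red_rel = spec.red_trait_mean + gr + rng.normal(0.0, se)

    founders: list[str] = []
    wild_mates: list[str] = []
    for i in range(spec.n_founder_females):
        fid, mid = f"G0-F{i:03d}", f"G0-M{i:03d}"
        ped.add(Individual(id=fid, sex="F", generation=0))
        ped.add(Individual(id=mid, sex="M", generation=0))
        gvals[fid] = (rng.normal(0.0, sg), rng.normal(0.0, sg))
        if mode == "autosomal":
            gvals[mid] = (rng.normal(0.0, sg), rng.normal(0.0, sg))
        else:
            gvals[mid] = (0.0, 0.0)
        _phenotype(ped[fid])
        founders.append(fid)
        wild_mates.append(mid)

    def _offspring_g(mother: str, father: str) -> tuple[float, float]:
        gm, gf = gvals[mother], gvals[father]
        if mode == "autosomal":
            seg = math.sqrt(spec.genetic_variance / 2.0)
            return (
                (gm[0] + gf[0]) / 2.0 + rng.normal(0.0, seg),
                (gm[1] + gf[1]) / 2.0 + rng.normal(0.0, seg),
            )
        # w_linked / organelle: exact maternal copy (no mutation over 3 generations)
        return gm

    pairs = list(zip(founders, wild_mates))
    counter = 0
    for gen in range(1, spec.n_generations + 1):
        children: list[Individual] = []
        for mother, father in pairs:
            for _ in range(spec.offspring_per_pair):
                sex = "F" if rng.random() < 0.5 else "M"
                cid = f"G{gen}-{counter:05d}"
                counter += 1
                child = Individual(
                    id=cid, sex=sex, mother_id=mother, father_id=father, generation=gen
                )
                ped.add(child)
                g = _offspring_g(mother, father)
                if mode == "w_linked" and sex == "M":
                    g = (0.0, 0.0)  # males carry no W
                gvals[cid] = g
                if sex == "F":
                    _phenotype(child)
                children.append(child)
        if gen == spec.n_generations:
            break
        females = [c.id for c in children if c.sex == "F"]
        males = [c.id for c in children if c.sex == "M"]
        pairs = _pair_up(ped, females, males, rng, gen)
    return ped


# ---------------------------------------------------------------------------
# Temporal specimen series
# ---------------------------------------------------------------------------


@dataclass
class TemporalSimSpec:
    """A specimen series with a breakpoint in trend and residual variance.

    The mean function is continuous piecewise-linear through
    ``intercept_at_breakpoint`` at ``breakpoint_year`` with slopes
    ``slope_pre``/``slope_post``; residuals are N(0, sd_pre²) up to the
    breakpoint year (inclusive) and N(0, sd_post²) after.  ``n_per_year``
    is either a single count applied to every year or a mapping
    year → count (years absent from the mapping yield no specimens).
    Defaults emulate a five-decade island series in trait-fraction units
    (percent axis ÷ 100): essentially flat before the breakpoint, rising at
    0.045 percentage points per year after, with era residual SDs chosen so
    that, under the historical sampling design, the post-era slope test and
    the variance-ratio test (F ≈ 0.56) operate at the signal-to-noise
    regime the field series showed.
    """

    year_start: int = 1961
    year_end: int = 2016
    breakpoint_year: int = 1993
    slope_pre: float = -0.00005
    slope_post: float = 0.00045
    sd_pre: float = 0.0124
    sd_post: float = 0.0165
    intercept_at_breakpoint: float = 0.055
    n_per_year: Union[int, dict[int, int]] = 2
    island_group: str = "okinawa"
    red_mean: float = 0.05
    red_sd: float = 0.012
    clip_at_zero: bool = True  # spotless specimens exist; fractions cannot go negative
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.year_start <= self.breakpoint_year <= self.year_end):
            raise ValueError("breakpoint_year must lie within [year_start, year_end]")
        if self.sd_pre < 0 or self.sd_post < 0:
            raise ValueError("sd values must be >= 0")

    def mean_at(self, year: float) -> float:
        slope = self.slope_pre if year <= self.breakpoint_year else self.slope_post
        return self.intercept_at_breakpoint + slope * (year - self.breakpoint_year)

    def counts(self) -> dict[int, int]:
        years = range(self.year_start, self.year_end + 1)
        if isinstance(self.n_per_year, int):
            if self.n_per_year <= 0:
                raise ValueError("n_per_year must be positive")
            return {y: self.n_per_year for y in years}
        out = {}
        for y, n in self.n_per_year.items():
            if n <= 0:
                raise ValueError(f"n_per_year for {y} must be positive")
            if self.year_start <= y <= self.year_end:
                out[int(y)] = int(n)
        return out


def simulate_temporal_series(spec: TemporalSimSpec) -> list[SpecimenRecord]:
    """Draw specimen records year by year from the configured trend model."""
    rng = np.random.default_rng(spec.seed)
    records: list[SpecimenRecord] = []
    idx = 0
    for year in sorted(spec.counts()):
        n = spec.counts()[year]
        sd = spec.sd_pre if year <= spec.breakpoint_year else spec.sd_post
        mu = spec.mean_at(year)
        whites = rng.normal(mu, sd, size=n)
        reds = rng.normal(spec.red_mean, spec.red_sd, size=n)
        if spec.clip_at_zero:
            whites = np.maximum(whites, 0.0)
            reds = np.maximum(reds, 0.0)
        for wv, rv in zip(whites, reds):
            records.append(
                SpecimenRecord(
                    id=f"S{idx:05d}",
                    year=int(year),
                    island_group=spec.island_group,
                    white_rel=float(wv),
                    red_rel=float(rv),
                )
            )
            idx += 1
    return records


def pairs_with_correlation(
    r: float,
    n: int = 12,
    lineage: str = "paternal",
    seed: int = 0,
    mean: float = 0.08,
    scale: float = 0.02,
):
    """Grandmother–granddaughter pairs whose sample Pearson correlation is
    exactly ``r`` (to floating-point precision).

    Built by Gram–Schmidt: granddaughter values are ``r`` times the
    standardised grandmother values plus ``sqrt(1−r²)`` times an orthogonal
    unit vector, then mapped affinely onto the trait scale (which leaves the
    correlation unchanged).  Each grandmother appears once, so pairs are
    independent clusters.
    """
    from .heritability import GGPair

    if not (-1.0 <= r <= 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = x - x.mean()
    x /= np.linalg.norm(x)
    z = z - z.mean()
    z -= (z @ x) * x
    z /= np.linalg.norm(z)
    y = r * x + math.sqrt(max(1.0 - r * r, 0.0)) * z
    g = mean + scale * x * math.sqrt(n)
    d = mean + scale * y * math.sqrt(n)
    return [
        GGPair(
            grandmother_id=f"GM{i:03d}",
            granddaughter_id=f"GD{i:03d}",
            lineage=lineage,
            g_value=float(g[i]),
            d_value=float(d[i]),
            family_id=f"GM{i:03d}",
        )
        for i in range(n)
    ]


def historical_series_spec(seed: int = 0) -> TemporalSimSpec:
    """The study-like sampling design: sparse museum holdings before the
    1993 breakpoint (~36 specimens) and dense recent sampling after
    (~331, dominated by 2011–2016 field collections)."""
    pre = {
        1961: 6, 1962: 2, 1966: 1, 1971: 8, 1972: 1, 1973: 1, 1975: 3,
        1980: 1, 1983: 1, 1984: 4, 1986: 2, 1988: 1, 1990: 1, 1991: 4,
    }  # 36
    post = {
        1994: 4, 1995: 6, 1996: 3, 1999: 1, 2005: 8, 2006: 5, 2008: 1,
        2011: 20, 2012: 20, 2013: 26, 2014: 73, 2015: 110, 2016: 54,
    }  # 331
    return TemporalSimSpec(n_per_year={**pre, **post}, seed=seed)
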