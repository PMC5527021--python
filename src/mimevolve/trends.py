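"""Temporal micro-evolution analysis of the mimicry trait.

A historical breakpoint (the arrival year of a new mimicry model species)
splits a multi-decade specimen series into two eras.  The module fits
least-squares regressions of relative white spot size on collection year
separately per era, compares era variances with a two-sided F-test,
checks normality (one-sample Kolmogorov–Smirnov against a normal with the
sample's own mean and SD), compares island groups with a pooled-variance
Student's t-test, and evaluates how much of the mimic series falls inside
the model species' mean ± 2 SD band.

Spot sizes are stored as fractions of the hind-wing analysis area; report
output also carries percentages for plotting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpecimenRecord",
    "EraRegression",
    "VarianceComparison",
    "ModelBand",
    "NormalityResult",
    "GroupComparison",
    "era_regression",
    "compare_variances",
    "normality_check",
    "compare_groups",
    "model_band",
    "band_coverage",
    "run_trend_report",
]


@dataclass
class SpecimenRecord:
    """One measured specimen: collection year, locality group and trait values."""

    id: str
    year: int
    island_group: str
    white_rel: float
    red_rel: Optional[float] = None


@dataclass
class EraRegression:
    """OLS fit of white_rel on year within a closed year window."""

    era_start: int
    era_end: int
    n: int
    slope: float
    intercept: float
    p_value: float
    slope_se: float


@dataclass
class VarianceComparison:
    """Variance-ratio F-test, F = var(A) / var(B), df = (nA−1, nB−1), two-sided p."""

    F: float
    df1: int
    df2: int
    p_value: float


@dataclass
class ModelBand:
    """The model species' mean ± 2 SD band of relative white spot size."""

    model_mean: float
    model_sd: float

    @property
    def low(self) -> float:
        return self.model_mean - 2.0 * self.model_sd

    @property
    def high(self) -> float:
        return self.model_mean + 2.0 * self.model_sd


@dataclass
class NormalityResult:
    """One-sample KS test against a normal with sample-estimated parameters.

    The p-value uses the asymptotic KS distribution and is approximate
    (anticonservative) because the normal's parameters are estimated from
    the same sample; ``approximate`` flags this.
    """

    statistic: float
    p_value: float
    label: str
    n: int
    approximate: bool = True


@dataclass
class GroupComparison:
    """Pooled-variance Student's t comparison of white_rel between two groups."""

    t: float
    p_value: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    window: Optional[tuple[int, int]] = None


def _values(records: Iterable[SpecimenRecord]) -> np.ndarray:
    return np.array([r.white_rel for r in records], dtype=float)


def era_regression(
    records: Sequence[SpecimenRecord], era_start: int, era_end: int
) -> EraRegression:
    """Least-squares regression of white_rel on year over the closed window.

    The p-value is that of the slope (the F statistic of the regression,
    identical to the squared slope t)."""
    sel = [r for r in records if era_start <= r.year <= era_end]
    if len(sel) < 3:
        raise ValueError(
            f"need >= 3 records in [{era_start}, {era_end}], found {len(sel)}"
        )
    years = np.array([r.year for r in sel], float)
    vals = _values(sel)
    if np.unique(years).size < 2:
        raise ValueError("need at least 2 distinct years for a regression")
    if np.allclose(vals, vals[0]):
        # constant response: slope exactly 0, no evidence against it
        return EraRegression(era_start, era_end, len(sel), 0.0, float(vals[0]), 1.0, 0.0)
    fit = stats.linregress(years, vals)
    return EraRegression(
        era_start=era_start,
        era_end=era_end,
        n=len(sel),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        slope_se=float(fit.stderr),
    )


def compare_variances(
    records_a: Sequence[SpecimenRecord] | np.ndarray,
    records_b: Sequence[SpecimenRecord] | np.ndarray,
) -> VarianceComparison:
    """Two-sided F-test of equal variances, oriented as var(A)/var(B)."""
    a = np.asarray(records_a, float) if not _is_records(records_a) else _values(records_a)
    b = np.asarray(records_b, float) if not _is_records(records_b) else _values(records_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2 for an F-test")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0.0:
        raise ValueError("zero variance in the denominator sample")
    F = va / vb
    df1, df2 = a.size - 1, b.size - 1
    cdf = stats.f.cdf(F, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return VarianceComparison(F=F, df1=df1, df2=df2, p_value=float(min(p, 1.0)))


def _is_records(x) -> bool:
    return len(x) > 0 and isinstance(x[0], SpecimenRecord) if hasattr(x, "__len__") else False


def normality_check(values: Sequence[float] | np.ndarray, label: str = "") -> NormalityResult:
    """One-sample KS test against N(sample mean, sample SD)."""
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError(f"need n >= 5 for the KS normality check, got {v.size}")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance sample")
    res = stats.kstest(v, "norm", args=(float(np.mean(v)), sd))
    return NormalityResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), label=label, n=int(v.size)
    )


def compare_groups(
    records_a: Sequence[SpecimenRecord],
    records_b: Sequence[SpecimenRecord],
    window: Optional[tuple[int, int]] = None,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Pooled-variance Student's t-test on white_rel, optionally within a year window."""
    if window is not None:
        lo, hi = window
        records_a = [r for r in records_a if lo <= r.year <= hi]
        records_b = [r for r in records_b if lo <= r.year <= hi]
    a, b = _values(records_a), _values(records_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2 within the window")
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        group_a=labels[0],
        group_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        window=window,
    )


def model_band(model_values: Sequence[float] | np.ndarray) -> ModelBand:
    """Mean ± 2 sample SD band of the model species' white spot sizes."""
    v = np.asarray(model_values, float)
    if v.size < 2:
        raise ValueError("need at least 2 model values for a band")
    return ModelBand(model_mean=float(np.mean(v)), model_sd=float(np.std(v, ddof=1)))


def band_coverage(records: Sequence[SpecimenRecord], band: ModelBand) -> float:
    """Fraction of records whose white_rel lies inside the closed band."""
    v = _values(records)
    if v.size == 0:
        raise ValueError("no records to evaluate band coverage on")
    return float(np.mean((v >= band.low) & (v <= band.high)))


@dataclass
class BreakpointConfig:
    """Era windows around the model-arrival breakpoint.

    Default windows exclude the arrival gap itself (e.g. 1992–1993): the
    'before' era runs to ``pre_end`` and the 'after' era starts at
    ``post_start``; records between them are counted as unassigned.
    """

    pre_end: int = 1991
    post_start: int = 1994


def run_trend_report(
    records: Sequence[SpecimenRecord],
    breakpoint_config: Optional[BreakpointConfig] = None,
    model_values: Optional[Sequence[float]] = None,
) -> dict:
    """Compose the full temporal analysis into a JSON-serialisable report."""
    if not records:
        raise ValueError("no specimen records supplied")
    cfg = breakpoint_config or BreakpointConfig()
    years = [r.year for r in records]
    y0, y1 = min(years), max(years)

    pre = [r for r in records if r.year <= cfg.pre_end]
    post = [r for r in records if r.year >= cfg.post_start]
    unassigned = len(records) - len(pre) - len(post)

    def _reg_dict(sel: list[SpecimenRecord], start: int, end: int) -> Optional[dict]:
        try:
            reg = era_regression(sel, start, end)
        except ValueError:
            return None
        return {
            "era_start": reg.era_start,
            "era_end": reg.era_end,
            "n": reg.n,
            "slope": reg.slope,
            "slope_percent_per_year": reg.slope * 100.0,
            "intercept": reg.intercept,
            "p_value": reg.p_value,
            "slope_se": reg.slope_se,
        }

    report: dict = {
        "n_records": len(records),
        "year_range": [y0, y1],
        "eras": {
            "pre": {"window": [y0, cfg.pre_end], "n": len(pre)},
            "post": {"window": [cfg.post_start, y1], "n": len(post)},
            "unassigned": unassigned,
        },
        "regressions": {
            "pre": _reg_dict(pre, y0, cfg.pre_end),
            "post": _reg_dict(post, cfg.post_start, y1),
        },
    }

    if len(pre) >= 2 and len(post) >= 2 and np.var(_values(post), ddof=1) > 0:
        vc = compare_variances(pre, post)
        report["variance_comparison"] = {
            "F": vc.F,
            "df1": vc.df1,
            "df2": vc.df2,
            "p_value": vc.p_value,
            "orientation": "var(pre)/var(post)",
        }
    else:
        report["variance_comparison"] = None

    report["normality"] = {}
    for label, sel in (("pre", pre), ("post", post), ("all", list(records))):
        try:
            nr = normality_check(_values(sel), label=label)
            report["normality"][label] = {
                "D": nr.statistic,
                "p_value": nr.p_value,
                "n": nr.n,
                "approximate": nr.approximate,
            }
        except ValueError:
            report["normality"][label] = None

    if model_values is not None:
        band = model_band(model_values)
        report["model_band"] = {
            "mean": band.model_mean,
            "sd": band.model_sd,
            "low": band.low,
            "high": band.high,
        }
        report["band_coverage"] = {
            "pre": band_coverage(pre, band) if pre else None,
            "post": band_coverage(post, band) if post else None,
            "all": band_coverage(list(records), band),
        }
    else:
        report["model_band"] = None
        report["band_coverage"] = None
    return report
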