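"""Competitive enzyme-immunoassay calibration and validation statistics.

Covers the full QC battery around a blubber cortisol EIA: four-parameter
logistic (4PL) standard curves and their inverse, conversion of assay
concentrations to tissue concentrations with an extraction-efficiency
correction, sensitivity from the zero-standard wells, intra/inter-assay
CVs, a bootstrapped slope-ratio parallelism test on serial dilutions, a
spike-volume matrix-interference regression, and a storage-time regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logit

__all__ = [
    "StandardCurve",
    "DilutionSeries",
    "ParallelismResult",
    "InterferenceResult",
    "RegressionResult",
    "AssayRangeError",
    "CurveFitError",
    "fit_standard_curve",
    "interpolate_concentration",
    "required_dilution",
    "blubber_concentration",
    "extraction_efficiency",
    "extraction_efficiency_batch",
    "sensitivity",
    "replicate_cv",
    "assay_cv",
    "parallelism_test",
    "matrix_interference_test",
    "storage_regression",
]

# Protocol constants: tissue resuspended in 250 uL buffer, extraction
# controls spiked with 200 ng cortisol, default recovery 68.5%.
RESUSPENSION_VOLUME_ML = 0.25
SPIKE_AMOUNT_NG = 200.0
DEFAULT_EFFICIENCY = 0.685
ASSAY_RANGE_PG_ML = (100.0, 3200.0)
WORKING_RANGE_PG_ML = (200.0, 2000.0)


class AssayRangeError(ValueError):
    """A response or concentration falls outside the usable curve range."""


class CurveFitError(RuntimeError):
    """The 4PL fit failed; carries the residuals when available."""


@dataclass
class StandardCurve:
    """Decreasing 4PL: OD = bottom + (top-bottom) / (1 + (c/mid)^slope)."""

    bottom: float
    top: float
    midpoint_conc: float
    hill_slope: float
    fit_residual_ss: float = 0.0

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("4PL top asymptote must exceed bottom")
        if not self.midpoint_conc > 0:
            raise ValueError("4PL midpoint concentration must be positive")
        if not self.hill_slope > 0:
            raise ValueError("4PL hill slope must be positive for a decreasing curve")

    def forward(self, concentration):
        """OD response at a concentration (vectorized)."""
        c = np.asarray(concentration, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        resp = self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.midpoint_conc) ** self.hill_slope
        )
        return float(resp) if np.isscalar(concentration) else resp

    @property
    def midpoint_od(self) -> float:
        return 0.5 * (self.top + self.bottom)


def _fourpl(c, bottom, top, mid, slope):
    return bottom + (top - bottom) / (1.0 + (c / mid) ** slope)


def fit_standard_curve(
    concentrations: Sequence[float], responses: Sequence[float]
) -> StandardCurve:
    """Least-squares 4PL fit of OD against standard concentration.

    Zero-concentration (B0) wells are legal inputs and pin the top
    asymptote.  Requires at least five standards.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if c.size < 5:
        raise ValueError(f"need >= 5 standards to fit a 4PL, got {c.size}")
    if np.ptp(y) == 0:
        raise CurveFitError("responses are constant; cannot fit a curve")
    pos = c[c > 0]
    if pos.size < 2:
        raise ValueError("need >= 2 non-zero standard concentrations")

    top0 = float(y.max())
    bottom0 = float(y.min())
    mid0 = float(np.exp(np.mean(np.log(pos))))
    p0 = (bottom0, top0, mid0, 1.0)
    bounds = (
        [-np.inf, -np.inf, 1e-12, 1e-3],
        [np.inf, np.inf, np.inf, 100.0],
    )
    try:
        popt, _ = optimize.curve_fit(_fourpl, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise CurveFitError(f"4PL fit did not converge: {exc}") from exc
    resid = y - _fourpl(c, *popt)
    if popt[1] <= popt[0]:
        raise CurveFitError(
            f"fitted curve is not decreasing (top {popt[1]:.4g} <= bottom "
            f"{popt[0]:.4g}); residual SS {float(resid @ resid):.4g}"
        )
    return StandardCurve(
        bottom=float(popt[0]),
        top=float(popt[1]),
        midpoint_conc=float(popt[2]),
        hill_slope=float(popt[3]),
        fit_residual_ss=float(resid @ resid),
    )


def interpolate_concentration(curve: StandardCurve, response: float) -> float:
    """Invert the 4PL at one OD; the response must lie between asymptotes.

    Out-of-range responses raise :class:`AssayRangeError` — the sample must
    be diluted further and re-run.
    """
    if not (curve.bottom < response < curve.top):
        raise AssayRangeError(
            f"response {response:.4g} outside the curve's open range "
            f"({curve.bottom:.4g}, {curve.top:.4g}); dilute the sample and re-assay"
        )
    ratio = (curve.top - curve.bottom) / (response - curve.bottom) - 1.0
    return float(curve.midpoint_conc * ratio ** (1.0 / curve.hill_slope))


def required_dilution(
    curve: StandardCurve,
    response: float,
    working_range: tuple[float, float] = WORKING_RANGE_PG_ML,
) -> float:
    """Smallest power-of-two dilution bringing a hot sample on-range.

    For a response below the quantifiable window (i.e. concentration above
    it), returns the factor by which to dilute; returns 1.0 when already
    within range.
    """
    low, high = working_range
    if curve.bottom < response < curve.top:
        conc = interpolate_concentration(curve, response)
        if conc <= high:
            return 1.0
    else:
        conc = math.inf  # saturated well: concentration beyond the curve
    factor = 1.0
    while conc / factor > high:
        factor *= 2.0
        if factor > 2**20:
            raise AssayRangeError("sample cannot be brought on-range by dilution")
    return factor


# ---------------------------------------------------------------------------
# Concentration arithmetic
# ---------------------------------------------------------------------------

def blubber_concentration(
    assay_conc: float,
    resuspension_volume: float = RESUSPENSION_VOLUME_ML,
    dilution_factor: float = 1.0,
    tissue_mass: float = 0.1,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """Convert an assay concentration (pg/mL) to tissue ng/g.

    ng/g = pg/mL x mL resuspension x dilution / efficiency / g tissue / 1000.
    The division by the extraction efficiency corrects for incomplete
    recovery of cortisol through the solvent extraction.
    """
    if not tissue_mass > 0:
        raise ValueError("tissue mass must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return assay_conc * resuspension_volume * dilution_factor / efficiency / tissue_mass / 1000.0


def extraction_efficiency(
    spiked_measured: float,
    unspiked_measured: float,
    spike_amount: float = SPIKE_AMOUNT_NG,
) -> float:
    """Fraction of a known cortisol spike recovered through extraction.

    (spiked - unspiked) / spike.  A negative recovery is reported as-is
    with a warning rather than clamped.
    """
    if not spike_amount > 0:
        raise ValueError("spike amount must be positive")
    value = (spiked_measured - unspiked_measured) / spike_amount
    if value < 0:
        warnings.warn(
            f"negative extraction efficiency {value:.3f}; check spike bookkeeping",
            stacklevel=2,
        )
    return value


def extraction_efficiency_batch(
    spiked: Sequence[float],
    unspiked: Sequence[float],
    spike_amount: float = SPIKE_AMOUNT_NG,
) -> tuple[float, float]:
    """Mean and sample SD of per-run extraction efficiencies."""
    effs = [extraction_efficiency(s, u, spike_amount) for s, u in zip(spiked, unspiked, strict=True)]
    arr = np.asarray(effs)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def sensitivity(
    zero_standard_ods: Sequence[float],
    curve: StandardCurve,
    tissue_mass: float = 0.1,
    resuspension_volume: float = RESUSPENSION_VOLUME_ML,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """Assay sensitivity in pg cortisol per g blubber.

    The detection threshold is the OD at mean + 2 SD of the zero-standard
    (B0) wells; the concentration interpolated there is converted to a
    per-gram tissue amount for the stated tissue mass.
    """
    ods = np.asarray(zero_standard_ods, dtype=float)
    if ods.size < 2:
        raise ValueError("need >= 2 zero-standard runs")
    threshold = float(ods.mean() + 2.0 * ods.std(ddof=1))
    conc = interpolate_concentration(curve, threshold)  # pg/mL
    return conc * resuspension_volume / efficiency / tissue_mass


# ---------------------------------------------------------------------------
# Coefficients of variation
# ---------------------------------------------------------------------------

def replicate_cv(values: Sequence[float]) -> float:
    """Percent CV of one replicate set: 100 x sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("replicate mean is zero; CV undefined")
    return float(100.0 * arr.std(ddof=1) / mean)


def assay_cv(replicate_sets: Sequence[Sequence[float]]) -> tuple[list[float], float]:
    """Per-set CVs and their pooled (root-mean-square) value.

    Feed within-plate replicate sets for the intra-assay CV, or the same
    control measured across plates for the inter-assay CV.
    """
    cvs = [replicate_cv(s) for s in replicate_sets]
    pooled = float(np.sqrt(np.mean(np.square(cvs))))
    return cvs, pooled


# ---------------------------------------------------------------------------
# Parallelism
# ---------------------------------------------------------------------------

@dataclass
class DilutionSeries:
    """Replicate B/B0 responses over a dilution (or spike-volume) ladder.

    ``labels`` are relative concentrations: 1 for neat, 0.5 for a 1/2
    dilution, and so on.
    """

    labels: tuple[float, ...]
    replicate_responses: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.replicate_responses):
            raise ValueError("one replicate tuple per label required")
        if len(set(self.labels)) < 3:
            raise ValueError("need >= 3 distinct dilution levels")
        if any(lab <= 0 for lab in self.labels):
            raise ValueError("dilution labels must be positive")
        for lab, reps in zip(self.labels, self.replicate_responses):
            if len(reps) < 1:
                raise ValueError(f"level {lab} has no replicates")

    @property
    def replicate_counts(self) -> tuple[int, ...]:
        return tuple(len(r) for r in self.replicate_responses)


@dataclass
class ParallelismResult:
    slope_ratio: float
    ci_low: float
    ci_high: float
    r_squared: float
    parallel: bool
    sample_slope: float = 0.0
    standard_slope: float = 0.0
    n_boot: int = 0


def _linearize(series: DilutionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Flatten to (log2 relative concentration, logit B/B0) point pairs."""
    xs: list[float] = []
    ys: list[float] = []
    for lab, reps in zip(series.labels, series.replicate_responses):
        for r in reps:
            if not 0 < r < 1:
                raise ValueError(f"B/B0 response {r} outside (0, 1); cannot linearize")
            xs.append(math.log2(lab))
            ys.append(float(logit(r)))
    return np.asarray(xs), np.asarray(ys)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, r^2) by least squares; degenerate x raises."""
    if np.ptp(x) == 0:
        raise ValueError("predictor has no spread")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2


def parallelism_test(
    sample_series: DilutionSeries,
    standard_series: DilutionSeries,
    n_boot: int = 1000,
    seed: int = 0,
) -> ParallelismResult:
    """Bootstrapped slope-ratio parallelism test.

    Both series are linearized as logit(B/B0) against log2 relative
    concentration, a straight line is fitted to each, and the ratio of
    sample (observed) to standard (expected) slope is returned with a
    percentile bootstrap CI built by resampling replicates within levels.
    The assay behaves parallel when the CI covers 1.
    """
    for s in (sample_series, standard_series):
        if min(s.replicate_counts) < 2:
            raise ValueError("parallelism requires >= 2 replicates per level")
    xs_s, ys_s = _linearize(sample_series)
    xs_t, ys_t = _linearize(standard_series)
    slope_s, r2_s = _ols_slope(xs_s, ys_s)
    slope_t, _ = _ols_slope(xs_t, ys_t)
    if slope_t == 0:
        raise ValueError("standard series has zero slope; ratio undefined")
    ratio = slope_s / slope_t

    degenerate = all(
        len(set(reps)) == 1
        for series in (sample_series, standard_series)
        for reps in series.replicate_responses
    )
    if degenerate and n_boot > 0:
        warnings.warn(
            "all replicate sets are identical; bootstrap CI is degenerate",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _boot_ratio(sample_series, standard_series, rng)
    if n_boot > 0:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low = float(min(ci_low, ratio))
        ci_high = float(max(ci_high, ratio))
    else:
        ci_low = ci_high = ratio
    return ParallelismResult(
        slope_ratio=ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        r_squared=r2_s,
        parallel=ci_low <= 1.0 <= ci_high,
        sample_slope=slope_s,
        standard_slope=slope_t,
        n_boot=n_boot,
    )


def _resample_series(series: DilutionSeries, rng: np.random.Generator) -> DilutionSeries:
    reps = tuple(
        tuple(rng.choice(r, size=len(r), replace=True)) for r in series.replicate_responses
    )
    return DilutionSeries(labels=series.labels, replicate_responses=reps)


def _boot_ratio(
    sample_series: DilutionSeries,
    standard_series: DilutionSeries,
    rng: np.random.Generator,
) -> float:
    xs_s, ys_s = _linearize(_resample_series(sample_series, rng))
    xs_t, ys_t = _linearize(_resample_series(standard_series, rng))
    s, _ = _ols_slope(xs_s, ys_s)
    t, _ = _ols_slope(xs_t, ys_t)
    return s / t if t != 0 else math.nan


# ---------------------------------------------------------------------------
# Matrix interference and storage regressions
# ---------------------------------------------------------------------------

@dataclass
class InterferenceResult:
    slope: float  # pg deviation per uL extract added
    r_squared: float
    p_value: float
    intercept: float = 0.0
    deviations: tuple[float, ...] = field(default_factory=tuple)


def matrix_interference_test(
    spike_volumes: Sequence[float],
    measured: Sequence[float],
    expected_added: float = 48.0,
    pool_neat_concentration: float = 56.5,
) -> InterferenceResult:
    """Regression of measurement deviation on extract volume added.

    Each well received ``expected_added`` pg of standard plus
    ``volume`` uL of pooled extract whose own cortisol contribution
    (volume x neat concentration, pg/mL over 1000 uL/mL) is subtracted.
    A slope distinguishable from 0 indicates matrix interference.
    """
    vols = np.asarray(spike_volumes, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if vols.shape != meas.shape:
        raise ValueError("spike_volumes and measured must have equal length")
    if np.unique(vols).size < 3:
        raise ValueError("need >= 3 distinct spike volumes")
    pool_contrib = vols * pool_neat_concentration / 1000.0  # uL x pg/mL -> pg
    deviation = meas - expected_added - pool_contrib
    # constant response up to rounding: flat fit, r undefined
    if np.ptp(deviation) <= 1e-12 * max(1.0, float(np.abs(meas).max())):
        return InterferenceResult(
            slope=0.0, r_squared=0.0, p_value=1.0,
            intercept=float(deviation.mean()), deviations=tuple(deviation),
        )
    res = stats.linregress(vols, deviation)
    return InterferenceResult(
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        intercept=float(res.intercept),
        deviations=tuple(deviation),
    )


@dataclass
class RegressionResult:
    slope: float
    r_squared: float
    p_value: float
    n: int
    underdetermined: bool = False


def storage_regression(
    storage_days: Sequence[float], cortisol: Sequence[float]
) -> RegressionResult:
    """OLS of cortisol concentration on frozen-storage time."""
    x = np.asarray(storage_days, dtype=float)
    y = np.asarray(cortisol, dtype=float)
    if x.shape != y.shape:
        raise ValueError("storage_days and cortisol must have equal length")
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    if np.ptp(x) == 0:
        raise ValueError("storage time is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue) if x.size > 2 else 1.0,
        n=int(x.size),
        underdetermined=x.size <= 2,
    )
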