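"""Circular three-month running means and their permutation null envelope.

A month's value is the average of the three 3-month window means that
contain it (windows wrap across the year boundary, so the
December-January-February window exists).  The null keeps each month's
sample count fixed and shuffles the cortisol values across specimens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import SpecimenRecord

__all__ = [
    "SeasonalityResult",
    "monthly_running_means",
    "permutation_envelope",
    "inject_seasonal_effect",
]


@dataclass
class SeasonalityResult:
    observed: np.ndarray  # (12,), January first; NaN where undefined
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    per_month_n: np.ndarray  # (12,) ints
    n_permutations: int
    outside_months: list[int]  # 1-based months where observed exits the envelope
    seed: int
    null_mean: np.ndarray | None = None  # per-month mean of the null matrix

    @property
    def null_matrix_shape(self) -> tuple[int, int]:
        return (12, self.n_permutations)


def _month_stats(values: np.ndarray, months: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-month sums and counts; ``months`` are 0-based."""
    sums = np.bincount(months, weights=values, minlength=12)[:12]
    counts = np.bincount(months, minlength=12)[:12]
    return sums, counts.astype(float)


def _running_from_sums(month_sums: np.ndarray, month_counts: np.ndarray) -> np.ndarray:
    """Running means from per-month sums/counts.

    Works on stacked inputs: the month axis must be last.  Window w starts
    at month w and pools months w, w+1, w+2 (circular); the running mean of
    month m averages the window means starting at m-2, m-1 and m.  Any
    empty contributing window makes the month NaN.
    """
    wsum = month_sums + np.roll(month_sums, -1, axis=-1) + np.roll(month_sums, -2, axis=-1)
    wcount = month_counts + np.roll(month_counts, -1, axis=-1) + np.roll(month_counts, -2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = np.where(wcount > 0, wsum / np.where(wcount > 0, wcount, 1.0), np.nan)
    return (wmean + np.roll(wmean, 1, axis=-1) + np.roll(wmean, 2, axis=-1)) / 3.0


def _values_and_months(records: Sequence[SpecimenRecord]) -> tuple[np.ndarray, np.ndarray]:
    dated = [r for r in records if r.collection_month is not None]
    if not dated:
        raise ValueError("no records carry a collection month")
    values = np.array([r.cortisol for r in dated])
    months = np.array([r.collection_month - 1 for r in dated])
    return values, months


def monthly_running_means(records: Sequence[SpecimenRecord]) -> np.ndarray:
    """Twelve circular running means (January first); NaN where any of the
    three contributing windows holds no samples."""
    values, months = _values_and_months(records)
    sums, counts = _month_stats(values, months)
    return _running_from_sums(sums, counts)


def permutation_envelope(
    records: Sequence[SpecimenRecord],
    n_permutations: int = 10_000,
    seed: int = 0,
    restrict_to: str | None = "stranded",
) -> SeasonalityResult:
    """Observed running means with a month-wise 95% permutation envelope.

    Cortisol values are shuffled across specimens while the month label
    multiset stays fixed, the running means are recomputed for each of the
    ``n_permutations`` shuffles, and the envelope is the per-month
    2.5/97.5 percentile band of that null.  By default only stranded
    specimens enter (bycatch sampling is confined to the fishing season);
    pass ``restrict_to=None`` to use every dated record.
    """
    if restrict_to is not None:
        records = [r for r in records if r.fatality_type == restrict_to]
    values, months = _values_and_months(records)
    populated = np.unique(months)
    if populated.size < 2:
        raise ValueError("need records in at least 2 distinct months")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100 gives unstable envelope percentiles",
            stacklevel=2,
        )

    sums, counts = _month_stats(values, months)
    observed = _running_from_sums(sums, counts)

    rng = np.random.default_rng(seed)
    perm_values = rng.permuted(np.tile(values, (n_permutations, 1)), axis=1)
    onehot = np.zeros((values.size, 12))
    onehot[np.arange(values.size), months] = 1.0
    perm_sums = perm_values @ onehot  # (n_permutations, 12)
    null = _running_from_sums(perm_sums, np.broadcast_to(counts, perm_sums.shape))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        low = np.nanpercentile(null, 2.5, axis=0)
        high = np.nanpercentile(null, 97.5, axis=0)
        null_mean = np.nanmean(null, axis=0)

    outside = [
        m + 1
        for m in range(12)
        if math.isfinite(observed[m])
        and math.isfinite(low[m])
        and not (low[m] <= observed[m] <= high[m])
    ]
    return SeasonalityResult(
        observed=observed,
        envelope_low=low,
        envelope_high=high,
        per_month_n=counts.astype(int),
        n_permutations=n_permutations,
        outside_months=outside,
        seed=seed,
        null_mean=null_mean,
    )


def inject_seasonal_effect(
    records: Sequence[SpecimenRecord], amplitude: float, peak_month: int
) -> list[SpecimenRecord]:
    """Add a sinusoidal month effect (power-analysis helper).

    Each dated record gains ``amplitude * cos(2 pi (month - peak) / 12)``;
    results are floored just above zero to keep cortisol valid.  Undated
    records pass through unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if peak_month not in range(1, 13):
        raise ValueError(f"peak_month must be 1-12, got {peak_month}")
    out = []
    for rec in records:
        if rec.collection_month is None or amplitude == 0:
            out.append(rec)
            continue
        shift = amplitude * math.cos(2.0 * math.pi * (rec.collection_month - peak_month) / 12.0)
        out.append(replace(rec, cortisol=max(rec.cortisol + shift, 1e-9)))
    return out
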