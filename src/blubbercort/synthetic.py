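"""Synthetic specimen cohorts and immunoassay plates.

Generates cohorts with the statistical structure the analyses assume: two
fatality groups with lognormal cortisol (the stranded group higher-mean
and higher-variance), demographic classes in realistic proportions, and
group-specific sampling seasons (bycatch confined to the fishing season,
strandings year-round with a spring/summer skew).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay_qc import DilutionSeries, StandardCurve
from .data_model import SpecimenRecord, classify_maturity, covariate_value

__all__ = [
    "CohortConfig",
    "DemographicProportions",
    "generate_cohort",
    "generate_plate",
    "generate_dilution_series",
    "DEFAULT_STANDARD_CURVE",
]

#: A plausible competitive-EIA calibration spanning the 100-3200 pg/mL
#: assay range, used as the default fixture curve.
DEFAULT_STANDARD_CURVE = StandardCurve(
    bottom=0.08, top=1.0, midpoint_conc=600.0, hill_slope=1.1
)


def _normalized(weights: dict[int, float]) -> dict[int, float]:
    total = sum(weights.values())
    return {m: w / total for m, w in weights.items()}


# Bycatch collections happen during the active gillnetting season,
# September through January.
BYCATCH_MONTH_WEIGHTS = _normalized({9: 1.0, 10: 1.0, 11: 1.0, 12: 1.0, 1: 1.0})

# Strandings occur year-round with a mild spring/summer peak.
STRANDED_MONTH_WEIGHTS = _normalized(
    {m: (1.6 if 3 <= m <= 8 else 1.0) for m in range(1, 13)}
)


@dataclass
class DemographicProportions:
    """Class frequencies mirroring the bycatch cohort's composition:
    22 female (6 immature; mature split 5 resting / 6 lactating /
    6 pregnant) to 18 male (8 immature, 10 mature)."""

    p_female: float = 22.0 / 40.0
    p_mature_female: float = 16.0 / 22.0
    p_mature_male: float = 10.0 / 18.0
    mature_female_classes: dict[str, float] = field(
        default_factory=lambda: {"resting": 5.0, "lactating": 6.0, "pregnant": 6.0}
    )

    def validate(self) -> None:
        for name in ("p_female", "p_mature_female", "p_mature_male"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(w < 0 for w in self.mature_female_classes.values()):
            raise ValueError("mature female class weights must be >= 0")
        if sum(self.mature_female_classes.values()) <= 0:
            raise ValueError("mature female class weights must sum > 0")


@dataclass
class CohortConfig:
    n_stranded: int = 23
    n_bycaught: int = 40
    stranded_mean: float = 24.3  # arithmetic mean ng/g
    bycaught_mean: float = 3.99
    stranded_log_sd: float = 1.0
    bycaught_log_sd: float = 0.55
    demographics: DemographicProportions = field(default_factory=DemographicProportions)
    bycatch_month_weights: dict[int, float] = field(
        default_factory=lambda: dict(BYCATCH_MONTH_WEIGHTS)
    )
    stranded_month_weights: dict[int, float] = field(
        default_factory=lambda: dict(STRANDED_MONTH_WEIGHTS)
    )
    condition_code_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.4, 3: 0.3, 4: 0.2}
    )
    #: Remove the in-sample projection of log-cortisol onto the null
    #: demographic covariates within each fatality group, so the cohort —
    #: like the study cohort — carries no chance association between
    #: cortisol and any factor other than fatality type.
    decorrelate_nulls: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_stranded < 0 or self.n_bycaught < 0:
            raise ValueError("group sizes must be >= 0")
        if not (self.stranded_mean > 0 and self.bycaught_mean > 0):
            raise ValueError("group means must be positive")
        if not (self.stranded_log_sd > 0 and self.bycaught_log_sd > 0):
            raise ValueError("log-scale SDs must be positive")
        self.demographics.validate()
        for name in ("bycatch_month_weights", "stranded_month_weights", "condition_code_weights"):
            weights = getattr(self, name)
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ValueError(f"{name} must hold non-negative weights summing > 0")
        if any(m not in range(1, 13) for m in self.bycatch_month_weights):
            raise ValueError("bycatch month weights carry an invalid month")
        if any(m not in range(1, 13) for m in self.stranded_month_weights):
            raise ValueError("stranded month weights carry an invalid month")
        if any(c not in (1, 2, 3, 4) for c in self.condition_code_weights):
            raise ValueError("condition codes must be 1-4")


def _lognormal_mu(arithmetic_mean: float, log_sd: float) -> float:
    """Log-scale location giving the requested arithmetic mean:
    mu = ln(mean) - sd^2 / 2."""
    return math.log(arithmetic_mean) - 0.5 * log_sd**2


def _draw_month(weights: dict[int, float], rng: np.random.Generator) -> int:
    months = sorted(weights)
    p = np.array([weights[m] for m in months], dtype=float)
    return int(rng.choice(months, p=p / p.sum()))


def _make_record(
    idx: int,
    fatality: str,
    cortisol: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SpecimenRecord:
    demo = config.demographics
    sex = "female" if rng.random() < demo.p_female else "male"

    # Draw the raw maturity criterion for the intended class and let the
    # classifier assign the label, keeping field and criterion consistent.
    if sex == "male":
        mature_intent = rng.random() < demo.p_mature_male
        testis = float(rng.normal(420.0, 80.0)) if mature_intent else float(rng.uniform(10.0, 190.0))
        testis = max(testis, 210.0) if mature_intent else testis
        maturity = classify_maturity("male", right_testis_mass=testis)
    else:
        mature_intent = rng.random() < demo.p_mature_female
        corpora = int(rng.integers(2, 15)) if mature_intent else int(rng.integers(0, 2))
        maturity = classify_maturity("female", corpora_count=corpora)

    pregnancy = "no"
    lactation = "no"
    if sex == "female" and maturity == "mature":
        classes = list(demo.mature_female_classes)
        w = np.array([demo.mature_female_classes[c] for c in classes], dtype=float)
        cls = str(rng.choice(classes, p=w / w.sum()))
        pregnancy = "yes" if cls == "pregnant" else "no"
        lactation = "yes" if cls == "lactating" else "no"

    if maturity == "mature":
        length = float(rng.normal(185.0, 12.0))
    else:
        length = float(rng.normal(140.0, 20.0))
    length = max(length, 80.0)
    adrenal = max(float(rng.normal(2.5, 0.6)), 0.5)

    if fatality == "stranded":
        month = _draw_month(config.stranded_month_weights, rng)
        codes = sorted(config.condition_code_weights)
        cw = np.array([config.condition_code_weights[c] for c in codes], dtype=float)
        condition = int(rng.choice(codes, p=cw / cw.sum()))
        prefix = "SYN-S"
    else:
        month = _draw_month(config.bycatch_month_weights, rng)
        condition = None
        prefix = "SYN-B"

    return SpecimenRecord(
        specimen_id=f"{prefix}-{idx:03d}",
        fatality_type=fatality,
        cortisol=cortisol,
        condition_code=condition,
        total_length=round(length, 1),
        sex=sex,
        maturity=maturity,
        pregnancy=pregnancy,
        lactation=lactation,
        adrenal_mass=round(adrenal, 2),
        collection_month=month,
        storage_days=float(rng.integers(30, 5000)),
    )


def generate_cohort(config: CohortConfig | None = None) -> list[SpecimenRecord]:
    """Draw a reproducible cohort of stranded plus bycaught specimens.

    Cortisol is lognormal per group with the log-location calibrated so the
    arithmetic mean matches the configured group mean.  Demographics are
    independent of cortisol, i.e. fatality type is the only real effect.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    records: list[SpecimenRecord] = []
    groups: list[tuple[str, float, float, list[int]]] = []
    for group, n, mean, log_sd in (
        ("stranded", config.n_stranded, config.stranded_mean, config.stranded_log_sd),
        ("bycatch", config.n_bycaught, config.bycaught_mean, config.bycaught_log_sd),
    ):
        mu = _lognormal_mu(mean, log_sd)
        cortisol = rng.lognormal(mu, log_sd, size=n)
        idx = []
        for i in range(n):
            idx.append(len(records))
            records.append(_make_record(i + 1, group, float(cortisol[i]), config, rng))
        groups.append((group, mu, log_sd, idx))
    if config.decorrelate_nulls:
        for _, mu, log_sd, idx in groups:
            _decorrelate_group(records, idx, mu, log_sd)
    return records


_NULL_FACTORS = ("condition", "length", "sex", "maturity", "pregnancy", "lactation", "adrenal_mass")


def _decorrelate_group(
    records: list[SpecimenRecord], idx: list[int], mu: float, log_sd: float
) -> None:
    """Make log-cortisol exactly orthogonal, in-sample, to the null
    covariates within one fatality group, with log-mean ``mu`` and
    log-scale SD ``log_sd`` held exact.

    The marginal cortisol distribution stays lognormal in shape; only the
    chance in-sample correlations that a finite draw produces are removed,
    mirroring a cohort in which fatality type is the sole real signal.
    """
    n = len(idx)
    cols = []
    for f in _NULL_FACTORS:
        vals = np.array(
            [covariate_value(records[i], f) for i in idx], dtype=float
        )
        vals = np.nan_to_num(vals, nan=0.0)  # inapplicable cells: constant
        if np.ptp(vals) > 0:
            cols.append(vals)
    z = np.log([records[i].cortisol for i in idx])
    design = np.column_stack([np.ones(n)] + cols)
    if n <= design.shape[1] + 1:
        return  # too few rows to orthogonalize; leave the raw draws
    q, _ = np.linalg.qr(design)
    resid = z - q @ (q.T @ z)
    sd = resid.std(ddof=1)
    if sd == 0:
        return
    z_new = mu + log_sd * resid / sd
    for k, i in enumerate(idx):
        records[i].cortisol = float(np.exp(z_new[k]))


# ---------------------------------------------------------------------------
# Plate data
# ---------------------------------------------------------------------------

def generate_plate(
    curve: StandardCurve,
    true_concentrations,
    replicate_cv: float = 5.0,
    seed: int = 0,
    n_replicates: int = 2,
) -> list[dict]:
    """Simulate plate rows (well, type, concentration_or_dilution, od).

    ODs come from the 4PL with multiplicative Gaussian noise at the given
    percent CV.  Zero concentrations become ``zero`` (B0) wells.
    """
    concs = np.asarray(true_concentrations, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    well = 0
    for conc in concs:
        base = curve.forward(float(conc))
        for _ in range(n_replicates):
            noise = 1.0 + (replicate_cv / 100.0) * rng.standard_normal() if replicate_cv else 1.0
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "type": "zero" if conc == 0 else "standard",
                    "concentration_or_dilution": float(conc),
                    "od": float(base * max(noise, 1e-6)),
                }
            )
            well += 1
    return rows


def generate_dilution_series(
    curve: StandardCurve,
    neat_concentration: float,
    dilutions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625),
    replicate_cv: float = 3.0,
    n_replicates: int = 3,
    seed: int = 0,
    slope_multiplier: float = 1.0,
) -> DilutionSeries:
    """B/B0 dilution ladder for parallelism fixtures.

    With ``slope_multiplier`` = 1 the series dilutes the given curve
    faithfully; other values rescale the linearized (logit) slope, giving
    deliberately non-parallel test material.
    """
    if neat_concentration <= 0:
        raise ValueError("neat concentration must be positive")
    rng = np.random.default_rng(seed)
    reps = []
    span = curve.top - curve.bottom
    for d in dilutions:
        od = curve.forward(neat_concentration * d)
        bb0 = (od - curve.bottom) / span  # fraction bound in (0, 1)
        lin = math.log(bb0 / (1.0 - bb0)) * slope_multiplier
        bb0 = 1.0 / (1.0 + math.exp(-lin))
        level = []
        for _ in range(n_replicates):
            noise = 1.0 + (replicate_cv / 100.0) * rng.standard_normal() if replicate_cv else 1.0
            level.append(float(np.clip(bb0 * noise, 1e-6, 1.0 - 1e-6)))
        reps.append(tuple(level))
    return DilutionSeries(labels=tuple(dilutions), replicate_responses=tuple(reps))
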