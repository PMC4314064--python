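"""Specimen data types, CSV I/O, covariate normalization and group summaries.

The on-disk dialect mirrors the field conventions of observer-program
specimen tables: two-state categorical columns are coded ``1 = yes`` /
``2 = no``, ``SEX`` is coded ``1 = male`` / ``2 = female``, and the token
``"nc"`` marks a value that was not collected.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "SpecimenRecord",
    "CovariateMatrix",
    "GroupSummary",
    "SpecimenFormatError",
    "SpecimenParseError",
    "FACTORS_FULL",
    "FACTORS_BYCATCH",
    "read_specimen_csv",
    "write_specimen_csv",
    "classify_maturity",
    "covariate_value",
    "normalize_covariates",
    "group_summary",
    "cohort_summaries",
    "fold_ratio",
]

MISSING_TOKEN = "nc"

#: Factor order of the full (both fatality groups) analysis.
FACTORS_FULL = (
    "fatality_type",
    "condition",
    "length",
    "sex",
    "maturity",
    "pregnancy",
    "lactation",
    "adrenal_mass",
)

#: Factor order once the analysis is restricted to bycaught animals
#: (fatality type and carcass condition drop out).
FACTORS_BYCATCH = (
    "length",
    "sex",
    "maturity",
    "pregnancy",
    "lactation",
    "adrenal_mass",
)


class SpecimenFormatError(ValueError):
    """The table is structurally unusable (e.g. mandatory column absent)."""


class SpecimenParseError(ValueError):
    """A cell could not be decoded; the message names the offending row."""


@dataclass
class SpecimenRecord:
    """One specimen: blubber cortisol plus its candidate cofactors.

    ``cortisol`` is ng of cortisol per g of blubber, already corrected for
    extraction efficiency.  ``condition_code`` (carcass decomposition stage
    1-4) is only meaningful for stranded animals.
    """

    specimen_id: str
    fatality_type: str  # "stranded" | "bycatch"
    cortisol: float
    condition_code: int | None = None
    total_length: float | None = None
    sex: str | None = None  # "male" | "female"
    maturity: str | None = None  # "immature" | "mature"
    pregnancy: str | None = None  # "yes" | "no"
    lactation: str | None = None  # "yes" | "no"
    adrenal_mass: float | None = None
    collection_month: int | None = None
    storage_days: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fatality_type not in ("stranded", "bycatch"):
            raise ValueError(
                f"{self.specimen_id}: fatality_type must be 'stranded' or "
                f"'bycatch', got {self.fatality_type!r}"
            )
        if not (self.cortisol > 0):
            raise ValueError(
                f"{self.specimen_id}: cortisol must be strictly positive, "
                f"got {self.cortisol!r}"
            )
        if self.condition_code is not None:
            if self.fatality_type != "stranded":
                raise ValueError(
                    f"{self.specimen_id}: condition code only applies to "
                    "stranded specimens"
                )
            if self.condition_code not in (1, 2, 3, 4):
                raise ValueError(
                    f"{self.specimen_id}: condition code must be 1-4, got "
                    f"{self.condition_code}"
                )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"{self.specimen_id}: bad sex {self.sex!r}")
        if self.maturity is not None and self.maturity not in ("immature", "mature"):
            raise ValueError(f"{self.specimen_id}: bad maturity {self.maturity!r}")
        for name in ("pregnancy", "lactation"):
            v = getattr(self, name)
            if v is not None and v not in ("yes", "no"):
                raise ValueError(f"{self.specimen_id}: bad {name} {v!r}")
        if self.pregnancy == "yes":
            if self.sex != "female":
                raise ValueError(f"{self.specimen_id}: pregnant specimen must be female")
            if self.maturity not in (None, "mature"):
                raise ValueError(f"{self.specimen_id}: pregnant specimen must be mature")
        if self.total_length is not None and not (self.total_length > 0):
            raise ValueError(f"{self.specimen_id}: total_length must be > 0")
        if self.adrenal_mass is not None and not (self.adrenal_mass > 0):
            raise ValueError(f"{self.specimen_id}: adrenal_mass must be > 0")
        if self.collection_month is not None and self.collection_month not in range(1, 13):
            raise ValueError(f"{self.specimen_id}: collection_month must be 1-12")
        if self.storage_days is not None and self.storage_days < 0:
            raise ValueError(f"{self.specimen_id}: storage_days must be >= 0")


@dataclass
class CovariateMatrix:
    """A design matrix with every column centred to mean 0 and scaled to SD 1.

    The per-column means and sample SDs used for the transform are retained
    so raw values can be recovered with :meth:`denormalize`.
    """

    values: np.ndarray  # (n, p)
    factor_names: tuple[str, ...]
    column_means: np.ndarray
    column_sds: np.ndarray
    n_dropped: int
    kept_indices: np.ndarray  # row index into the source record list

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def denormalize(self) -> np.ndarray:
        """Back-transform to the raw covariate scale."""
        return self.values * self.column_sds + self.column_means


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean: float
    se: float | None
    min: float
    max: float

    def as_dict(self) -> dict:
        return {
            "group": self.group_label,
            "n": self.n,
            "mean": self.mean,
            "se": self.se,
            "min": self.min,
            "max": self.max,
        }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

# canonical header -> record attribute
_CANONICAL_COLUMNS = {
    "ID": "specimen_id",
    "FATALITY TYPE": "fatality_type",
    "CONDITION": "condition_code",
    "LENGTH": "total_length",
    "SEX": "sex",
    "MATURE": "maturity",
    "PREGNANT": "pregnancy",
    "LACTATING": "lactation",
    "ADRENAL WEIGHT": "adrenal_mass",
    "BLUBBER CORTISOL": "cortisol",
    "MONTH": "collection_month",
    "STORAGE DAYS": "storage_days",
}

_HEADER_ALIASES = {
    "ID": ("ID", "SPECIMEN ID", "FIELD NUMBER", "SPECIMEN"),
    "FATALITY TYPE": ("FATALITY TYPE", "FATALITY", "SOURCE", "MORTALITY TYPE"),
    "CONDITION": ("CONDITION", "STRANDING CODE", "CARCASS CONDITION", "CODE"),
    "LENGTH": ("LENGTH", "TOTAL LENGTH"),
    "SEX": ("SEX",),
    "MATURE": ("MATURE", "MATURITY", "SEXUALLY MATURE"),
    "PREGNANT": ("PREGNANT", "PREGNANCY"),
    "LACTATING": ("LACTATING", "LACTATION"),
    "ADRENAL WEIGHT": ("ADRENAL WEIGHT", "ADRENAL MASS"),
    "BLUBBER CORTISOL": ("BLUBBER CORTISOL", "CORTISOL"),
    "MONTH": ("MONTH", "COLLECTION MONTH"),
    "STORAGE DAYS": ("STORAGE DAYS", "STORAGE TIME", "STORAGE"),
}


def _is_missing(cell: str | None) -> bool:
    return cell is None or cell.strip() == "" or cell.strip().lower() == MISSING_TOKEN


def _parse_float(cell: str, column: str, row_num: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise SpecimenParseError(
            f"row {row_num}: cannot parse {column}={cell!r} as a number"
        ) from None


def _decode_yes_no(cell: str, column: str, row_num: int) -> str:
    token = cell.strip()
    if token in ("1", "yes", "y", "YES", "Yes"):
        return "yes"
    if token in ("2", "no", "n", "NO", "No", "0"):
        return "no"
    raise SpecimenParseError(f"row {row_num}: cannot decode {column}={cell!r} (1=yes, 2=no)")


def _decode_sex(cell: str, row_num: int) -> str:
    token = cell.strip().lower()
    if token in ("1", "m", "male"):
        return "male"
    if token in ("2", "f", "female"):
        return "female"
    raise SpecimenParseError(f"row {row_num}: cannot decode SEX={cell!r} (1=male, 2=female)")


def _decode_fatality(cell: str, row_num: int) -> str:
    token = cell.strip().lower()
    if "strand" in token:
        return "stranded"
    if "bycat" in token or "bycaught" in token or "gillnet" in token or "fishery" in token:
        return "bycatch"
    raise SpecimenParseError(f"row {row_num}: cannot decode FATALITY TYPE={cell!r}")


def read_specimen_csv(path) -> list[SpecimenRecord]:
    """Read a specimen table, decoding the 1/2 and ``nc`` conventions.

    Unknown columns are preserved verbatim in :attr:`SpecimenRecord.extra`
    (latitude/longitude fields, for instance, pass straight through).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpecimenFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        upper = [h.upper() for h in header]

        col_of: dict[str, int] = {}
        for canonical, aliases in _HEADER_ALIASES.items():
            for alias in aliases:
                if alias in upper:
                    col_of[canonical] = upper.index(alias)
                    break
        if "BLUBBER CORTISOL" not in col_of:
            raise SpecimenFormatError(
                f"{path}: mandatory column 'BLUBBER CORTISOL' not found in header {header}"
            )
        known = set(col_of.values())
        extra_cols = [(i, header[i]) for i in range(len(header)) if i not in known]

        records: list[SpecimenRecord] = []
        for row_num, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue

            def cell(canonical: str) -> str | None:
                idx = col_of.get(canonical)
                if idx is None or idx >= len(row):
                    return None
                return row[idx]

            cortisol_cell = cell("BLUBBER CORTISOL")
            if _is_missing(cortisol_cell):
                raise SpecimenParseError(f"row {row_num}: BLUBBER CORTISOL is missing")
            cortisol = _parse_float(cortisol_cell, "BLUBBER CORTISOL", row_num)

            fat_cell = cell("FATALITY TYPE")
            if _is_missing(fat_cell):
                raise SpecimenParseError(f"row {row_num}: FATALITY TYPE is missing")
            fatality = _decode_fatality(fat_cell, row_num)

            def opt_float(canonical: str) -> float | None:
                c = cell(canonical)
                return None if _is_missing(c) else _parse_float(c, canonical, row_num)

            def opt_yes_no(canonical: str) -> str | None:
                c = cell(canonical)
                return None if _is_missing(c) else _decode_yes_no(c, canonical, row_num)

            cond = opt_float("CONDITION")
            sex_cell = cell("SEX")
            mat_cell = cell("MATURE")
            maturity = None
            if not _is_missing(mat_cell):
                token = mat_cell.strip().lower()
                if token in ("mature", "immature"):
                    maturity = token
                else:
                    maturity = "mature" if _decode_yes_no(mat_cell, "MATURE", row_num) == "yes" else "immature"
            month = opt_float("MONTH")

            sid_cell = cell("ID")
            sid = sid_cell.strip() if not _is_missing(sid_cell) else f"row{row_num}"

            try:
                rec = SpecimenRecord(
                    specimen_id=sid,
                    fatality_type=fatality,
                    cortisol=cortisol,
                    condition_code=int(cond) if cond is not None else None,
                    total_length=opt_float("LENGTH"),
                    sex=None if _is_missing(sex_cell) else _decode_sex(sex_cell, row_num),
                    maturity=maturity,
                    pregnancy=opt_yes_no("PREGNANT"),
                    lactation=opt_yes_no("LACTATING"),
                    adrenal_mass=opt_float("ADRENAL WEIGHT"),
                    collection_month=int(month) if month is not None else None,
                    storage_days=opt_float("STORAGE DAYS"),
                    extra={name: (row[i] if i < len(row) else "") for i, name in extra_cols},
                )
            except ValueError as exc:
                raise SpecimenParseError(f"row {row_num}: {exc}") from None
            records.append(rec)
    return records


def _encode_yes_no(value: str | None) -> str:
    if value is None:
        return MISSING_TOKEN
    return "1" if value == "yes" else "2"


def _encode_float(value: float | None) -> str:
    if value is None:
        return MISSING_TOKEN
    return repr(float(value))


def write_specimen_csv(records: Sequence[SpecimenRecord], path) -> None:
    """Write records in the same dialect :func:`read_specimen_csv` accepts."""
    extra_cols: list[str] = []
    for rec in records:
        for name in rec.extra:
            if name not in extra_cols:
                extra_cols.append(name)
    header = list(_CANONICAL_COLUMNS) + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [
                rec.specimen_id,
                rec.fatality_type,
                MISSING_TOKEN if rec.condition_code is None else str(rec.condition_code),
                _encode_float(rec.total_length),
                MISSING_TOKEN if rec.sex is None else ("1" if rec.sex == "male" else "2"),
                _encode_yes_no(None if rec.maturity is None else ("yes" if rec.maturity == "mature" else "no")),
                _encode_yes_no(rec.pregnancy),
                _encode_yes_no(rec.lactation),
                _encode_float(rec.adrenal_mass),
                repr(float(rec.cortisol)),
                MISSING_TOKEN if rec.collection_month is None else str(rec.collection_month),
                _encode_float(rec.storage_days),
            ]
            row.extend(rec.extra.get(name, "") for name in extra_cols)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Maturity classification from raw criteria
# ---------------------------------------------------------------------------

def classify_maturity(
    sex: str,
    right_testis_mass: float | None = None,
    corpora_count: int | None = None,
) -> str | None:
    """Classify sexual maturity from the sex-appropriate raw criterion.

    Males are mature when right testis mass exceeds 200 g; females when
    their ovarian corpora count exceeds one.  Returns ``None`` when the
    relevant criterion was not recorded.
    """
    if sex == "male":
        if right_testis_mass is None:
            return None
        return "mature" if right_testis_mass > 200.0 else "immature"
    if sex == "female":
        if corpora_count is None:
            return None
        return "mature" if corpora_count > 1 else "immature"
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


# ---------------------------------------------------------------------------
# Covariate extraction and normalization
# ---------------------------------------------------------------------------

def _cov_fatality(rec: SpecimenRecord) -> float | None:
    return 1.0 if rec.fatality_type == "stranded" else 0.0


def _cov_condition(rec: SpecimenRecord) -> float | None:
    # Bycaught carcasses carry no stranding code: the factor is
    # structurally inapplicable rather than unrecorded.  NaN marks
    # impute-at-column-mean so the column carries only within-stranded
    # decomposition contrast and no fatality-type proxy signal.
    if rec.fatality_type == "bycatch":
        return math.nan
    return None if rec.condition_code is None else float(rec.condition_code)


def _cov_length(rec: SpecimenRecord) -> float | None:
    return rec.total_length


def _cov_sex(rec: SpecimenRecord) -> float | None:
    if rec.sex is None:
        return None
    return 1.0 if rec.sex == "female" else 0.0


def _cov_maturity(rec: SpecimenRecord) -> float | None:
    if rec.maturity is None:
        return None
    return 1.0 if rec.maturity == "mature" else 0.0


def _reproductive(value: str | None, rec: SpecimenRecord) -> float | None:
    # Males and immature females cannot be pregnant/lactating: code "no"
    # rather than missing so they are not dropped from the model.
    if rec.sex == "male" or rec.maturity == "immature":
        return 0.0
    if value is None:
        return None
    return 1.0 if value == "yes" else 0.0


def _cov_pregnancy(rec: SpecimenRecord) -> float | None:
    return _reproductive(rec.pregnancy, rec)


def _cov_lactation(rec: SpecimenRecord) -> float | None:
    return _reproductive(rec.lactation, rec)


def _cov_adrenal(rec: SpecimenRecord) -> float | None:
    return rec.adrenal_mass


_COVARIATE_FUNCS: dict[str, Callable[[SpecimenRecord], float | None]] = {
    "fatality_type": _cov_fatality,
    "condition": _cov_condition,
    "length": _cov_length,
    "sex": _cov_sex,
    "maturity": _cov_maturity,
    "pregnancy": _cov_pregnancy,
    "lactation": _cov_lactation,
    "adrenal_mass": _cov_adrenal,
}


def covariate_value(rec: SpecimenRecord, factor: str) -> float | None:
    """Numeric coding of one factor for one record (``None`` = missing)."""
    try:
        return _COVARIATE_FUNCS[factor](rec)
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}; choose from {sorted(_COVARIATE_FUNCS)}") from None


def normalize_covariates(
    records: Sequence[SpecimenRecord],
    factors: Sequence[str],
    missing_policy: str = "complete_case",
) -> CovariateMatrix:
    """Build a design matrix with each column z-scored (sample SD, n-1).

    ``missing_policy='complete_case'`` drops any record missing a modelled
    factor and records the dropped count.  NaN cells mark factors that are
    structurally inapplicable to a record (a stranding code on a bycaught
    animal); those are imputed at the column mean of the applicable records
    so they contribute no contrast, rather than dropping the record.
    """
    if missing_policy != "complete_case":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    factors = tuple(factors)
    raw_rows: list[list[float]] = []
    kept: list[int] = []
    for i, rec in enumerate(records):
        vals = [covariate_value(rec, f) for f in factors]
        if any(v is None for v in vals):
            continue
        raw_rows.append([float(v) for v in vals])  # type: ignore[arg-type]
        kept.append(i)
    n_dropped = len(records) - len(kept)
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} records survive the missing policy")
    if len(kept) < len(factors):
        raise ValueError(
            f"{len(kept)} records after drops is fewer than {len(factors)} factors"
        )
    raw = np.asarray(raw_rows, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        nan_mask = np.isnan(col)
        if nan_mask.any():
            if nan_mask.all():
                raise ValueError(f"factor {factors[j]!r} is inapplicable to every record")
            col[nan_mask] = col[~nan_mask].mean()
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0 or not math.isfinite(sd):
            raise ValueError(f"factor {factors[j]!r} has zero variance")
    values = (raw - means) / sds
    return CovariateMatrix(
        values=values,
        factor_names=factors,
        column_means=means,
        column_sds=sds,
        n_dropped=n_dropped,
        kept_indices=np.asarray(kept, dtype=int),
    )


# ---------------------------------------------------------------------------
# Group summaries and the headline ratio
# ---------------------------------------------------------------------------

def group_summary(
    records: Iterable[SpecimenRecord],
    group_spec: Callable[[SpecimenRecord], bool] = lambda r: True,
    label: str = "all",
) -> GroupSummary:
    """Arithmetic mean, SE (sample SD / sqrt n) and range of a group."""
    values = [r.cortisol for r in records if group_spec(r)]
    if not values:
        raise ValueError(f"group {label!r} is empty")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    return GroupSummary(
        group_label=label,
        n=n,
        mean=float(arr.mean()),
        se=se,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def cohort_summaries(records: Sequence[SpecimenRecord]) -> list[GroupSummary]:
    """Demographic-class summaries of the bycaught animals plus the two
    fatality groups — the layout of the study's descriptive table."""
    by = [r for r in records if r.fatality_type == "bycatch"]
    out = [
        group_summary(records, lambda r: r.fatality_type == "stranded", "stranded"),
        group_summary(records, lambda r: r.fatality_type == "bycatch", "bycaught"),
    ]
    specs: list[tuple[str, Callable[[SpecimenRecord], bool]]] = [
        ("bycaught immature female", lambda r: r.sex == "female" and r.maturity == "immature"),
        ("bycaught mature female", lambda r: r.sex == "female" and r.maturity == "mature"),
        ("bycaught resting female", lambda r: r.sex == "female" and r.maturity == "mature" and r.pregnancy == "no" and r.lactation == "no"),
        ("bycaught lactating female", lambda r: r.sex == "female" and r.lactation == "yes"),
        ("bycaught pregnant female", lambda r: r.pregnancy == "yes"),
        ("bycaught all female", lambda r: r.sex == "female"),
        ("bycaught immature male", lambda r: r.sex == "male" and r.maturity == "immature"),
        ("bycaught mature male", lambda r: r.sex == "male" and r.maturity == "mature"),
        ("bycaught all male", lambda r: r.sex == "male"),
    ]
    for label, pred in specs:
        try:
            out.append(group_summary(by, pred, label))
        except ValueError:
            continue  # class absent from this cohort
    return out


def fold_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means; report rounded to one decimal."""
    if not mean_b > 0:
        raise ValueError(f"denominator mean must be positive, got {mean_b}")
    return mean_a / mean_b
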