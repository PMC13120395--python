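"""Cohort domain types, CSV input/output, and cytological scoring rules.

The unit of observation is one indoor cat characterised by its household
tobacco-smoke exposure (number of smoker owners, cigarettes smoked per day
at home), demographics, and optional cytology read-outs: urinary cotinine
(ng/mL), an ordinal oral-inflammation score (0-3), an ordinal dysplasia
grade (0-3), and the case-level nucleus-to-cytoplasm (N/C) area ratio
computed by the morphometry pipeline.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import SchemaError, ValidationError

EXPOSED = "exposed"
NON_EXPOSED = "non_exposed"

#: canonical column order for cohort CSV files
COHORT_COLUMNS = [
    "cat_id",
    "exposure",
    "age",
    "sex",
    "smoker_owners",
    "cigarettes_per_day",
    "cotinine_ng_ml",
    "inflammation_score",
    "dysplasia_grade",
    "case_nc_ratio",
]
MANDATORY_COLUMNS = COHORT_COLUMNS[:6]

# header aliases accepted on input (lower-cased, punctuation stripped)
_ALIASES = {
    "cat id": "cat_id",
    "cat_id": "cat_id",
    "id": "cat_id",
    "exposure": "exposure",
    "age": "age",
    "age years": "age",
    "sex": "sex",
    "smoker owners": "smoker_owners",
    "smoker owners n": "smoker_owners",
    "smoker_owners": "smoker_owners",
    "cigarettes day": "cigarettes_per_day",
    "cigarettes per day": "cigarettes_per_day",
    "cigarettes_per_day": "cigarettes_per_day",
    "cotinine": "cotinine_ng_ml",
    "cotinine ng ml": "cotinine_ng_ml",
    "cotinine_ng_ml": "cotinine_ng_ml",
    "inflammation score": "inflammation_score",
    "inflammation_score": "inflammation_score",
    "dysplasia grade": "dysplasia_grade",
    "dysplasia_grade": "dysplasia_grade",
    "case nc ratio": "case_nc_ratio",
    "case_nc_ratio": "case_nc_ratio",
    "nc ratio": "case_nc_ratio",
}

_EXPOSURE_SPELLINGS = {
    "exposed": EXPOSED,
    "non_exposed": NON_EXPOSED,
    "non-exposed": NON_EXPOSED,
    "nonexposed": NON_EXPOSED,
    "control": NON_EXPOSED,
}


@dataclass
class CatRecord:
    """Demographics, exposure covariates and optional cytology measurements
    for a single animal."""

    cat_id: str
    exposure: str
    age: float
    sex: str
    smoker_owners: int
    cigarettes_per_day: float
    cotinine_ng_ml: Optional[float] = None
    inflammation_score: Optional[int] = None
    dysplasia_grade: Optional[int] = None
    case_nc_ratio: Optional[float] = None

    def __post_init__(self):
        if self.exposure not in (EXPOSED, NON_EXPOSED):
            raise ValidationError(
                f"cat {self.cat_id}: exposure must be "
                f"'{EXPOSED}' or '{NON_EXPOSED}', got {self.exposure!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"cat {self.cat_id}: age must be positive")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"cat {self.cat_id}: sex must be 'M' or 'F'")
        if self.smoker_owners < 0 or int(self.smoker_owners) != self.smoker_owners:
            raise ValidationError(
                f"cat {self.cat_id}: smoker_owners must be a non-negative integer"
            )
        self.smoker_owners = int(self.smoker_owners)
        if self.cigarettes_per_day < 0:
            raise ValidationError(
                f"cat {self.cat_id}: cigarettes_per_day must be non-negative"
            )
        if self.exposure == NON_EXPOSED and (
            self.smoker_owners != 0 or self.cigarettes_per_day != 0
        ):
            raise ValidationError(
                f"cat {self.cat_id}: non-exposed cats must have zero smoker "
                "owners and zero cigarettes/day"
            )
        for name in ("inflammation_score", "dysplasia_grade"):
            v = getattr(self, name)
            if v is not None:
                if v not in (0, 1, 2, 3):
                    raise ValidationError(
                        f"cat {self.cat_id}: {name} must be in {{0,1,2,3}}, got {v}"
                    )
                setattr(self, name, int(v))
        if self.cotinine_ng_ml is not None and self.cotinine_ng_ml < 0:
            raise ValidationError(f"cat {self.cat_id}: cotinine must be >= 0")
        if self.case_nc_ratio is not None and not self.case_nc_ratio > 0:
            raise ValidationError(f"cat {self.cat_id}: case_nc_ratio must be > 0")


@dataclass
class Cohort:
    """An ordered collection of :class:`CatRecord` with unique ids."""

    records: list[CatRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.cat_id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate cat_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def group(self, exposure: str) -> list[CatRecord]:
        return [r for r in self.records if r.exposure == exposure]

    @property
    def exposed(self) -> list[CatRecord]:
        return self.group(EXPOSED)

    @property
    def non_exposed(self) -> list[CatRecord]:
        return self.group(NON_EXPOSED)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name) for f in fields(CatRecord)})
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _canon_header(name: str) -> str:
    key = (
        name.strip()
        .lower()
        .replace("(", " ")
        .replace(")", " ")
        .replace("/", " ")
        .replace("-", " ")
    )
    key = " ".join(key.split())
    return _ALIASES.get(key, key)


def read_cohort_table(path, provenance: Optional[str] = None, **read_csv_kwargs) -> Cohort:
    """Read a cohort CSV and return a validated :class:`Cohort`.

    Headers are matched case-insensitively and common spellings
    (``Cat ID``, ``Smoker Owners (n)``, ``Cigarettes/Day``,
    ``Non-exposed``) are accepted.  Optional columns that are absent map
    to missing fields, never to zero.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    df.columns = [_canon_header(c) for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records = []
    for idx, row in df.iterrows():
        exposure_raw = str(row["exposure"]).strip().lower()
        exposure = _EXPOSURE_SPELLINGS.get(exposure_raw)
        if exposure is None:
            raise ValidationError(
                f"row {idx}: unrecognised exposure value {row['exposure']!r}"
            )
        kwargs = {"cat_id": str(row["cat_id"]).strip(), "exposure": exposure,
                  "sex": str(row["sex"]).strip().upper()}
        for col in ("age", "smoker_owners", "cigarettes_per_day",
                    "cotinine_ng_ml", "inflammation_score",
                    "dysplasia_grade", "case_nc_ratio"):
            if col not in df.columns:
                continue
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                if col in MANDATORY_COLUMNS:
                    raise ValidationError(f"row {idx}: missing value for {col}")
                continue
            try:
                num = float(val)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"row {idx}: non-numeric value {val!r} in column {col}"
                ) from exc
            if col in ("smoker_owners", "inflammation_score", "dysplasia_grade"):
                if num != int(num):
                    raise ValidationError(
                        f"row {idx}: column {col} must be an integer, got {val!r}"
                    )
                num = int(num)
            kwargs[col] = num
        records.append(CatRecord(**kwargs))
    return Cohort(records, provenance=provenance or str(path))


def write_cohort_table(cohort: Cohort, path) -> None:
    """Write a cohort to CSV using the canonical column set."""
    df = cohort.to_frame()
    # keep optional columns only when at least one record carries a value
    for col in COHORT_COLUMNS[6:]:
        if df[col].isna().all():
            df = df.drop(columns=[col])
    df.to_csv(path, index=False)


def load_study_cohort() -> Cohort:
    """Cohort of the 30 enrolled indoor cats (20 exposed, 10 non-exposed)
    with their household exposure covariates, bundled with the package."""
    ref = resources.files("cytomorph.data").joinpath("smoke_exposure_cohort.csv")
    with resources.as_file(ref) as p:
        return read_cohort_table(Path(p), provenance="bundled study cohort")


def inflammation_score_from_count(cells_per_hpf: float, *,
                                  zero_threshold: float = 1.0) -> int:
    """Ordinal oral-inflammation score from inflammatory cells per HPF.

    0 = no inflammation (count below ``zero_threshold``, operationalising
    an almost complete absence of inflammatory cells), 1 = mild (< 30),
    2 = moderate (30-100 inclusive), 3 = marked (> 100).
    """
    if cells_per_hpf < 0:
        raise ValidationError("cells_per_hpf must be non-negative")
    if cells_per_hpf < zero_threshold:
        return 0
    if cells_per_hpf < 30:
        return 1
    if cells_per_hpf <= 100:
        return 2
    return 3


def summarize_exposure(cohort: Cohort) -> dict:
    """Per-group counts of smoker-owner categories and sex.

    Returns ``{group: {"n": int, "smoker_owners": {k: count},
    "sex": {"M": count, "F": count}}}``.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot summarise an empty cohort")
    out = {}
    for grp in (EXPOSED, NON_EXPOSED):
        recs = cohort.group(grp)
        if not recs:
            continue
        out[grp] = {
            "n": len(recs),
            "smoker_owners": dict(Counter(r.smoker_owners for r in recs)),
            "sex": dict(Counter(r.sex for r in recs)),
        }
    return out
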