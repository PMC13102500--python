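"""Data model and I/O for individual-bird corticosterone records.

The unit of observation is one bird sampled once: a treatment group
(``shot``, ``baseline`` or ``trapped`` = live trapping followed by
confinement), the bird's sex, the minutes elapsed from net activation to
blood sampling, and the plasma corticosterone concentration (CORT, ng/ml).
Files are plain CSV with the fixed header
``bird_id,treatment,sex,time_min,cort_ng_ml`` (UTF-8, "." decimal).

Two levels of validation are distinguished.  Type invariants (CORT strictly
positive — gamma support — and non-negative time) are enforced on every
:class:`CortSample`.  Study-design invariants (baseline bleeds within
3 minutes of disturbance; confinement times inside the 10–210 minute
window) are checked when reading study-like files and can be relaxed for
general use.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

COLUMNS = ("bird_id", "treatment", "sex", "time_min", "cort_ng_ml")

#: baseline bleeds must precede the handling-induced CORT rise
BASELINE_MAX_TIME_MIN = 3.0
#: confinement sampling window of the study design (minutes)
TRAPPED_TIME_WINDOW = (10.0, 210.0)


class DataValidationError(ValueError):
    """Raised when a record or file violates the data contract.

    ``messages`` carries one row-indexed message per violation.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


class Treatment(str, enum.Enum):
    SHOT = "shot"
    BASELINE = "baseline"
    TRAPPED = "trapped"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CortSample:
    """One bird's record.

    ``time_min`` is minutes since net activation; shot birds carry 0 by
    convention (death at stressor onset), which lets the whole-dataset
    time-course models run on all birds.
    """

    bird_id: str
    treatment: Treatment
    sex: Sex
    time_min: float
    cort: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "time_min", float(self.time_min))
        object.__setattr__(self, "cort", float(self.cort))
        if not math.isfinite(self.cort) or self.cort <= 0.0:
            raise DataValidationError(
                [f"bird {self.bird_id}: cort must be a positive, finite "
                 f"concentration (gamma support), got {self.cort!r}"]
            )
        if not math.isfinite(self.time_min) or self.time_min < 0.0:
            raise DataValidationError(
                [f"bird {self.bird_id}: time_min must be non-negative, "
                 f"got {self.time_min!r}"]
            )


def study_design_violations(sample: CortSample) -> list[str]:
    """Messages for violations of the study's sampling-design rules."""
    msgs = []
    if sample.treatment is Treatment.BASELINE and sample.time_min >= BASELINE_MAX_TIME_MIN:
        msgs.append(
            f"bird {sample.bird_id}: baseline samples must be taken within "
            f"{BASELINE_MAX_TIME_MIN:g} min of capture, got {sample.time_min:g}"
        )
    if sample.treatment is Treatment.TRAPPED:
        lo, hi = TRAPPED_TIME_WINDOW
        if not (lo <= sample.time_min <= hi):
            msgs.append(
                f"bird {sample.bird_id}: trapped-confined sampling time "
                f"{sample.time_min:g} outside the [{lo:g}, {hi:g}] min window"
            )
    return msgs


@dataclass
class Dataset:
    """Validated, ordered collection of :class:`CortSample` records.

    ``provenance`` is a free-text source tag (file path or simulation seed
    record) and does not take part in equality.
    """

    samples: tuple[CortSample, ...]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        ids = [s.bird_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(
                [f"duplicate bird_id values (each bird is sampled once): {dupes}"]
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[CortSample]:
        return iter(self.samples)

    # -- array accessors used by the fitting stages -------------------------
    def cort_array(self) -> np.ndarray:
        return np.array([s.cort for s in self.samples], dtype=float)

    def time_array(self) -> np.ndarray:
        return np.array([s.time_min for s in self.samples], dtype=float)

    def treatment_array(self) -> np.ndarray:
        return np.array([s.treatment.value for s in self.samples], dtype=object)

    def sex_array(self) -> np.ndarray:
        return np.array([s.sex.value for s in self.samples], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bird_id": [s.bird_id for s in self.samples],
                "treatment": [s.treatment.value for s in self.samples],
                "sex": [s.sex.value for s in self.samples],
                "time_min": [s.time_min for s in self.samples],
                "cort_ng_ml": [s.cort for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Dataset":
        samples = [
            CortSample(
                bird_id=str(row.bird_id),
                treatment=Treatment(row.treatment),
                sex=Sex(row.sex),
                time_min=float(row.time_min),
                cort=float(row.cort_ng_ml),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(samples=tuple(samples), provenance=provenance)

    def subset(self, keep) -> "Dataset":
        """New Dataset with the samples for which ``keep(sample)`` is true."""
        return Dataset(
            samples=tuple(s for s in self.samples if keep(s)),
            provenance=self.provenance,
        )


def read_dataset(path, strict: bool = True, study_windows: bool = True) -> Dataset:
    """Read and validate a CSV sample table.

    Under ``strict`` every violation is fatal and reported with its data-row
    index (1-based, excluding the header).  Otherwise structurally invalid
    rows (unparseable numbers, non-positive CORT, unknown enum labels,
    duplicate ids) are dropped with a warning and design-window violations
    are kept with a warning.  ``study_windows=False`` disables the
    baseline/confinement time-window rules for general (non-study) tables.
    """
    df = pd.read_csv(path, dtype={"bird_id": str}, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            [f"{path}: missing required column(s) {missing}; header must name "
             f"{list(COLUMNS)}"]
        )

    errors: list[str] = []
    warnings_: list[str] = []
    samples: list[CortSample] = []
    seen_ids: set[str] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        tag = f"row {pos}"
        try:
            sample = CortSample(
                bird_id=str(row.bird_id),
                treatment=Treatment(str(row.treatment)),
                sex=Sex(str(row.sex)),
                time_min=float(row.time_min),
                cort=float(row.cort_ng_ml),
            )
        except (DataValidationError, ValueError, TypeError) as exc:
            msg = exc.messages[0] if isinstance(exc, DataValidationError) else str(exc)
            errors.append(f"{tag}: {msg}")
            continue
        if sample.bird_id in seen_ids:
            errors.append(f"{tag}: duplicate bird_id {sample.bird_id!r}")
            continue
        design_msgs = study_design_violations(sample) if study_windows else []
        if design_msgs:
            if strict:
                errors.extend(f"{tag}: {m}" for m in design_msgs)
                continue
            warnings_.extend(f"{tag}: {m}" for m in design_msgs)
        seen_ids.add(sample.bird_id)
        samples.append(sample)

    if strict and errors:
        raise DataValidationError(errors)
    for msg in errors + warnings_:
        warnings.warn(msg, stacklevel=2)
    return Dataset(samples=tuple(samples), provenance=str(path))


def write_dataset(ds: Dataset, path) -> None:
    """Write a Dataset to CSV; ``read_dataset(write_dataset(ds))`` round-trips."""
    ds.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class GroupSummary:
    """Per-treatment descriptive statistics of CORT (ng/ml).

    The study's summary values are reported as "mean ± x" without labelling
    x as SD or SE; both are carried so either reading can be compared.
    """

    treatment: Treatment
    n: int
    mean_cort: float
    sd_cort: float
    se_cort: float


def summarize_groups(ds: Dataset) -> list[GroupSummary]:
    """One :class:`GroupSummary` per treatment present, in enum order.

    SD uses the n−1 denominator; a singleton group reports SD = SE = 0.
    """
    if len(ds) == 0:
        raise DataValidationError(["cannot summarize an empty dataset"])
    df = ds.to_frame()
    out: list[GroupSummary] = []
    for treatment in Treatment:
        grp = df.loc[df["treatment"] == treatment.value, "cort_ng_ml"]
        if grp.empty:
            continue
        n = int(grp.size)
        sd = float(grp.std(ddof=1)) if n > 1 else 0.0
        out.append(
            GroupSummary(
                treatment=treatment,
                n=n,
                mean_cort=float(grp.mean()),
                sd_cort=sd,
                se_cort=sd / math.sqrt(n),
            )
        )
    return out
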