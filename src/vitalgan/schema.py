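"""Canonical vital-sign dataset schema, CSV I/O, labelling and scaling.

Every stage of the pipeline exchanges data through :class:`LabeledDataset`:
an ``n x 10`` matrix of continuous predictor features plus a binary class per
record.  The class is derived from peak expiratory flow (PEF) thresholded at
400 L/min; PEF itself is therefore *never* a predictor (it would leak the
label).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_HIGH = "high"
CLASS_LOW = "low"
CLASSES = (CLASS_LOW, CLASS_HIGH)

#: PEF threshold (L/min) separating the two breathing-performance classes.
PEF_THRESHOLD = 400.0

#: The 11 canonical features, fixed order.  ``heart_rate`` is the
#: oximeter-derived rate; ``heart_rate_master`` comes from the
#: sphygmomanometer.
FEATURE_NAMES = (
    "oxygen",
    "body_temperature",
    "heart_rate",
    "heart_rate_master",
    "weight",
    "bmi",
    "fev1",
    "pef",
    "map",
    "diastolic_pressure",
    "systolic_pressure",
)

#: The 10 predictors: every canonical feature except ``pef``.
PREDICTOR_NAMES = tuple(n for n in FEATURE_NAMES if n != "pef")

UNITS = {
    "oxygen": "%",
    "body_temperature": "degC",
    "heart_rate": "bpm",
    "heart_rate_master": "bpm",
    "weight": "kg",
    "bmi": "kg/m^2",
    "fev1": "L",
    "pef": "L/min",
    "map": "mmHg",
    "diastolic_pressure": "mmHg",
    "systolic_pressure": "mmHg",
}

PROVENANCES = ("real", "synthetic", "simulated")


class SchemaError(ValueError):
    """A dataset or column set does not match the canonical schema."""


class ValidationError(ValueError):
    """An input value violates a precondition."""


def _normalize(name: str) -> str:
    return re.sub(r"[\s_\-]", "", name.strip().lower())


_ALIASES = {_normalize(n): n for n in FEATURE_NAMES}
_ALIASES.update(
    {
        "bodymassindex": "bmi",
        "meanarterialpressure": "map",
        "diastolicbloodpressure": "diastolic_pressure",
        "systolicbloodpressure": "systolic_pressure",
        "heartratemaster": "heart_rate_master",
        # printed rules spell the oximeter rate plainly as "heartrate"
        "heartrate": "heart_rate",
        "temperature": "body_temperature",
    }
)


def canonical_feature(name: str) -> str:
    """Map a column/rule spelling (case/space-insensitive) to its schema name."""
    key = _normalize(name)
    if key not in _ALIASES:
        raise SchemaError(f"unknown feature name: {name!r}")
    return _ALIASES[key]


def derive_label(pef_value: float) -> str:
    """Class of a record from its PEF (L/min): ``high`` iff PEF >= 400.

    The boundary value 400 itself maps to ``high`` (documented convention).
    """
    v = float(pef_value)
    if not math.isfinite(v) or v <= 0:
        raise ValidationError(f"PEF must be finite and positive, got {pef_value!r}")
    return CLASS_HIGH if v >= PEF_THRESHOLD else CLASS_LOW


@dataclass
class LabeledDataset:
    """Predictor matrix plus binary labels; the pipeline's common currency.

    Parameters
    ----------
    features
        ``(n, 10)`` float array over :data:`PREDICTOR_NAMES`.
    labels
        length-``n`` array of ``"high"`` / ``"low"``.
    provenance
        one of ``real`` / ``synthetic`` / ``simulated``.
    pef
        optional length-``n`` PEF values (L/min); present for real and
        simulated data, absent for GAN samples whose label is the
        conditioning class.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: str = "real"
    pef: np.ndarray | None = None
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[1] != len(PREDICTOR_NAMES):
            raise SchemaError(
                f"features must be (n, {len(PREDICTOR_NAMES)}), got {self.features.shape}"
            )
        if self.features.shape[0] < 1:
            raise SchemaError("dataset must contain at least one record")
        if len(self.labels) != self.features.shape[0]:
            raise SchemaError("labels length does not match feature rows")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise SchemaError(f"invalid labels: {sorted(map(str, bad))}")
        if not np.all(np.isfinite(self.features)):
            raise SchemaError("features contain missing or non-finite values")
        if self.provenance not in PROVENANCES:
            raise SchemaError(f"provenance must be one of {PROVENANCES}")
        if self.pef is not None:
            self.pef = np.asarray(self.pef, dtype=float)
            if self.pef.shape != (self.n,):
                raise SchemaError("pef length does not match feature rows")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def column(self, name: str) -> np.ndarray:
        """Predictor column by canonical (or alias) name."""
        return self.features[:, PREDICTOR_NAMES.index(canonical_feature(name))]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def prevalence_high(self) -> float:
        return float(np.mean(self.labels == CLASS_HIGH))

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        mask = np.asarray(mask, dtype=bool)
        return LabeledDataset(
            self.features[mask],
            self.labels[mask],
            self.provenance,
            None if self.pef is None else self.pef[mask],
        )

    def subset_class(self, cls: str) -> "LabeledDataset":
        return self.subset(self.labels == cls)

    def to_frame(self) -> pd.DataFrame:
        # copy: a DataFrame built on the raw array would alias our features
        df = pd.DataFrame(self.features.copy(), columns=list(PREDICTOR_NAMES))
        if self.pef is not None:
            df["pef"] = self.pef.copy()
        df["label"] = self.labels
        return df


def read_dataset(path: str | Path, provenance: str = "real") -> LabeledDataset:
    """Read a CSV into a :class:`LabeledDataset`.

    The header must contain (case/space-insensitive spellings accepted) the
    10 predictors plus either a ``pef`` column, a ``label`` column, or both.
    When only ``pef`` is present, labels are derived via :func:`derive_label`.
    Rows with a missing predictor (or missing label source) are dropped; the
    drop count is logged and stored on ``n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    colmap: dict[str, str] = {}
    label_col = None
    for col in df.columns:
        key = _normalize(col)
        if key in ("label", "class", "target"):
            label_col = col
        elif key in _ALIASES:
            colmap[_ALIASES[key]] = col
    missing = [n for n in PREDICTOR_NAMES if n not in colmap]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    has_pef = "pef" in colmap
    if not has_pef and label_col is None:
        raise SchemaError(f"{path}: need a 'pef' column or a 'label' column")

    wanted = [colmap[n] for n in PREDICTOR_NAMES]
    if has_pef:
        wanted.append(colmap["pef"])
    if label_col is not None:
        wanted.append(label_col)
    sub = df[wanted]
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d incomplete rows", path, n_dropped)
    sub = sub[keep]
    if sub.empty:
        raise SchemaError(f"{path}: all rows incomplete after cleaning")

    features = sub[[colmap[n] for n in PREDICTOR_NAMES]].to_numpy(dtype=float)
    pef = sub[colmap["pef"]].to_numpy(dtype=float) if has_pef else None
    if label_col is not None:
        labels = np.array([str(v).strip().lower() for v in sub[label_col]], dtype=object)
    else:
        labels = np.array([derive_label(v) for v in pef], dtype=object)
    ds = LabeledDataset(features, labels, provenance, pef)
    ds.n_dropped = n_dropped
    return ds


def write_dataset(ds: LabeledDataset, path: str | Path) -> None:
    """Write CSV: predictors in schema order, then ``pef`` (if carried), then
    ``label``.  Values are printed with 6 significant digits (the documented
    dialect), comma-separated, UTF-8, '.' decimal."""
    ds.to_frame().to_csv(Path(path), index=False, float_format="%.6g")


@dataclass
class ScalingTransform:
    """Per-feature min-max scaling fitted on a reference dataset.

    ``transform`` maps each predictor onto [0, 1] of the fitted range;
    ``inverse`` is its exact inverse.  Values outside the fitted range are
    allowed (they land outside [0, 1]) — synthetic samples may exceed the
    real envelope and that is flagged, not rejected.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = (X - self.minimum) / (self.maximum - self.minimum)
        frac = np.mean((out < 0) | (out > 1))
        if frac > 0:
            logger.info("scaler: %.1f%% of values fall outside the fitted range", 100 * frac)
        return out

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * (self.maximum - self.minimum) + self.minimum


def fit_scaler(ds: LabeledDataset) -> ScalingTransform:
    if ds.n < 2:
        raise ValidationError("scaler requires at least 2 records")
    lo = ds.features.min(axis=0)
    hi = ds.features.max(axis=0)
    const = np.nonzero(hi <= lo)[0]
    if const.size:
        names = [PREDICTOR_NAMES[i] for i in const]
        raise ValidationError(f"constant feature(s), cannot scale: {names}")
    return ScalingTransform(lo, hi)


def apply_scaler(ds: LabeledDataset, t: ScalingTransform) -> LabeledDataset:
    return LabeledDataset(t.transform(ds.features), ds.labels, ds.provenance, ds.pef)


def invert_scaler(ds: LabeledDataset, t: ScalingTransform) -> LabeledDataset:
    return LabeledDataset(t.inverse(ds.features), ds.labels, ds.provenance, ds.pef)
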