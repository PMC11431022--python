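"""Mixed categorical/continuous factor spaces for cloud point extraction (CPE).

A CPE screening study varies process factors of two kinds: categorical
(surfactant type, salt type, number of extraction steps) and continuous
(surfactant concentration, solid:liquid ratio, pH, equilibration temperature
and time, salt concentration, centrifugation speed and time).  This module
defines the factor space, its expansion to numeric model inputs (one value per
continuous factor, a full one-hot block per categorical factor), and per-column
min-max scaling of inputs and responses.

The reference space (:func:`cpe_screening_space`) holds the 11 factors of the
horned-melon-peel CPE study with the two levels each takes in the 12-run
screening design; its one-hot expansion has width 14 (8 continuous + 3 two-level
categorical), feeding the 14-input surrogate network.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Factor",
    "FactorSpace",
    "ScalingParams",
    "solid_liquid_to_numeric",
    "cpe_screening_space",
    "RESPONSE_NAMES",
    "RESPONSE_UNITS",
]

RESPONSE_NAMES = ("TPC", "TC", "AA")
RESPONSE_UNITS = {
    "TPC": "mg GAE/100 g dw",
    "TC": "mg beta-carotene/100 g dw",
    "AA": "umol TE/100 g dw",
}

_RATIO_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*:\s*(\d+(?:\.\d+)?)\s*$")


def solid_liquid_to_numeric(label: str | float) -> float:
    """Convert a solid:liquid ratio label such as ``"1:50"`` to the fraction 0.02.

    Numeric input is passed through unchanged, so tables that already store the
    fraction load transparently.
    """
    if isinstance(label, (int, float)) and not isinstance(label, bool):
        return float(label)
    m = _RATIO_RE.match(str(label))
    if m is None:
        raise ValueError(f"malformed solid:liquid ratio label: {label!r}")
    a, b = float(m.group(1)), float(m.group(2))
    if b <= 0:
        raise ValueError(f"solid:liquid ratio denominator must be positive: {label!r}")
    return a / b


@dataclass(frozen=True)
class Factor:
    """One process factor.

    Parameters
    ----------
    name:
        Unique factor name (e.g. ``"X4"`` or ``"pH"``).
    kind:
        ``"categorical"`` or ``"continuous"``.
    levels:
        For categorical factors, the ordered level labels (>= 2 distinct).
    low, high:
        For continuous factors, the bounds of the admissible range.
    grid:
        Optional one-factor-at-a-time (OVAT) grid of values/levels to scan.
    screen_levels:
        The (minus, plus) pair used in a two-level screening design.  Defaults
        to the two categorical levels, or ``(low, high)`` for continuous
        factors.
    units:
        Free-text units for reporting.
    """

    name: str
    kind: str
    levels: tuple = ()
    low: float = float("nan")
    high: float = float("nan")
    grid: tuple = ()
    screen_levels: tuple = ()
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "categorical":
            if len(set(self.levels)) < 2:
                raise ValueError(
                    f"categorical factor {self.name!r} needs >= 2 distinct levels"
                )
        else:
            if not np.isfinite(self.low) or not np.isfinite(self.high):
                raise ValueError(f"continuous factor {self.name!r} needs finite bounds")
            if not self.low < self.high:
                raise ValueError(
                    f"continuous factor {self.name!r} needs low < high "
                    f"(got {self.low} >= {self.high})"
                )

    @property
    def width(self) -> int:
        """Number of encoded input columns this factor occupies."""
        return len(self.levels) if self.kind == "categorical" else 1

    def two_levels(self) -> tuple:
        """(minus, plus) levels for screening designs."""
        if self.screen_levels:
            if len(self.screen_levels) != 2:
                raise ValueError(
                    f"factor {self.name!r}: screen_levels must have length 2"
                )
            return tuple(self.screen_levels)
        if self.kind == "categorical":
            if len(self.levels) != 2:
                raise ValueError(
                    f"factor {self.name!r} has {len(self.levels)} levels; "
                    "set screen_levels to pick two for screening"
                )
            return tuple(self.levels)
        return (self.low, self.high)

    def ovat_values(self) -> tuple:
        if self.grid:
            return tuple(self.grid)
        if self.kind == "categorical":
            return tuple(self.levels)
        raise ValueError(f"factor {self.name!r} has no OVAT grid")

    def coerce(self, value):
        """Validate/convert a raw setting value for this factor."""
        if self.kind == "categorical":
            if value not in self.levels:
                raise ValueError(
                    f"unknown level {value!r} for factor {self.name!r}; "
                    f"declared levels: {list(self.levels)}"
                )
            return value
        v = solid_liquid_to_numeric(value) if isinstance(value, str) else float(value)
        if v < self.low or v > self.high:
            warnings.warn(
                f"value {v} for factor {self.name!r} outside "
                f"[{self.low}, {self.high}]",
                stacklevel=3,
            )
        return v

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "units": self.units}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
        else:
            d["low"] = self.low
            d["high"] = self.high
        if self.grid:
            d["grid"] = list(self.grid)
        if self.screen_levels:
            d["screen_levels"] = list(self.screen_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Factor":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            low=float(d.get("low", float("nan"))),
            high=float(d.get("high", float("nan"))),
            grid=tuple(d.get("grid", ())),
            screen_levels=tuple(d.get("screen_levels", ())),
            units=d.get("units", ""),
        )


@dataclass(frozen=True)
class FactorSpace:
    """An ordered collection of factors plus the named responses."""

    factors: tuple
    response_names: tuple = RESPONSE_NAMES

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique within a space")

    @property
    def factor_names(self) -> list:
        return [f.name for f in self.factors]

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r} in space")

    @property
    def encoded_width(self) -> int:
        return sum(f.width for f in self.factors)

    @property
    def feature_names(self) -> list:
        """Names of the encoded input columns (one-hot slots expanded)."""
        out = []
        for f in self.factors:
            if f.kind == "categorical":
                out.extend(f"{f.name}={lvl}" for lvl in f.levels)
            else:
                out.append(f.name)
        return out

    def feature_slices(self) -> dict:
        """Map factor name -> slice of its columns in the encoded vector."""
        slices, start = {}, 0
        for f in self.factors:
            slices[f.name] = slice(start, start + f.width)
            start += f.width
        return slices

    def encode(self, settings) -> np.ndarray:
        """Encode one run's factor settings to a numeric model-input vector.

        ``settings`` is a mapping from factor name to value (or anything with
        ``__getitem__`` over factor names, e.g. a pandas Series).  Categorical
        factors contribute a one-hot block; continuous factors contribute their
        raw value (scaling is applied later, at model level).
        """
        vec = np.zeros(self.encoded_width)
        pos = 0
        for f in self.factors:
            try:
                value = settings[f.name]
            except (KeyError, IndexError):
                raise ValueError(f"missing value for factor {f.name!r}") from None
            value = f.coerce(value)
            if f.kind == "categorical":
                vec[pos + f.levels.index(value)] = 1.0
            else:
                vec[pos] = value
            pos += f.width
        return vec

    def encode_table(self, frame) -> np.ndarray:
        """Encode a DataFrame of runs (factor columns) row-wise to a matrix."""
        return np.vstack([self.encode(row) for _, row in frame.iterrows()])

    def to_dict(self) -> dict:
        return {
            "factors": [f.to_dict() for f in self.factors],
            "response_names": list(self.response_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpace":
        return cls(
            factors=tuple(Factor.from_dict(fd) for fd in d["factors"]),
            response_names=tuple(d.get("response_names", RESPONSE_NAMES)),
        )


@dataclass
class ScalingParams:
    """Per-column min-max scaling parameters fitted on a training table.

    Columns map linearly onto [0, 1]; a constant column maps to 0 and inverts
    back to its constant value.
    """

    mins: np.ndarray
    maxs: np.ndarray
    columns: tuple = ()

    @classmethod
    def fit(cls, X: np.ndarray, columns=()) -> "ScalingParams":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaling on an empty table")
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0), columns=tuple(columns))

    @property
    def span(self) -> np.ndarray:
        return self.maxs - self.mins

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.span > 0, self.span, 1.0)
        out = (X - self.mins) / span
        return np.where(self.span > 0, out, 0.0)

    def invert(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X * self.span + self.mins

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "columns": list(self.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            columns=tuple(d.get("columns", ())),
        )


def cpe_screening_space() -> FactorSpace:
    """The 11-factor CPE screening space (two levels per factor).

    Factor names X1..X11 follow the study convention: surfactant type,
    surfactant concentration (%, w/v), solid:liquid ratio (as the fraction
    solid/liquid, so 1:50 -> 0.02), pH, equilibration temperature (degC),
    equilibration time (min), salt type, salt concentration (%, w/v),
    centrifugation speed (g), centrifugation time (min), number of CPE steps.

    Continuous bounds span the full ranges explored in the one-factor scans;
    ``screen_levels`` carry the (minus, plus) pairing used in the 12-run
    screening design.  One-hot expansion width is 14.
    """
    return FactorSpace(
        factors=(
            Factor("X1", "categorical", levels=("Tween 80", "Triton X-100"),
                   screen_levels=("Triton X-100", "Tween 80")),
            Factor("X2", "continuous", low=2, high=10,
                   grid=(2, 4, 6, 8, 10), screen_levels=(2, 10), units="%, w/v"),
            Factor("X3", "continuous", low=0.01, high=0.1,
                   grid=(0.1, 1 / 30, 0.02, 1 / 70, 0.01),
                   screen_levels=(0.1, 0.01), units="w/v fraction"),
            Factor("X4", "continuous", low=1.5, high=7.5,
                   grid=(1.5, 3.0, 4.5, 6.0, 7.5), screen_levels=(1.5, 7.5)),
            Factor("X5", "continuous", low=35, high=75,
                   grid=(35, 45, 55, 65, 75), screen_levels=(35, 75), units="degC"),
            Factor("X6", "continuous", low=20, high=60,
                   grid=(20, 30, 40, 50, 60), screen_levels=(20, 60), units="min"),
            Factor("X7", "categorical", levels=("NaCl", "KCl"),
                   screen_levels=("KCl", "NaCl")),
            Factor("X8", "continuous", low=6, high=18,
                   grid=(6, 10, 14, 16, 18), screen_levels=(16, 18), units="%, w/v"),
            Factor("X9", "continuous", low=2473, high=9892,
                   grid=(2473, 5564, 9892), screen_levels=(2473, 9892), units="g"),
            Factor("X10", "continuous", low=10, high=20,
                   grid=(10, 15, 20), screen_levels=(10, 20), units="min"),
            Factor("X11", "categorical", levels=("Step 1", "Step 2"),
                   screen_levels=("Step 1", "Step 2")),
        ),
    )
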