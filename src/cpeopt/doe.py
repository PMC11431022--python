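"""Screening and one-factor-at-a-time designs, plus bundled study tables.

Provides the 12-run Plackett-Burman (PB) screening design for 11 two-level
factors, OVAT grids (vary one factor over its declared grid while holding the
rest fixed), and loaders for the study's printed tables, which ship as
tab-separated fixtures:

``table2``
    the 12-run PB design with measured TPC/TC/AA responses (five runs show no
    phase separation and carry all-zero responses);
``table13``
    two-step CPE recoveries and their printed sum;
``table15``
    HPLC phenol/carotenoid profiles per extraction technique;
``table16``
    model-vs-experiment verification runs, including the optimized sample.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .factor_space import FactorSpace, cpe_screening_space, solid_liquid_to_numeric

__all__ = ["DesignResponseTable", "pb_design", "ovat_grid", "load_fixture"]

# sha256 of the bundled fixture files; guards against silent corruption.
_FIXTURES = {
    "table2": (
        "table2_pb_design.tsv",
        "6057101192392df6e0476b9c3c1dce6d12d2571f52217c2def3ba0a50e8a2073",
    ),
    "table13": (
        "table13_cpe_steps.tsv",
        "0082c41d69bfbecc47477eed85cbcf2057ceeeeb06ccc29327a34fe06bf1d930",
    ),
    "table15": (
        "table15_hplc.tsv",
        "1d2f6f9bf19c00db4970ab361373f5ffbacb360bcaa9bb1000fa3f40b5471d10",
    ),
    "table16": (
        "table16_verification.tsv",
        "ffb0327379948359532cf3f3122924daa359545c5f0b0347f6a27f65e49e345a",
    ),
}

# First row of the cyclic N=12 Plackett-Burman construction; the remaining
# rows are its 10 right-rotations plus a final all-minus row.
_PB12_GENERATOR = (+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1)


@dataclass
class DesignResponseTable:
    """Runs x (factor settings, responses) — the exchange format between stages.

    ``frame`` holds one row per run with the space's factor columns and,
    optionally, its response columns.  Continuous values are stored numerically
    (solid:liquid labels are converted to fractions on construction).
    """

    space: FactorSpace
    frame: pd.DataFrame

    def __post_init__(self):
        missing = [n for n in self.space.factor_names if n not in self.frame.columns]
        if missing:
            raise ValueError(f"design table missing factor columns: {missing}")
        frame = self.frame.copy()
        for f in self.space.factors:
            if f.kind == "continuous":
                frame[f.name] = [solid_liquid_to_numeric(v) for v in frame[f.name]]
        if self.has_responses:
            resp = frame[list(self.space.response_names)].to_numpy(dtype=float)
            if (resp < 0).any():
                raise ValueError("responses must be non-negative")
        self.frame = frame.reset_index(drop=True)

    @property
    def has_responses(self) -> bool:
        return all(n in self.frame.columns for n in self.space.response_names)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def settings_frame(self) -> pd.DataFrame:
        return self.frame[self.space.factor_names]

    def encoded_inputs(self) -> np.ndarray:
        return self.space.encode_table(self.settings_frame)

    def response_matrix(self) -> np.ndarray:
        if not self.has_responses:
            raise ValueError("table has no responses")
        return self.frame[list(self.space.response_names)].to_numpy(dtype=float)

    def failed_separation(self) -> np.ndarray:
        """Boolean mask of runs whose responses are all zero (no phase split)."""
        return (self.response_matrix() == 0).all(axis=1)

    def drop_failed(self) -> "DesignResponseTable":
        keep = ~self.failed_separation()
        return DesignResponseTable(self.space, self.frame.loc[keep])

    def with_responses(self, responses: np.ndarray) -> "DesignResponseTable":
        frame = self.settings_frame.copy()
        responses = np.asarray(responses, dtype=float)
        for j, name in enumerate(self.space.response_names):
            frame[name] = responses[:, j]
        return DesignResponseTable(self.space, frame)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, space: FactorSpace) -> "DesignResponseTable":
        return cls(space, pd.read_csv(path, sep="\t"))


def pb_design(space: FactorSpace) -> DesignResponseTable:
    """Generate the 12-run Plackett-Burman design for 11 two-level factors.

    Each factor column carries each of its two screening levels exactly six
    times, and any two columns are orthogonal under +/-1 coding.  Level
    assignment: +1 maps to each factor's plus screening level, -1 to the minus
    level (see :meth:`Factor.two_levels`).
    """
    if len(space.factors) != 11:
        raise ValueError(
            f"unsupported factor count {len(space.factors)}: this release "
            "implements the cyclic N=12 construction for exactly 11 two-level "
            "factors"
        )
    gen = np.array(_PB12_GENERATOR)
    rows = [np.roll(gen, i) for i in range(11)]
    rows.append(-np.ones(11, dtype=int))
    coded = np.array(rows)

    data = {}
    for j, f in enumerate(space.factors):
        minus, plus = f.two_levels()
        data[f.name] = [plus if c > 0 else minus for c in coded[:, j]]
    return DesignResponseTable(space, pd.DataFrame(data))


def pb_coded_matrix(table: DesignResponseTable) -> np.ndarray:
    """Recover the +/-1 coding of a two-level design table (for diagnostics)."""
    coded = np.empty((table.n_runs, len(table.space.factors)), dtype=int)
    for j, f in enumerate(table.space.factors):
        minus, plus = f.two_levels()
        if f.kind == "continuous":
            minus, plus = float(minus), float(plus)
        col = table.frame[f.name]
        for i, v in enumerate(col):
            if v == plus:
                coded[i, j] = 1
            elif v == minus:
                coded[i, j] = -1
            else:
                raise ValueError(
                    f"value {v!r} in factor {f.name!r} is neither screening level"
                )
    return coded


def ovat_grid(space: FactorSpace, vary: str, fixed: dict) -> DesignResponseTable:
    """One-factor-at-a-time design: scan ``vary`` over its grid, others fixed."""
    f = space.factor(vary)
    values = f.ovat_values()
    rows = []
    for v in values:
        row = dict(fixed)
        row[vary] = v
        rows.append(row)
    frame = pd.DataFrame(rows, columns=space.factor_names)
    return DesignResponseTable(space, frame)


def _fixture_text(name: str) -> str:
    try:
        fname, expected = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    data = resources.files("cpeopt.data").joinpath(fname).read_bytes()
    if expected is not None:
        digest = hashlib.sha256(data).hexdigest()
        if digest != expected:
            raise IOError(
                f"fixture {fname} is corrupted (sha256 {digest}, "
                f"expected {expected})"
            )
    return data.decode()


def load_fixture(name: str, space: FactorSpace | None = None):
    """Load a bundled study table.

    ``table2`` returns a :class:`DesignResponseTable` over the CPE screening
    space; the others return plain DataFrames.
    """
    import io

    text = _fixture_text(name)
    frame = pd.read_csv(io.StringIO(text), sep="\t")
    if name == "table2":
        space = space or cpe_screening_space()
        table = DesignResponseTable(space, frame.drop(columns=["run"]))
        # sanity: the printed design has 12 runs, 4 of them all-zero
        # (failed separation); two more runs have zero TPC but nonzero TC/AA
        assert table.n_runs == 12
        assert int(table.failed_separation().sum()) == 4
        return table
    if name == "table16":
        for col in ("X3",):
            frame[col] = [solid_liquid_to_numeric(v) for v in frame[col]]
    return frame
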