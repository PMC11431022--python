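"""Verification arithmetic and pipeline orchestration.

Holds the small arithmetic used to verify surrogate predictions against
laboratory measurements (signed relative errors at print precision, table-sum
checks, percentage shares) and :func:`run_pipeline`, which chains
design -> fit -> sensitivity -> optimize -> verify with a single top-level seed
and writes every artifact as delimited/structured text so a rerun with the
same configuration reproduces them bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doe import DesignResponseTable, load_fixture, pb_design
from .factor_space import cpe_screening_space
from .moo import optimize
from .sensitivity import yoon
from .surrogate import search

__all__ = [
    "relative_error",
    "sum_check",
    "share_percent",
    "verification_table",
    "run_pipeline",
]


def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def relative_error(model_value: float, experimental: float) -> float:
    """Signed percent error of a model value against the measured value.

    (model - experimental) / experimental x 100, rounded half-away-from-zero
    to two decimals.  Undefined (NaN) when the measured value is zero.
    """
    if experimental == 0:
        return float("nan")
    return _round_half_away((model_value - experimental) / experimental * 100.0, 2)


@dataclass(frozen=True)
class SumCheck:
    passed: bool
    delta: float


def sum_check(values, printed_total: float, tol: float = 0.01) -> SumCheck:
    """Does a list of printed values add up to its printed total within tol?

    The default tolerance 0.01 is the print precision of the study tables.
    """
    delta = abs(float(np.sum(values)) - printed_total)
    return SumCheck(passed=bool(delta <= tol + 1e-12), delta=round(delta, 2))


def share_percent(part: float, whole: float) -> int:
    """part/whole as a percentage rounded to the nearest integer."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return int(_round_half_away(part / whole * 100.0, 0))


def verification_table(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute signed relative errors for every verification run.

    Returns one row per (sample, response) with model value, experimental
    value, and the recomputed relative error in percent.
    """
    if fixture is None:
        fixture = load_fixture("table16")
    rows = []
    for _, r in fixture.iterrows():
        for quantity, m_col, e_col in (
            ("TP", "model_TP", "exp_TP"),
            ("TC", "model_TC", "exp_TC"),
            ("AA", "model_AA", "exp_AA"),
        ):
            rows.append({
                "sample": r["sample"],
                "quantity": quantity,
                "model": r[m_col],
                "experimental": r[e_col],
                "relative_error_pct": relative_error(r[m_col], r[e_col]),
            })
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Run design -> fit -> sensitivity -> optimize -> verify and write artifacts.

    ``config`` keys:

    - ``source``: ``"table2"`` (bundled screening data), ``"simulator"``
      (default simulated ground truth) or a path to a design/response TSV;
    - ``seed``: top-level seed (default 0); stage sub-seeds derive from it;
    - ``search``: optional kwargs for :func:`cpeopt.surrogate.search`;
    - ``moo``: optional kwargs for :func:`cpeopt.moo.optimize`.

    Artifacts written to ``outdir``: ``design.tsv``, ``model.json``,
    ``sensitivity.tsv``, ``pareto.tsv``, ``compromise.tsv``,
    ``verification.tsv`` (fixture source only) and ``run.log``.  All outputs
    are plain text and a rerun with the same config reproduces them exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    source = config.get("source", "table2")
    space = cpe_screening_space()
    log = [
        f"cpeopt {__version__}",
        f"seed {seed}",
        f"config_hash {_config_hash(config)}",
    ]

    stage = "design"
    try:
        if source == "table2":
            table = load_fixture("table2")
        elif source == "simulator":
            from .synthetic_data import default_config, simulate_table
            sim = default_config(seed=seed)
            table = simulate_table(sim, pb_design(space), seed=seed)
        else:
            table = DesignResponseTable.read_tsv(source, space)
        if table.n_runs == 0:
            raise ValueError("design table is empty")
        table.write_tsv(outdir / "design.tsv")
        log.append(f"design: {table.n_runs} runs, "
                   f"{int(table.failed_separation().sum())} failed separations")

        stage = "fit"
        search_kw = {"hidden_sizes": (5, 6, 7, 8, 9, 10),
                     "activation_options": (("identity", "identity"),),
                     "n_restarts": 4, "seed": seed}
        search_kw.update(config.get("search", {}))
        model, search_log = search(table, **search_kw)
        model.save(outdir / "model.json")
        log.append(
            f"fit: topology {model.topology}, activations {model.activations}, "
            f"mean r2 {model.fit_stats['mean_r2']:.6f}, "
            f"{len(search_log)} candidates"
        )

        stage = "sensitivity"
        report = yoon(model)
        report.write_tsv(outdir / "sensitivity.tsv")
        log.append("sensitivity: factor-level relative influences written")

        stage = "optimize"
        moo_kw = {"seed": seed}
        moo_kw.update(config.get("moo", {}))
        result = optimize(model, space, **moo_kw)
        result.write_tsv(outdir / "pareto.tsv")
        result.compromise.to_frame().T.to_csv(
            outdir / "compromise.tsv", sep="\t", index=False
        )
        log.append(f"optimize: {result.n_front} points on the Pareto front")

        stage = "verify"
        verification = None
        if source == "table2":
            verification = verification_table()
            verification.to_csv(outdir / "verification.tsv", sep="\t",
                                index=False)
            log.append("verify: relative errors recomputed for all "
                       f"{len(verification)} model/experiment pairs")
    except Exception as exc:
        log.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return {
        "table": table,
        "model": model,
        "sensitivity": report,
        "pareto": result,
        "verification": verification,
        "log": log,
    }
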