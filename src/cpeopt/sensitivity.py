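"""Yoon connection-weight global sensitivity for one-hidden-layer surrogates.

Yoon's relative influence (RI) attributes each output's variation to each input
through the products of input-to-hidden and hidden-to-output weights:

    RI(i, j) = sum_k W[i, k] * V[k, j]
               ------------------------------------  x 100
               sum_i' | sum_k W[i', k] * V[k, j] |

Biases are excluded; for every output the absolute influences sum to 100%.
The sign carries direction: a positive RI means raising the (scaled) input
raises the predicted output.  Weights are used on the scaled (unit-free)
training scale so influences are comparable across inputs with different
units.  One-hot level columns are additionally aggregated per factor.

Reference: Yoon, Swales & Margavio (1993), J. Oper. Res. Soc. 44, 51-60.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surrogate import SurrogateModel

__all__ = ["SensitivityReport", "yoon", "rank_factors"]


@dataclass
class SensitivityReport:
    """Relative-influence matrices at encoded-input and factor level.

    ``encoded`` is (encoded input x output) signed percentages; ``by_factor``
    aggregates one-hot blocks by signed sum, ``by_factor_abs`` by absolute sum,
    and ``by_factor_contrast`` by the spread (max - min) of the block's level
    influences (|RI| for continuous factors).  The contrast is the robust
    choice for ranking: a one-hot block is collinear with the bias, so only
    differences between its level influences are identified by the data — the
    split of weight among levels, hence the signed and absolute sums, depends
    on the training initialization.
    """

    encoded: pd.DataFrame
    by_factor: pd.DataFrame
    by_factor_abs: pd.DataFrame
    by_factor_contrast: pd.DataFrame
    model: SurrogateModel | None = None

    def write_tsv(self, path) -> None:
        self.by_factor.to_csv(path, sep="\t")

    def plot(self, output: str, ax=None):
        """Bar chart of factor-level RI for one output (matplotlib optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = self.by_factor[output]
        ax.bar(vals.index, vals.to_numpy())
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel(f"relative influence on {output} (%)")
        ax.tick_params(axis="x", rotation=60)
        return ax


def yoon(model: SurrogateModel) -> SensitivityReport:
    """Compute Yoon relative influences from a model's connection weights.

    If every weight product vanishes for some output, that output's RI is
    undefined and reported as NaN with a warning.
    """
    prod = model.W @ model.V                      # (n_in, n_out)
    denom = np.abs(prod).sum(axis=0)
    ri = np.full_like(prod, np.nan)
    for j, d in enumerate(denom):
        if d == 0:
            warnings.warn(
                f"all connection-weight products vanish for output {j}; "
                "relative influence undefined", stacklevel=2,
            )
        else:
            ri[:, j] = prod[:, j] / d * 100.0

    if model.space is not None:
        feature_names = model.space.feature_names
        outputs = list(model.space.response_names)
        slices = model.space.feature_slices()
    else:
        feature_names = [f"in{i}" for i in range(model.n_in)]
        outputs = [f"out{j}" for j in range(model.n_out)]
        slices = {n: slice(i, i + 1) for i, n in enumerate(feature_names)}

    encoded = pd.DataFrame(ri, index=feature_names, columns=outputs)
    by_factor = pd.DataFrame(
        {name: ri[sl].sum(axis=0) for name, sl in slices.items()},
        index=outputs,
    ).T
    by_factor_abs = pd.DataFrame(
        {name: np.abs(ri[sl]).sum(axis=0) for name, sl in slices.items()},
        index=outputs,
    ).T
    contrast = {}
    for name, sl in slices.items():
        block = ri[sl]
        if block.shape[0] > 1:
            contrast[name] = block.max(axis=0) - block.min(axis=0)
        else:
            contrast[name] = np.abs(block[0])
    by_factor_contrast = pd.DataFrame(contrast, index=outputs).T
    return SensitivityReport(encoded=encoded, by_factor=by_factor,
                             by_factor_abs=by_factor_abs,
                             by_factor_contrast=by_factor_contrast, model=model)


def rank_factors(report: SensitivityReport, output: str,
                 aggregation: str = "signed") -> list:
    """Factor names ordered by decreasing |aggregated RI| for one output.

    ``aggregation`` selects the one-hot block aggregation: ``"signed"`` (sum of
    signed level RIs, the default), ``"abs"`` (sum of absolute level RIs) or
    ``"contrast"`` (spread of level RIs).  Ties keep the factor-declaration
    order (stable sort).
    """
    table = {
        "signed": report.by_factor,
        "abs": report.by_factor_abs,
        "contrast": report.by_factor_contrast,
    }.get(aggregation)
    if table is None:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if output not in table.columns:
        raise KeyError(
            f"unknown output {output!r}; available: {list(table.columns)}"
        )
    vals = table[output].abs()
    order = np.argsort(-vals.to_numpy(), kind="stable")
    return [vals.index[i] for i in order]
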