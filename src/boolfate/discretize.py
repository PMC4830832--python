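"""Discretization of expression measurements for Boolean model training.

qRT-PCR fold changes (2^-ddCt scale) are rescaled per node to the unit
interval, passed through a Hill function f(x) = x^n / (x^n + k^n) to sharpen
them toward quasi-Boolean activity values, and binarized with a strict
threshold when compared against simulated Boolean states.  With k = 0.5 the
binarization at threshold 0.5 is independent of the Hill coefficient n, which
is why the discretized trajectories are insensitive to the choice of n.

Tables are handled in long format with columns ``node, condition, time_h,
value`` and can be exported to a MIDAS-style CSV (TR:/DA:/DV: prefixes) for
interchange with logic-modeling tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HillConfig",
    "ddct_fold_change",
    "rescale_unit_interval",
    "hill_transform",
    "binarize",
    "read_long_table",
    "write_long_table",
    "write_midas",
    "read_midas",
]

LONG_COLUMNS = ["node", "condition", "time_h", "value"]


class DegenerateScaleWarning(UserWarning):
    """A constant series cannot be rescaled; it is mapped to all zeros."""


@dataclass(frozen=True)
class HillConfig:
    """Hill coefficient ``n`` and half-activation threshold ``k``."""

    n: float = 2.0
    k: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if not 0 < self.k < 1:
            raise ValueError("threshold k must lie in (0, 1)")


def ddct_fold_change(ct_target, ct_reference, ct_control_target, ct_control_reference):
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    a ddCt of -1 corresponds to a one-cycle doubling, i.e. fold change 2.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    ddct = (ct_target - ct_reference) - (
        np.asarray(ct_control_target, dtype=float)
        - np.asarray(ct_control_reference, dtype=float)
    )
    if not np.all(np.isfinite(ddct)):
        raise ValueError("Ct values must be finite")
    result = np.power(2.0, -ddct)
    return result.item() if result.ndim == 0 else result


def rescale_unit_interval(table: pd.DataFrame) -> pd.DataFrame:
    """Per-node min-max rescaling to [0, 1] across all conditions/timepoints.

    Rescaling jointly across conditions preserves the cross-condition
    contrast the training objective relies on.  A constant series is
    degenerate: it is mapped to all zeros and a warning is emitted so that
    whole-table processing never aborts.
    """
    _check_long(table)
    out = table.copy()
    for node, idx in out.groupby("node").groups.items():
        vals = out.loc[idx, "value"].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            out.loc[idx, "value"] = (vals - lo) / (hi - lo)
        else:
            warnings.warn(
                f"constant series for node {node!r}; mapped to 0",
                DegenerateScaleWarning, stacklevel=2)
            out.loc[idx, "value"] = 0.0
    return out


def hill_transform(x, config: HillConfig = HillConfig()):
    """Hill function x^n / (x^n + k^n), strictly monotone on [0, 1].

    Maps 0 to 0, k to exactly 0.5, and 1 to 1 / (1 + k^n) < 1.
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("hill_transform input must lie in [0, 1]")
    xn = np.power(arr, config.n)
    result = xn / (xn + config.k ** config.n)
    return result.item() if result.ndim == 0 else result


def binarize(value, threshold: float = 0.5):
    """1 if value > threshold else 0 (strictly above counts as on)."""
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("binarize input must lie in [0, 1]")
    result = (arr > threshold).astype(int)
    return result.item() if result.ndim == 0 else result


def discretize_table(table: pd.DataFrame, config: HillConfig = HillConfig(),
                     threshold: float = 0.5) -> pd.DataFrame:
    """rescale -> Hill transform -> binarize, on a long-format table."""
    normed = rescale_unit_interval(table)
    normed["value"] = hill_transform(normed["value"].to_numpy(), config)
    normed["value"] = binarize(normed["value"].to_numpy(), threshold)
    return normed


# -- I/O -------------------------------------------------------------------


def _check_long(table: pd.DataFrame) -> None:
    missing = set(LONG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"long table missing column(s) {sorted(missing)}")


def read_long_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    _check_long(table)
    return table


def write_long_table(table: pd.DataFrame, path) -> None:
    _check_long(table)
    table.to_csv(path, sep="\t", index=False)


def write_midas(table: pd.DataFrame, path, stimuli=(), inhibitors=()) -> None:
    """Export a long table to a MIDAS-style CSV.

    Columns: ``TR:<name>`` treatment indicators (1 where the condition label
    contains the treatment name), ``DA:ALL`` acquisition time, and one
    ``DV:<node>`` column per measured node.
    """
    _check_long(table)
    wide = table.pivot_table(index=["condition", "time_h"], columns="node",
                             values="value").reset_index()
    cols = {}
    for tr in list(stimuli) + list(inhibitors):
        cols[f"TR:{tr}"] = [int(tr in c.split("+")) for c in wide["condition"]]
    out = pd.DataFrame(cols)
    out.insert(0, "ID:condition", wide["condition"])
    out["DA:ALL"] = wide["time_h"]
    for node in [c for c in wide.columns if c not in ("condition", "time_h")]:
        out[f"DV:{node}"] = wide[node]
    out.to_csv(path, index=False)


def read_midas(path) -> pd.DataFrame:
    """Read a MIDAS-style CSV back into the long format."""
    raw = pd.read_csv(path)
    dv_cols = [c for c in raw.columns if c.startswith("DV:")]
    rows = []
    for _, rec in raw.iterrows():
        for dv in dv_cols:
            rows.append({
                "node": dv[3:],
                "condition": rec.get("ID:condition", ""),
                "time_h": rec["DA:ALL"],
                "value": rec[dv],
            })
    return pd.DataFrame(rows, columns=LONG_COLUMNS)
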