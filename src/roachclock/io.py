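"""Reading and writing the package's text formats.

Configurations are YAML key–value files (matrices as nested numeric lists);
tabular data (activity records, Ct tables, trajectories, periodograms) are
comma-separated text with a header row, readable by any spreadsheet or by
pandas directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clockwork import CellSpec, ClockworkModel, CouplingSpec
from .rhythm import ActivityRecord, Periodogram
from .sls import SwitchingLinearSystem

__all__ = [
    "load_sls_config",
    "save_sls_config",
    "load_clockwork_config",
    "save_clockwork_config",
    "read_activity",
    "write_activity",
    "read_ct_table",
    "write_table",
    "write_periodogram",
]


# --- switching-linear-system configs ---------------------------------------

def save_sls_config(sys: SwitchingLinearSystem, path) -> None:
    """Threshold-form SLS config: mode matrices, switching threshold, x(0), tau."""
    if len(sys.regions) != 2:
        raise ValueError("config format covers the two-mode threshold oscillator")
    data = {
        "A_below": np.asarray(sys.dynamics[0].state_matrix).tolist(),
        "A_above": np.asarray(sys.dynamics[1].state_matrix).tolist(),
        "threshold": float(sys.regions[0].bound_vector[-1]),
        "x0": np.asarray(sys.x0).tolist(),
        "tau": float(sys.tau),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_sls_config(path) -> SwitchingLinearSystem:
    """Build a two-mode threshold oscillator from a YAML config.

    Unknown keys are rejected so typos fail loudly.
    """
    data = yaml.safe_load(Path(path).read_text())
    allowed = {"A_below", "A_above", "threshold", "x0", "tau"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in SLS config: {sorted(unknown)}")
    from .sls import ModeDynamics, ModeRegion

    thr = float(data.get("threshold", 10.0))
    A_below = np.asarray(data["A_below"], dtype=float)
    A_above = np.asarray(data["A_above"], dtype=float)
    region_below = ModeRegion(
        constraint_matrix=np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 1.0, 0.0]]),
        bound_vector=np.array([0.0, 0.0, thr]),
    )
    region_above = ModeRegion(
        constraint_matrix=np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0]]),
        bound_vector=np.array([0.0, -thr]),
    )
    return SwitchingLinearSystem(
        regions=(region_below, region_above),
        dynamics=(ModeDynamics(A_below), ModeDynamics(A_above)),
        x0=np.asarray(data.get("x0", [10.0, 10.0, 10.0]), dtype=float),
        tau=float(data.get("tau", 1.0)),
        labels=("below", "above"),
    )


# --- clockwork configs ------------------------------------------------------

def save_clockwork_config(model: ClockworkModel, path) -> None:
    data = {
        "cells": [
            {
                "network": c.network,
                "identity": c.identity,
                "tau": float(c.tau),
                "x0": list(c.x0),
            }
            for c in model.cells
        ],
        "coupling": {
            "E_Le": np.asarray(model.coupling.E_Le).tolist(),
            "E_La": np.asarray(model.coupling.E_La).tolist(),
            "F_Le": np.asarray(model.coupling.F_Le).tolist(),
            "F_La": np.asarray(model.coupling.F_La).tolist(),
            "output_weights": list(model.coupling.output_weights),
        },
        "threshold": float(model.threshold),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_clockwork_config(path) -> ClockworkModel:
    data = yaml.safe_load(Path(path).read_text())
    allowed = {"cells", "coupling", "threshold"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in clockwork config: {sorted(unknown)}")
    coupling = CouplingSpec()
    if "coupling" in data:
        cdata = dict(data["coupling"])
        unknown = set(cdata) - {"E_Le", "E_La", "F_Le", "F_La", "output_weights"}
        if unknown:
            raise ValueError(f"unknown coupling keys: {sorted(unknown)}")
        if "output_weights" in cdata:
            cdata["output_weights"] = tuple(cdata["output_weights"])
        coupling = CouplingSpec(**cdata)
    cells = tuple(
        CellSpec(
            index=i,
            network=c["network"],
            identity=c["identity"],
            tau=float(c["tau"]),
            x0=tuple(c.get("x0", (10.0, 10.0, 10.0))),
        )
        for i, c in enumerate(data["cells"])
    )
    return ClockworkModel(cells=cells, coupling=coupling, threshold=float(data.get("threshold", 10.0)))


# --- tabular data -----------------------------------------------------------

def read_activity(path, bin_width: float | None = None, metadata: dict | None = None) -> ActivityRecord:
    """Read a binned activity record.

    Two layouts are accepted: two columns ``time_h, count`` (bin width is
    inferred from the time grid and cross-checked against ``bin_width`` if
    given), or a single ``count`` column with ``bin_width`` declared by the
    caller.
    """
    df = pd.read_csv(path)
    if "count" not in df.columns:
        raise ValueError("activity table needs a 'count' column")
    if "time_h" in df.columns:
        steps = np.diff(df["time_h"].to_numpy())
        if steps.size == 0:
            raise ValueError("activity record needs at least two bins")
        inferred = float(np.median(steps))
        if not np.allclose(steps, inferred, rtol=1e-6, atol=1e-9):
            raise ValueError("time column is not a uniform grid")
        if bin_width is not None and not np.isclose(bin_width, inferred, rtol=1e-6):
            raise ValueError(
                f"declared bin width {bin_width} h disagrees with the time grid ({inferred} h)"
            )
        times = df["time_h"].to_numpy(dtype=float)
        bin_width = inferred
    else:
        if bin_width is None:
            raise ValueError("a counts-only table needs an explicit bin width")
        times = np.arange(len(df)) * bin_width
    return ActivityRecord(
        times=times,
        counts=df["count"].to_numpy(),
        bin_width=float(bin_width),
        metadata=metadata or {},
    )


def write_activity(record: ActivityRecord, path) -> None:
    record.to_frame().to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table with columns sample, gene, group, zt, ct."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample", "gene", "group", "zt", "ct") if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    return df


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def write_periodogram(pg: Periodogram, path) -> None:
    pg.to_frame().to_csv(path, index=False)
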