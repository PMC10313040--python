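"""Tabular and configuration I/O.

The primary interchange format is a long-format CSV with one row per cell per
timepoint and columns ``cell_id, time_h, fluorescence_au`` (plus optional
``phase_truth`` and ``cycle_index`` truth columns).  A read-only FCS 3.0/3.1
adapter can ingest list-mode flow-cytometry events, one file per timepoint.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, SchemaError
from .interphase import NoiseSpec
from .population import PopulationTimecourse, SimulationConfig

__all__ = [
    "write_timecourse",
    "read_events_table",
    "write_asf_series",
    "read_fcs",
    "timecourse_from_fcs",
    "AnalysisConfig",
]

REQUIRED_COLUMNS = ("cell_id", "time_h", "fluorescence_au")
TRUTH_COLUMNS = ("phase_truth", "cycle_index")


def write_timecourse(timecourse: PopulationTimecourse, path) -> None:
    """Write a timecourse as a long-format CSV (one row per cell per timepoint)."""
    n_cells, n_t = timecourse.measurements.shape
    cell_ids = np.repeat(np.arange(n_cells), n_t)
    times = np.tile(timecourse.times, n_cells)
    frame = pd.DataFrame({
        "cell_id": cell_ids,
        "time_h": times,
        "fluorescence_au": timecourse.measurements.ravel(),
    })
    if timecourse.truth_phase is not None:
        frame["phase_truth"] = timecourse.truth_phase.ravel()
    if timecourse.truth_cycle_index is not None:
        frame["cycle_index"] = timecourse.truth_cycle_index.ravel()
    frame.to_csv(path, index=False)


def read_events_table(path) -> PopulationTimecourse:
    """Read a long-format events CSV back into a ``PopulationTimecourse``.

    Row order is irrelevant; timepoints are inferred from the distinct
    ``time_h`` values.  Every cell must appear at every timepoint.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        On missing columns, non-numeric fluorescence, or a ragged
        cell x timepoint layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"events table not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"events table {path} is missing required columns {missing}")
    for col in ("time_h", "fluorescence_au"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            bad = int(frame.index[coerced.isna()][0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {bad}")
        frame[col] = coerced

    frame = frame.sort_values(["cell_id", "time_h"], kind="stable")
    times = np.sort(frame["time_h"].unique())
    cells = frame["cell_id"].unique()
    n_cells, n_t = len(cells), len(times)
    if len(frame) != n_cells * n_t:
        raise SchemaError(
            f"expected {n_cells} cells x {n_t} timepoints = {n_cells * n_t} rows, "
            f"got {len(frame)}"
        )
    measurements = frame["fluorescence_au"].to_numpy().reshape(n_cells, n_t)
    truth_phase = None
    truth_cycle = None
    if "phase_truth" in frame.columns:
        truth_phase = frame["phase_truth"].to_numpy(dtype=object).reshape(n_cells, n_t)
    if "cycle_index" in frame.columns:
        truth_cycle = frame["cycle_index"].to_numpy(dtype=int).reshape(n_cells, n_t)
    return PopulationTimecourse(
        times=times,
        measurements=measurements,
        truth_phase=truth_phase,
        truth_cycle_index=truth_cycle,
    )


def write_asf_series(series, path) -> None:
    """Write an ASF series as CSV with columns t_start,t_end,asf."""
    frame = pd.DataFrame({
        "t_start": [p[0] for p in series.pair_labels],
        "t_end": [p[1] for p in series.pair_labels],
        "asf": series.values,
    })
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode adapter (read-only, no compensation)
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise InvalidInputError("empty FCS TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path) -> pd.DataFrame:
    """Read list-mode events from an FCS 3.0/3.1 file.

    Supports float (``$DATATYPE F``/``D``) and unsigned-integer (``I``)
    list-mode data with little- or big-endian byte order.  Returns a frame
    with one column per channel, named by ``$PnN``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FCS file not found: {path}")
    blob = path.read_bytes()
    version = blob[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise InvalidInputError(f"unsupported FCS version {version!r} (need FCS 3.0/3.1)")
    text_start, text_end = int(blob[10:18]), int(blob[18:26])
    text = _parse_text_segment(blob[text_start:text_end + 1])

    data_start = int(text.get("$BEGINDATA", "0"))
    data_end = int(text.get("$ENDDATA", "0"))
    if data_start == 0 or data_end == 0:  # fall back to the header offsets
        data_start, data_end = int(blob[26:34]), int(blob[34:42])
    if text.get("$MODE", "L").upper() != "L":
        raise InvalidInputError("only list-mode ($MODE L) FCS data is supported")

    n_par = int(text["$PAR"])
    n_events = int(text["$TOT"])
    datatype = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    raw = blob[data_start:data_end + 1]
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        width = bits[0]
        if any(b != width for b in bits) or width not in (16, 32):
            raise InvalidInputError("only uniform 16/32-bit integer FCS data is supported")
        dtype = np.dtype(f"{endian}u{width // 8}")
    else:
        raise InvalidInputError(f"unsupported $DATATYPE {datatype!r}")
    needed = n_events * n_par * dtype.itemsize
    if len(raw) < needed:
        raise InvalidInputError(
            f"FCS DATA segment holds {len(raw)} bytes, need {needed} "
            f"({n_events} events x {n_par} channels)"
        )
    values = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_events, n_par)
    return pd.DataFrame(values.astype(float), columns=names)


def timecourse_from_fcs(paths, times, channel: str) -> PopulationTimecourse:
    """Assemble a timecourse from one FCS file per timepoint.

    Events are not tracked across files (flow cytometry is destructive), so
    cell identities are per-timepoint row indices; all files must carry the
    named channel and, to form a rectangular matrix, files are truncated to
    the smallest event count.
    """
    if len(paths) != len(times):
        raise InvalidInputError(f"{len(paths)} files but {len(times)} timepoints")
    if len(paths) == 0:
        raise InvalidInputError("need at least one FCS file")
    columns = []
    for p in paths:
        events = read_fcs(p)
        if channel not in events.columns:
            raise SchemaError(
                f"channel {channel!r} not in {Path(p).name}; available: {list(events.columns)}"
            )
        columns.append(events[channel].to_numpy())
    n = min(len(c) for c in columns)
    measurements = np.column_stack([c[:n] for c in columns])
    order = np.argsort(np.asarray(times, dtype=float))
    return PopulationTimecourse(
        times=np.asarray(times, dtype=float)[order],
        measurements=measurements[:, order],
    )


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Serializable configuration for a full pipeline run.

    Round-trips losslessly through YAML/JSON via :meth:`to_dict` /
    :meth:`from_dict`.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    normalize_asf: bool = True
    sigma_grid: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    estimate_reps: int = 5
    n_bins: int = 256
    seed: int = 0

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.simulation)
        sim["t_grid"] = [float(t) for t in sim["t_grid"]]
        return {
            "simulation": sim,
            "normalize_asf": self.normalize_asf,
            "sigma_grid": [float(s) for s in self.sigma_grid],
            "estimate_reps": self.estimate_reps,
            "n_bins": self.n_bins,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        sim_data = dict(data.pop("simulation", {}))
        noise_data = sim_data.pop("noise", {})
        sim = SimulationConfig(noise=NoiseSpec(**noise_data), **sim_data)
        return cls(
            simulation=sim,
            normalize_asf=bool(data.get("normalize_asf", True)),
            sigma_grid=tuple(data.get("sigma_grid", (1.0, 2.0, 3.0, 4.0, 5.0))),
            estimate_reps=int(data.get("estimate_reps", 5)),
            n_bins=int(data.get("n_bins", 256)),
            seed=int(data.get("seed", 0)),
        )

    def dump(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)
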