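"""Raw cursor-log ingestion, uniform resampling and complex embedding.

A cursor stream arrives as irregularly timestamped ``(x, y)`` pixel
positions (browser mouse-move events poll only while the cursor moves,
typically every 8--12 ms).  Analysis requires a uniform grid, so each
coordinate is linearly interpolated onto a fixed ``dt`` grid anchored at
the first observed timestamp, and the two spatial dimensions are folded
into a single complex series ``z_n = x_n + i*y_n`` so that 1-D
time-series machinery applies without discarding a dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RawTrace",
    "UniformTrace",
    "FormatError",
    "InsufficientDataError",
    "read_trace_log",
    "read_cohort_log",
    "complex_embed",
    "resample_uniform",
    "trim_cohort",
    "write_uniform_cohort",
    "read_uniform_cohort",
]


class FormatError(ValueError):
    """Input file does not expose the expected columns."""


class InsufficientDataError(ValueError):
    """Too few usable samples to resample or analyze."""


@dataclass
class RawTrace:
    """One participant's irregularly sampled cursor log.

    Parameters
    ----------
    participant_id : str
        Stable identifier, carried through every downstream artifact.
    t : ndarray
        Timestamps in milliseconds, sorted non-decreasing.
    x, y : ndarray
        Cursor position in pixels at each timestamp.
    clicks : list of (t, x, y), optional
        Click events; metadata only, never enters spectral or DFA
        computation.
    accuracy : float, optional
        Fraction of targets hit in the task, in [0, 1].
    """

    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    clicks: list | None = None
    accuracy: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise InsufficientDataError(
                f"trace {self.participant_id!r}: need >= 2 samples, got {len(self.t)}"
            )
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be sorted non-decreasing")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class UniformTrace:
    """Complex-valued cursor series on a fixed sampling grid.

    ``z[j]`` is the cursor position at time ``t0 + j*dt`` with the real
    part the horizontal and the imaginary part the vertical pixel
    coordinate.  Length is kept even so the two-sided spectrum index
    range ``-N/2 .. N/2-1`` is well-defined.
    """

    participant_id: str
    z: np.ndarray
    dt: float = 20.0
    t0: float = 0.0
    accuracy: float | None = None
    clicks: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=complex)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite values in z")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.z)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.z))


_DEFAULT_DIALECT = {
    "t": "t",
    "x": "x",
    "y": "y",
    "participant_id": "participant_id",
    "click": "click",
    "accuracy": "accuracy",
    "delimiter": ",",
}


def _resolve_columns(df: pd.DataFrame, dialect: dict) -> dict:
    cols = {}
    for key in ("t", "x", "y"):
        name = dialect.get(key, _DEFAULT_DIALECT[key])
        if name not in df.columns:
            raise FormatError(f"required column {name!r} (for {key}) not found")
        cols[key] = name
    return cols


def _frame_to_trace(df: pd.DataFrame, cols: dict, participant_id: str,
                    dialect: dict, accuracy: float | None = None) -> RawTrace:
    df = df.sort_values(cols["t"], kind="stable")
    # browsers can emit repeated poll times; last write wins
    df = df.drop_duplicates(subset=cols["t"], keep="last")
    if len(df) < 2:
        raise InsufficientDataError(
            f"trace {participant_id!r}: fewer than 2 usable rows"
        )
    clicks = None
    click_col = dialect.get("click", _DEFAULT_DIALECT["click"])
    if click_col in df.columns:
        hit = df[df[click_col].astype(float) > 0]
        clicks = list(zip(hit[cols["t"]].astype(float),
                          hit[cols["x"]].astype(float),
                          hit[cols["y"]].astype(float)))
    return RawTrace(
        participant_id=participant_id,
        t=df[cols["t"]].to_numpy(dtype=float),
        x=df[cols["x"]].to_numpy(dtype=float),
        y=df[cols["y"]].to_numpy(dtype=float),
        clicks=clicks,
        accuracy=accuracy,
    )


def read_trace_log(path, dialect: dict | None = None,
                   participant_id: str | None = None) -> RawTrace:
    """Read a single participant's delimited cursor log.

    Rows are sorted by timestamp; duplicate timestamps are collapsed
    keeping the last row.  ``dialect`` maps logical column names
    (``t``, ``x``, ``y``, optional ``click``) to file column names and
    may set ``delimiter``.
    """
    dialect = {**_DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=dialect["delimiter"])
    cols = _resolve_columns(df, dialect)
    pid = participant_id if participant_id is not None else str(path)
    return _frame_to_trace(df, cols, pid, dialect)


def read_cohort_log(path, dialect: dict | None = None) -> list[RawTrace]:
    """Read a long-format cohort CSV with a participant-id column.

    Expected columns: participant id, timestamp, x, y, optionally click
    and a per-participant accuracy (constant within participant).
    """
    dialect = {**_DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=dialect["delimiter"])
    cols = _resolve_columns(df, dialect)
    pid_col = dialect["participant_id"]
    if pid_col not in df.columns:
        raise FormatError(f"participant id column {pid_col!r} not found")
    acc_col = dialect.get("accuracy", "accuracy")
    traces = []
    for pid, grp in df.groupby(pid_col, sort=False):
        acc = None
        if acc_col in grp.columns:
            vals = grp[acc_col].dropna().unique()
            if len(vals):
                acc = float(vals[0])
        traces.append(_frame_to_trace(grp, cols, str(pid), dialect, accuracy=acc))
    return traces


def complex_embed(x, y) -> np.ndarray:
    """Embed paired coordinates as ``z_n = x_n + i*y_n``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x + 1j * y


def resample_uniform(raw: RawTrace, dt: float = 20.0) -> UniformTrace:
    """Resample a raw trace onto a uniform ``dt`` grid by linear interpolation.

    The grid starts at the first raw timestamp and never extends past the
    last one (no extrapolation: positions are only known while the cursor
    reported them).  x and y are interpolated independently, then embedded
    as one complex series; an odd-length result drops its final sample so
    the two-sided spectrum index range stays well-defined.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = raw.t[-1] - raw.t[0]
    if span < 2 * dt:
        raise InsufficientDataError(
            f"trace {raw.participant_id!r}: span {span} ms < 2*dt = {2 * dt} ms"
        )
    n_grid = int(np.floor(span / dt)) + 1
    grid = raw.t[0] + dt * np.arange(n_grid)
    xi = np.interp(grid, raw.t, raw.x)
    yi = np.interp(grid, raw.t, raw.y)
    z = complex_embed(xi, yi)
    if len(z) % 2:
        z = z[:-1]
    return UniformTrace(
        participant_id=raw.participant_id,
        z=z,
        dt=float(dt),
        t0=float(raw.t[0]),
        accuracy=raw.accuracy,
        clicks=raw.clicks,
    )


def trim_cohort(traces: list[UniformTrace]) -> list[UniformTrace]:
    """Trim every trace to the cohort's shortest length (forced even).

    Pass the union of all samples to trim jointly across cohorts; the
    first ``N*`` samples of each trace are kept.
    """
    if not traces:
        raise ValueError("empty cohort")
    dts = {tr.dt for tr in traces}
    if len(dts) > 1:
        raise ValueError(f"mixed sampling intervals in cohort: {sorted(dts)}")
    n_star = min(len(tr) for tr in traces)
    n_star -= n_star % 2
    if n_star < 2:
        raise InsufficientDataError("cohort minimum length below 2 samples")
    return [replace(tr, z=tr.z[:n_star]) for tr in traces]


def write_uniform_cohort(traces: list[UniformTrace], path) -> None:
    """Write uniform traces as long-format CSV (participant_id, t_ms, x, y).

    Values are written with 17 significant digits so a read-back
    round-trips bit-exactly at double precision.
    """
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "t_ms": tr.times,
            "x": tr.z.real,
            "y": tr.z.imag,
            "accuracy": tr.accuracy if tr.accuracy is not None else np.nan,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_uniform_cohort(path) -> list[UniformTrace]:
    """Read traces written by :func:`write_uniform_cohort`."""
    df = pd.read_csv(path, float_precision="round_trip")
    traces = []
    for pid, grp in df.groupby("participant_id", sort=False):
        t = grp["t_ms"].to_numpy(dtype=float)
        if len(t) < 2:
            raise InsufficientDataError(f"trace {pid!r}: fewer than 2 rows")
        steps = np.diff(t)
        # snap against last-ulp wobble in the printed grid so cohorts read
        # back from CSV agree on dt exactly
        dt = round(float(np.median(steps)), 9)
        if not np.allclose(steps, dt, rtol=1e-9, atol=1e-6):
            raise ValueError(f"trace {pid!r}: grid not uniform")
        acc = None
        if "accuracy" in grp.columns:
            v = grp["accuracy"].iloc[0]
            if np.isfinite(v):
                acc = float(v)
        traces.append(UniformTrace(
            participant_id=str(pid),
            z=complex_embed(grp["x"].to_numpy(float), grp["y"].to_numpy(float)),
            dt=float(dt),
            t0=float(t[0]),
            accuracy=acc,
        ))
    return traces
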