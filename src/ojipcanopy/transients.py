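"""Fast chlorophyll-fluorescence transients: data model and delimited I/O.

A *transient* is one dark-adapted fluorescence-induction curve recorded by a
continuous-excitation fluorimeter under saturating light: a strictly
increasing time axis (seconds) and positive fluorescence values (instrument
units), plus the sample metadata used downstream (nitrogen level, growth
stage, canopy layer).

The instrument class emulated here samples densely during the fast O-J phase
(every 10 us up to 2 ms) and more coarsely afterwards (every 1 ms up to ~1 s),
which is the `InstrumentGrid` default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, OutOfRangeError, ValidationError

NITROGEN_LEVELS = ("N0", "N1", "N2")
STAGES = ("V1", "V2", "V3", "R1", "R2", "R3", "R4", "R5")
VEGETATIVE_STAGES = ("V1", "V2", "V3")
LAYERS = ("L1", "L2", "L3", "L4", "L5")

# Canonical landmark read-out times (seconds).  F0 is read at 50 us (the first
# reliable sample on this instrument class), the J step at 2 ms, the I step at
# 30 ms, with the 300-us point feeding the initial-slope estimate.
T_F0 = 50e-6
T_F300 = 300e-6
T_FJ = 2e-3
T_FI = 30e-3

TRANSIENT_COLUMNS = ("sample_id", "nitrogen", "stage", "layer", "time_s", "fluorescence")


@dataclass(frozen=True)
class InstrumentGrid:
    """Two-rate sampling grid: ``fast_step`` spacing on (0, fast_until] and
    ``slow_step`` spacing on (fast_until, total_duration]."""

    fast_step: float = 1e-5
    fast_until: float = 2e-3
    slow_step: float = 1e-3
    total_duration: float = 1.0

    def __post_init__(self) -> None:
        if min(self.fast_step, self.fast_until, self.slow_step, self.total_duration) <= 0:
            raise ValidationError("grid parameters must all be positive")
        if not self.fast_step < self.slow_step:
            raise ValidationError("fast_step must be smaller than slow_step")
        if not self.fast_until < self.total_duration:
            raise ValidationError("fast_until must precede total_duration")

    def times(self) -> np.ndarray:
        """Sampling times in seconds (excludes t = 0; the instrument's first
        sample is one fast step after light-on)."""
        n_fast = int(round(self.fast_until / self.fast_step))
        fast = self.fast_step * np.arange(1, n_fast + 1)
        n_slow = int(round((self.total_duration - self.fast_until) / self.slow_step))
        slow = self.fast_until + self.slow_step * np.arange(1, n_slow + 1)
        return np.concatenate([fast, slow])


DEFAULT_GRID = InstrumentGrid()


@dataclass(frozen=True)
class Transient:
    """One fluorescence-induction curve with its sample metadata."""

    sample_id: str
    nitrogen: str
    stage: str
    layer: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.nitrogen not in NITROGEN_LEVELS:
            raise ValidationError(f"unknown nitrogen level {self.nitrogen!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown growth stage {self.stage!r}")
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown canopy layer {self.layer!r}")
        if times.ndim != 1 or times.shape != values.shape:
            raise ValidationError("times and values must be 1-D and equal length")
        if times.size < 2:
            raise ValidationError("a transient needs at least two samples")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"times not strictly increasing for {self.sample_id!r}")
        if times[0] > T_F0:
            raise ValidationError(
                f"first sample of {self.sample_id!r} at {times[0]:g} s is after the "
                f"{T_F0:g} s F0 read-out"
            )
        if times[-1] < T_FI:
            raise ValidationError(
                f"last sample of {self.sample_id!r} at {times[-1]:g} s precedes the "
                f"{T_FI:g} s I-step read-out"
            )
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError(f"non-finite or non-positive fluorescence in {self.sample_id!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray) -> "Transient":
        return replace(self, values=np.asarray(values, dtype=float))


def fluorescence_at(transient: Transient, t: float) -> float:
    """Fluorescence at time ``t`` (s), linearly interpolated in time.

    Exact at grid nodes; raises :class:`OutOfRangeError` outside the recorded
    range (the curve is never extrapolated).
    """
    times = transient.times
    if t < times[0] or t > times[-1]:
        raise OutOfRangeError(
            f"t = {t:g} s outside recorded range [{times[0]:g}, {times[-1]:g}] s"
        )
    return float(np.interp(t, times, transient.values))


def read_transients(path: str | Path) -> list[Transient]:
    """Read a delimited transient table into one :class:`Transient` per
    distinct ``sample_id``.

    The file must be comma-separated with a header naming the columns
    ``sample_id, nitrogen, stage, layer, time_s, fluorescence``.  Rows are
    grouped by sample (order of first appearance) and sorted by time within a
    sample; duplicate times and inconsistent metadata raise
    :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRANSIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    transients: list[Transient] = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        meta = group[["nitrogen", "stage", "layer"]].drop_duplicates()
        if len(meta) != 1:
            raise ValidationError(f"inconsistent metadata for sample {sample_id!r}")
        group = group.sort_values("time_s", kind="mergesort")
        transients.append(
            Transient(
                sample_id=str(sample_id),
                nitrogen=str(meta.iloc[0]["nitrogen"]),
                stage=str(meta.iloc[0]["stage"]),
                layer=str(meta.iloc[0]["layer"]),
                times=group["time_s"].to_numpy(dtype=float),
                values=group["fluorescence"].to_numpy(dtype=float),
            )
        )
    return transients


def transients_to_frame(transients: Iterable[Transient]) -> pd.DataFrame:
    """Long-format table (one row per sampled point) for a collection."""
    parts = []
    for tr in transients:
        parts.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "nitrogen": tr.nitrogen,
                    "stage": tr.stage,
                    "layer": tr.layer,
                    "time_s": tr.times,
                    "fluorescence": tr.values,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(TRANSIENT_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def write_transients(transients: Sequence[Transient], path: str | Path) -> None:
    """Write the CSV dialect that :func:`read_transients` reads back."""
    transients_to_frame(transients).to_csv(path, index=False)
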