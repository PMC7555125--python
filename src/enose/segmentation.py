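"""Thermal-cycle detection from the synchronization channels.

The heaters of all 14 sensors are driven together: 3.5 s on, 5.5 s off.
Channels 15 and 16 carry a square wave locked to that drive (a positive
constant while heating, zero while cooling) whose only purpose is to let
the preprocessing stage cut each record into thermal periods exactly.

Conventions fixed here and used everywhere downstream:

* 0-based sample indices, half-open ``[start, end)`` intervals;
* a heat->cool transition is the first index of a maximal run of zeros on
  a sync channel; runs shorter than ``min_run`` samples (default 5) are
  treated as acquisition glitches and merged into their neighbours;
* the two sync channels must agree on every transition — disagreement is
  an acquisition-integrity failure and raises, never a majority vote;
* a *complete* cycle is a heating run followed by a cooling phase whose
  full 165 samples lie inside the record; partial leading/trailing cycles
  are discarded, and ``cycle_index`` numbers complete cycles from 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .exceptions import InsufficientCyclesError, SyncChannelError
from .records import COOL_SAMPLES, N_SENSORS, SensorRecord

#: Minimum number of complete cycles the feature stage needs (period 4 / period 1).
MIN_CYCLES = 4


@dataclass(frozen=True)
class ThermalCycle:
    """One complete heating/cooling period, in 0-based half-open indices."""

    cycle_index: int  # 1-based position among complete cycles
    heat_start: int
    cool_start: int
    cool_end: int


@dataclass
class SegmentedRecord:
    """Cooling-phase sensor data of one record, cut along detected cycles.

    ``cooling_segments`` has shape (14 sensors, n_cycles, 165 samples).
    """

    record_id: str
    cycles: List[ThermalCycle]
    cooling_segments: np.ndarray
    age: int
    sex: str
    smoking: str
    label: int

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def _runs(binary: np.ndarray) -> List[Tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, length, value)."""
    change = np.flatnonzero(np.diff(binary.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [binary.size]])
    return [(int(s), int(e - s), bool(binary[s])) for s, e in zip(starts, ends)]


def _debounced_runs(binary: np.ndarray, min_run: int) -> List[Tuple[int, int, bool]]:
    """Run-length encoding with runs shorter than ``min_run`` absorbed.

    A short run is flipped to its neighbours' value and adjacent equal
    runs are merged; repeated until stable.  Record-edge runs are subject
    to the same rule.
    """
    runs = _runs(binary)
    while True:
        short = [i for i, (_, length, _) in enumerate(runs) if length < min_run]
        if not short or len(runs) == 1:
            return runs
        i = short[0]
        start, length, value = runs[i]
        runs[i] = (start, length, not value)
        merged: List[Tuple[int, int, bool]] = []
        for run in runs:
            if merged and merged[-1][2] == run[2]:
                s, l, v = merged[-1]
                merged[-1] = (s, l + run[1], v)
            else:
                merged.append(run)
        runs = merged


def _transitions(runs: Sequence[Tuple[int, int, bool]]) -> List[Tuple[int, str]]:
    """Interior phase transitions as (sample_index, 'heat->cool'|'cool->heat')."""
    out = []
    for prev, cur in zip(runs, runs[1:]):
        kind = "heat->cool" if prev[2] else "cool->heat"
        out.append((cur[0], kind))
    return out


def detect_cycles(record: SensorRecord, min_run: int = 5) -> List[ThermalCycle]:
    """Locate complete thermal cycles from the two sync channels.

    Raises :class:`SyncChannelError` if the channels disagree on any
    transition and :class:`InsufficientCyclesError` if fewer than
    :data:`MIN_CYCLES` complete cycles fit in the record.
    """
    n_samples = record.channels.shape[1]
    sync_a = record.channels[N_SENSORS] > 0
    sync_b = record.channels[N_SENSORS + 1] > 0
    runs_a = _debounced_runs(sync_a, min_run)
    runs_b = _debounced_runs(sync_b, min_run)
    trans_a = _transitions(runs_a)
    trans_b = _transitions(runs_b)
    for ta, tb in zip(trans_a, trans_b):
        if ta != tb:
            raise SyncChannelError(min(ta[0], tb[0]))
    if len(trans_a) != len(trans_b):
        extra = (trans_a if len(trans_a) > len(trans_b) else trans_b)[
            min(len(trans_a), len(trans_b))
        ]
        raise SyncChannelError(extra[0])

    cycles: List[ThermalCycle] = []
    for prev, cur in zip(runs_a, runs_a[1:]):
        if prev[2] and not cur[2]:  # heating run followed by cooling run
            cool_start = cur[0]
            cool_end = cool_start + COOL_SAMPLES
            if cool_end <= n_samples and cur[1] >= COOL_SAMPLES:
                cycles.append(
                    ThermalCycle(
                        cycle_index=len(cycles) + 1,
                        heat_start=prev[0],
                        cool_start=cool_start,
                        cool_end=cool_end,
                    )
                )
    if len(cycles) < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"{record.record_id}: only {len(cycles)} complete thermal cycle(s) "
            f"detected; at least {MIN_CYCLES} required"
        )
    return cycles


def extract_cooling_segments(
    record: SensorRecord, cycles: Sequence[ThermalCycle]
) -> SegmentedRecord:
    """Slice the 14 sensor channels along the detected cooling phases."""
    segments = np.stack(
        [record.channels[:N_SENSORS, c.cool_start : c.cool_end] for c in cycles],
        axis=1,
    )
    return SegmentedRecord(
        record_id=record.record_id,
        cycles=list(cycles),
        cooling_segments=segments,
        age=record.age,
        sex=record.sex,
        smoking=record.smoking,
        label=record.label,
    )


def segment_record(record: SensorRecord, min_run: int = 5) -> SegmentedRecord:
    """Detect cycles and extract cooling segments in one step."""
    return extract_cooling_segments(record, detect_cycles(record, min_run=min_run))
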