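"""Emotional Attention Task (EAT) paradigm and hemodynamic regressors.

The EAT is a block design alternating face-emotion matching (ME) and shape
matching (MS): four blocks in the order MS-ME-ME-MS, each of 20 trials
presented for 5 s back to back, each block followed by a 10 s instruction
screen and 10 s of crosshair fixation, for an 8 min run.

This module builds that timeline, samples condition indicator functions on
the scanner's volume grid, and convolves them with a double-gamma
hemodynamic response function (HRF) to obtain BOLD regressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Event",
    "TaskDesign",
    "HRFParams",
    "RegressorSeries",
    "build_eat_design",
    "sample_indicator",
    "hrf_kernel",
    "convolve_regressor",
]

# EAT timing constants (seconds)
TRIAL_S = 5.0
TRIALS_PER_BLOCK = 20
INSTR_S = 10.0
FIX_S = 10.0
BLOCK_ORDER = ("MS", "ME", "ME", "MS")


class Condition(str, Enum):
    """Task conditions: match-shapes, match-emotions, instructions, fixation."""

    MS = "MS"
    ME = "ME"
    INSTR = "INSTR"
    FIX = "FIX"


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: Condition

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"negative onset {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"non-positive duration {self.duration_s}")


@dataclass
class TaskDesign:
    """Ordered event timeline defining the paradigm.

    Events must have non-negative, strictly increasing onsets and must not
    overlap within a condition track; ``total_duration_s`` must cover every
    event.
    """

    events: list[Event]
    total_duration_s: float

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        end = max((e.onset_s + e.duration_s for e in self.events), default=0.0)
        if self.total_duration_s < end - 1e-9:
            raise ValueError(
                f"total_duration_s={self.total_duration_s} < last event end {end}"
            )
        # overlap check within each condition track
        by_cond: dict[Condition, list[Event]] = {}
        for e in self.events:
            by_cond.setdefault(e.condition, []).append(e)
        for cond, evs in by_cond.items():
            for a, b in zip(evs, evs[1:]):
                if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                    raise ValueError(f"overlapping {cond.value} events at {b.onset_s}")

    def to_events_table(self) -> pd.DataFrame:
        """BIDS-style events table with onset, duration, trial_type columns."""
        return pd.DataFrame(
            {
                "onset": [e.onset_s for e in self.events],
                "duration": [e.duration_s for e in self.events],
                "trial_type": [e.condition.value for e in self.events],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_events_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events_table(
        cls, table: pd.DataFrame, total_duration_s: float | None = None
    ) -> "TaskDesign":
        events = [
            Event(float(r.onset), float(r.duration), Condition(r.trial_type))
            for r in table.itertuples()
        ]
        if total_duration_s is None:
            total_duration_s = max(e.onset_s + e.duration_s for e in events)
        return cls(events=events, total_duration_s=total_duration_s)

    @classmethod
    def from_tsv(cls, path: str | Path, total_duration_s: float | None = None) -> "TaskDesign":
        return cls.from_events_table(pd.read_csv(path, sep="\t"), total_duration_s)


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (canonical defaults).

    The response is a positive gamma lobe peaking at ``peak1_shape * scale1_s``
    seconds minus ``undershoot_ratio`` times a later gamma lobe, truncated at
    ``duration_s``.
    """

    peak1_shape: float = 6.0
    peak2_shape: float = 12.0
    scale1_s: float = 0.9
    scale2_s: float = 0.9
    undershoot_ratio: float = 0.35
    duration_s: float = 28.0

    def __post_init__(self) -> None:
        if min(self.peak1_shape, self.peak2_shape, self.scale1_s, self.scale2_s) <= 0:
            raise ValueError("HRF shapes and scales must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must lie in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class RegressorSeries:
    """A per-volume regressor: sampled values, repetition time, and a label."""

    values: np.ndarray
    tr_s: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def __len__(self) -> int:
        return len(self.values)


def build_eat_design() -> TaskDesign:
    """Construct the EAT timeline: MS-ME-ME-MS, 20x5 s trials per block,
    each block followed by 10 s instructions and 10 s fixation (480 s total)."""
    events: list[Event] = []
    t = 0.0
    for block_cond in BLOCK_ORDER:
        cond = Condition(block_cond)
        for _ in range(TRIALS_PER_BLOCK):
            events.append(Event(t, TRIAL_S, cond))
            t += TRIAL_S
        events.append(Event(t, INSTR_S, Condition.INSTR))
        t += INSTR_S
        events.append(Event(t, FIX_S, Condition.FIX))
        t += FIX_S
    return TaskDesign(events=events, total_duration_s=t)


def sample_indicator(
    design: TaskDesign, condition: Condition | str, tr_s: float, n_volumes: int
) -> RegressorSeries:
    """Sample a condition's indicator on the volume grid.

    The value at volume ``k`` is the fraction of the half-open interval
    ``[k*TR, (k+1)*TR)`` covered by events of the condition, in [0, 1].
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    try:
        cond = Condition(condition)
    except ValueError:
        valid = ", ".join(c.value for c in Condition)
        raise ValueError(f"unknown condition {condition!r}; valid: {valid}") from None

    starts = np.arange(n_volumes) * tr_s
    ends = starts + tr_s
    values = np.zeros(n_volumes)
    for e in design.events:
        if e.condition is not cond:
            continue
        overlap = np.clip(
            np.minimum(ends, e.onset_s + e.duration_s) - np.maximum(starts, e.onset_s),
            0.0,
            None,
        )
        values += overlap / tr_s
    return RegressorSeries(np.clip(values, 0.0, 1.0), tr_s, label=cond.value)


def hrf_kernel(params: HRFParams | None = None, tr_s: float = 2.5) -> RegressorSeries:
    """Sample the double-gamma HRF kernel on the TR grid.

    Uses the two-gamma form h(t) = (t/d1)^a1 exp(-(t-d1)/b1)
    - c (t/d2)^a2 exp(-(t-d2)/b2) with d_i = a_i * b_i (each lobe peaks at
    d_i with unit height), truncated at ``duration_s`` and rescaled so the
    kernel's peak absolute value is 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.duration_s + 1e-9, tr_s)
    d1 = p.peak1_shape * p.scale1_s
    d2 = p.peak2_shape * p.scale2_s
    with np.errstate(divide="ignore", invalid="ignore"):
        lobe1 = (t / d1) ** p.peak1_shape * np.exp(-(t - d1) / p.scale1_s)
        lobe2 = (t / d2) ** p.peak2_shape * np.exp(-(t - d2) / p.scale2_s)
    h = np.nan_to_num(lobe1 - p.undershoot_ratio * lobe2)
    peak = np.abs(h).max()
    if peak > 0:
        h = h / peak
    return RegressorSeries(h, tr_s, label="hrf")


def convolve_regressor(indicator: RegressorSeries, kernel: RegressorSeries) -> RegressorSeries:
    """Causal discrete convolution of an indicator with the HRF kernel,
    truncated to the indicator's length."""
    if not np.isclose(indicator.tr_s, kernel.tr_s, rtol=1e-9):
        raise ValueError(
            f"TR mismatch: indicator {indicator.tr_s} s vs kernel {kernel.tr_s} s"
        )
    out = np.convolve(indicator.values, kernel.values)[: len(indicator)]
    return RegressorSeries(out, indicator.tr_s, label=f"conv({indicator.label})")
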