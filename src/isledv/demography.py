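"""Rescaling MSMC2-style coalescence-rate output into real-time Ne
trajectories, and the two scalar summaries used downstream: recent Ne and the
time-weighted harmonic mean Ne over a fixed horizon (default 200,000 years).

MSMC2 reports time boundaries in per-site mutation units and coalescence
rates lambda in coalescent units.  With a per-generation mutation rate
``mu_g = mu_per_year * generation_time``:

    t_years = (scaled_time / mu_g) * generation_time
    Ne      = 1 / (2 * mu_g * lambda)

The harmonic mean is the right long-term summary because genetic drift
compounds as 1/Ne: a single bottleneck epoch dominates diversity loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class ScalingParams:
    """Mutation rate (substitutions/site/year) and generation time (years)."""

    mu_per_year: float = 3.16e-9
    generation_time_years: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.generation_time_years <= 0:
            raise ValueError("mutation rate and generation time must be positive")

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.generation_time_years


@dataclass
class ScaledEpoch:
    """One MSMC2 output row: scaled time boundaries (per-site mutation units)
    and a dimensionless coalescence rate."""

    index: int
    left_time: float
    right_time: float  # math.inf for the final, unbounded epoch
    lam: float


@dataclass
class DemographicEpoch:
    """One (time interval, Ne) step in real units: years before present and
    diploid individuals."""

    t_start: float
    t_end: float
    ne: float


@dataclass
class NeSummary:
    sample: str
    recent_ne: float
    harmonic_mean_ne: float
    horizon_years: float = 200_000.0


def read_msmc(path: str) -> List[ScaledEpoch]:
    """Read an MSMC2 ``.final.txt`` whitespace-delimited table with columns
    time_index, left_time_boundary, right_time_boundary, lambda."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"time_index", "left_time_boundary", "right_time_boundary", "lambda"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MSMC table missing columns: {sorted(missing)}")
    epochs = []
    for _, row in df.iterrows():
        right = float(row["right_time_boundary"])
        if math.isnan(right):
            right = math.inf
        epochs.append(
            ScaledEpoch(int(row["time_index"]), float(row["left_time_boundary"]), right, float(row["lambda"]))
        )
    return epochs


def unscale(epochs: Sequence[ScaledEpoch], p: ScalingParams = ScalingParams()) -> List[DemographicEpoch]:
    """Convert scaled epochs to years-before-present and diploid Ne."""
    mu_g = p.mu_per_generation
    out = []
    for e in epochs:
        if e.lam <= 0:
            raise ValueError(f"non-positive coalescence rate at epoch {e.index}")
        out.append(
            DemographicEpoch(
                t_start=e.left_time / mu_g * p.generation_time_years,
                t_end=e.right_time / mu_g * p.generation_time_years,
                ne=1.0 / (2.0 * mu_g * e.lam),
            )
        )
    return out


def rescale(trajectory: Sequence[DemographicEpoch], p: ScalingParams = ScalingParams()) -> List[ScaledEpoch]:
    """Exact inverse of :func:`unscale`."""
    mu_g = p.mu_per_generation
    out = []
    for i, e in enumerate(trajectory):
        if e.ne <= 0:
            raise ValueError("Ne must be positive")
        out.append(
            ScaledEpoch(
                index=i,
                left_time=e.t_start / p.generation_time_years * mu_g,
                right_time=e.t_end / p.generation_time_years * mu_g,
                lam=1.0 / (2.0 * mu_g * e.ne),
            )
        )
    return out


def recent_ne(trajectory: Sequence[DemographicEpoch], skip_first: bool = False) -> float:
    """Ne of the epoch containing the present (time 0), or the next epoch
    with ``skip_first`` (the most recent MSMC2 epoch is notoriously noisy)."""
    if not trajectory:
        raise ValueError("empty trajectory")
    ordered = sorted(trajectory, key=lambda e: e.t_start)
    k = 1 if skip_first and len(ordered) > 1 else 0
    return ordered[k].ne


def harmonic_mean_ne(trajectory: Sequence[DemographicEpoch], horizon: float = 200_000.0) -> float:
    """Time-weighted harmonic mean Ne over [0, horizon) years:
    ``horizon / sum_i(dt_i / ne_i)`` with epochs clipped to the horizon and
    the final epoch treated as unbounded.  Raises on a coverage gap."""
    if not trajectory:
        raise ValueError("empty trajectory")
    ordered = sorted(trajectory, key=lambda e: e.t_start)
    if ordered[0].t_start > 0:
        raise ValueError("trajectory does not cover time 0")
    acc = 0.0
    covered = 0.0
    for i, e in enumerate(ordered):
        if i > 0 and e.t_start > ordered[i - 1].t_end + 1e-9 * horizon:
            raise ValueError(f"gap in trajectory coverage before {e.t_start} years")
        t_end = e.t_end if i < len(ordered) - 1 else max(e.t_end, horizon)
        lo = max(e.t_start, 0.0)
        hi = min(t_end, horizon)
        if hi > lo:
            acc += (hi - lo) / e.ne
            covered = max(covered, hi)
    if covered < horizon * (1 - 1e-12):
        raise ValueError("trajectory does not cover the full horizon")
    return horizon / acc


def summarize_ne(
    trajectory: Sequence[DemographicEpoch],
    sample: str = "",
    horizon: float = 200_000.0,
    skip_first: bool = False,
) -> NeSummary:
    return NeSummary(
        sample=sample,
        recent_ne=recent_ne(trajectory, skip_first=skip_first),
        harmonic_mean_ne=harmonic_mean_ne(trajectory, horizon=horizon),
        horizon_years=horizon,
    )


def write_trajectory_csv(trajectory: Sequence[DemographicEpoch], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("t_start,t_end,ne\n")
        for e in trajectory:
            fh.write(f"{e.t_start:.6g},{e.t_end:.6g},{e.ne:.6g}\n")
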