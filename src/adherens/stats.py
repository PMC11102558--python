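"""Group-level statistics and TEER utilities.

The per-cell discontinuity ratios are heavily tied, bounded percentages with
no distributional guarantee, so conditions are compared with the
Kruskal–Wallis rank test (tie-corrected H, chi-squared approximation).
The unit of analysis is the cell, pooled across the images of a condition;
a per-image aggregation is also available but note that cells within one
image share acquisition conditions and are not independent.

Transendothelial electrical resistance (TEER) is the orthogonal functional
readout of barrier integrity: raw well resistance minus the blank
(cell-free) well, scaled by the insert membrane area of 0.32 cm^2, and
usually reported relative to the pre-stimulation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


@dataclass
class GroupComparison:
    """Kruskal–Wallis omnibus result plus box-plot summaries per group."""

    group_labels: list[str]
    per_group_ratios: dict[str, list[float]]
    H_statistic: float
    p_value: float
    group_summaries: dict[str, GroupSummary] = field(default_factory=dict)


def kruskal_wallis(per_group_ratios: dict[str, list[float]]) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis H with chi-squared p (df = groups - 1).

    Identical pooled distributions give H = 0 and p = 1. Group summaries use
    linear-interpolation quartiles for reproducible box plots.
    """
    labels = list(per_group_ratios)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    groups = [np.asarray(per_group_ratios[g], dtype=float) for g in labels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations tie: H is 0 by convention, the test is vacuous
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*groups)
    summaries = {
        g: GroupSummary(
            n=len(v),
            median=float(np.percentile(v, 50)),
            q1=float(np.percentile(v, 25)),
            q3=float(np.percentile(v, 75)),
            minimum=float(np.min(v)),
            maximum=float(np.max(v)),
        )
        for g, v in zip(labels, groups)
    }
    return GroupComparison(
        group_labels=labels,
        per_group_ratios={g: list(map(float, v)) for g, v in zip(labels, groups)},
        H_statistic=float(H),
        p_value=float(p),
        group_summaries=summaries,
    )


# ---------------------------------------------------------------------------
# TEER

#: membrane area (cm^2) of the standard 24-well 0.4 µm cell-culture insert
DEFAULT_AREA_FACTOR = 0.32


def compute_teer(
    raw_resistance: float, blank_resistance: float, area_factor: float = DEFAULT_AREA_FACTOR
) -> float:
    """TEER in ohm*cm^2: (experimental well - blank well) * membrane area."""
    if blank_resistance < 0:
        raise ValueError("blank_resistance must be >= 0")
    if raw_resistance < blank_resistance:
        raise ValueError(
            "raw resistance below blank resistance: check well/blank labeling "
            f"(raw={raw_resistance}, blank={blank_resistance})"
        )
    return (raw_resistance - blank_resistance) * area_factor


@dataclass
class TeerSeries:
    """Time course of blank-corrected, area-normalized resistance."""

    timepoints: list[float]                 # hours
    raw_resistance: list[float]             # ohms
    blank_resistance: list[float]           # ohms
    area_factor: float = DEFAULT_AREA_FACTOR
    teer: list[float] = field(default_factory=list)        # ohm*cm^2
    relative_teer: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.raw_resistance) != len(self.timepoints) or len(
            self.blank_resistance
        ) != len(self.timepoints):
            raise ValueError("timepoints, raw and blank resistance must have equal length")
        if not self.teer:
            self.teer = [
                compute_teer(r, b, self.area_factor)
                for r, b in zip(self.raw_resistance, self.blank_resistance)
            ]


def relative_teer(series: TeerSeries, baseline_time: float) -> TeerSeries:
    """Divide the TEER course by its value at the pre-stimulation baseline.

    The baseline entry becomes exactly 1; the result is invariant to any
    common rescaling of the resistance readings.
    """
    times = np.asarray(series.timepoints, dtype=float)
    match = np.nonzero(times == float(baseline_time))[0]
    if len(match) == 0:
        raise ValueError(f"baseline_time {baseline_time} not present in timepoints")
    baseline = series.teer[int(match[0])]
    if baseline <= 0:
        raise ValueError(f"baseline TEER must be positive, got {baseline}")
    return TeerSeries(
        timepoints=list(series.timepoints),
        raw_resistance=list(series.raw_resistance),
        blank_resistance=list(series.blank_resistance),
        area_factor=series.area_factor,
        teer=list(series.teer),
        relative_teer=[t / baseline for t in series.teer],
    )
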