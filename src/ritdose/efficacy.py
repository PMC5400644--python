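"""Tumor-growth efficacy statistics for radioimmunotherapy experiments.

Caliper measurements become ellipsoid-approximation volumes, each animal's
growth curve is summarized by its trapezoidal area under the curve (AUC),
and treatment groups are compared with a one-way ANOVA at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthRecord",
    "GroupComparison",
    "caliper_volume",
    "growth_auc",
    "compare_groups",
]


def caliper_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid xenograft volume V = length x width^2 / 2 [mm^3].

    Inputs with width > length are swapped with a warning (the caliper
    convention takes length as the larger axis).
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} > length {length_mm}; swapping axes", stacklevel=2
        )
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0


@dataclass(frozen=True)
class GrowthRecord:
    """One animal's tumor-volume time course."""

    mouse_id: str
    group: str
    days: np.ndarray
    volumes_mm3: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        v = np.asarray(self.volumes_mm3, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("days and volumes must be matching 1-D arrays")
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"mouse {self.mouse_id}: days must be increasing")
        if np.any(v < 0):
            raise ValueError(f"mouse {self.mouse_id}: negative volume")
        object.__setattr__(self, "days", d)
        object.__setattr__(self, "volumes_mm3", v)

    @classmethod
    def from_caliper(
        cls, mouse_id: str, group: str, days, lengths_mm, widths_mm
    ) -> "GrowthRecord":
        vols = [caliper_volume(l, w) for l, w in zip(lengths_mm, widths_mm)]
        return cls(mouse_id=mouse_id, group=group, days=np.asarray(days, float),
                   volumes_mm3=np.asarray(vols, float))


def growth_auc(
    record: GrowthRecord, t_end: float | None = None, baseline_subtract: bool = False
) -> float:
    """Trapezoidal AUC [mm^3·day] up to ``t_end`` (last measurement default).

    No extrapolation past the last measurement; the baseline is the day of
    the first measurement, optionally subtracting the starting volume.
    """
    d, v = record.days, record.volumes_mm3
    if t_end is not None:
        keep = d <= t_end
        d, v = d[keep], v[keep]
    if d.size < 2:
        raise ValueError(
            f"mouse {record.mouse_id}: AUC needs >= 2 measurements in range"
        )
    if baseline_subtract:
        v = v - v[0]
    return float(np.trapezoid(v, d))


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA summary across treatment groups."""

    f_stat: float
    p_value: float
    significant: bool
    alpha: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_n: dict[str, int]
    degenerate: bool = False


def compare_groups(
    aucs_by_group: dict[str, list[float] | np.ndarray], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA on per-animal AUCs; significance flag at ``alpha``.

    Groups with all values identical across the board produce a degenerate
    exact-equality report instead of a test.
    """
    if len(aucs_by_group) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in aucs_by_group.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 animals")
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sems = {
        g: float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
        for g, a in arrays.items()
    }
    ns = {g: int(a.size) for g, a in arrays.items()}
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        return GroupComparison(
            f_stat=float("nan"),
            p_value=float("nan"),
            significant=False,
            alpha=alpha,
            group_means=means,
            group_sems=sems,
            group_n=ns,
            degenerate=True,
        )
    f_stat, p_value = stats.f_oneway(*arrays.values())
    return GroupComparison(
        f_stat=float(f_stat),
        p_value=float(p_value),
        significant=bool(p_value < alpha),
        alpha=alpha,
        group_means=means,
        group_sems=sems,
        group_n=ns,
    )
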