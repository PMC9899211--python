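"""Average-method probability maps, border-zone ratios, and certainty index.

The average method estimates the likelihood of a voxel belonging to a
territory as the lesion frequency across that territory's subjects:
p_s(j) = (# subjects lesioned at j) / N_s.  Border zones between two
territories are characterized by the ratio p_a/p_b on the region where both
are positive.  The certainty index normalizes the per-territory maps so they
sum to one at each voxel with any signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    TERRITORIES,
    BinaryVolume,
    LabelVolume,
    LesionCohort,
    VolumeGrid,
    _check_same_grid,
)


@dataclass
class ProbMapSet:
    """One probability volume per territory, plus per-territory sample sizes."""

    grid: VolumeGrid
    maps: dict[str, np.ndarray]
    n_subjects: dict[str, int]
    method: str = "average"

    def __post_init__(self):
        for code, m in self.maps.items():
            m = np.asarray(m, dtype=float)
            if m.shape != self.grid.shape:
                raise ValueError(f"map {code} shape {m.shape} != grid {self.grid.shape}")
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"map {code} has values outside [0, 1]")
            self.maps[code] = m
        if self.method not in ("average", "bmm"):
            raise ValueError(f"method must be 'average' or 'bmm', got {self.method!r}")

    @property
    def territories(self) -> list[str]:
        return [t for t in TERRITORIES if t in self.maps]

    def support_mask(self) -> np.ndarray:
        """Voxels where at least one territory has positive probability."""
        total = sum(self.maps.values())
        return total > 0


def average_prob_map(cohort: LesionCohort, territory: str) -> np.ndarray:
    """Lesion-frequency map for one territory: voxelwise mean of its binary masks.

    Masks must already be left-lateralized (see LesionCohort.flipped_to_left).
    """
    if cohort.n_subjects(territory) == 0:
        raise ValueError(f"no subjects in territory {territory}: cannot average")
    stack = cohort.territory_masks(territory)
    return stack.mean(axis=0)


def average_prob_maps(cohort: LesionCohort) -> ProbMapSet:
    present = [t for t in TERRITORIES if cohort.n_subjects(t) > 0]
    return ProbMapSet(
        grid=cohort.grid,
        maps={t: average_prob_map(cohort, t) for t in present},
        n_subjects={t: cohort.n_subjects(t) for t in present},
        method="average",
    )


@dataclass
class RatioMap:
    """p_a / p_b on the two-territory overlap; undefined elsewhere (NaN + mask)."""

    grid: VolumeGrid
    numerator_territory: str
    denominator_territory: str
    values: np.ndarray
    support_mask: BinaryVolume


def border_ratio(maps: ProbMapSet, a: str, b: str) -> RatioMap:
    """Border-zone ratio map p_a/p_b where both probabilities are positive.

    Values > 1 mean the voxel is more often lesioned in a-territory strokes
    than in b-territory strokes; the ratio is undefined (stored as NaN)
    outside the shared support.
    """
    for code in (a, b):
        if code not in maps.maps:
            raise ValueError(f"territory {code} not present in the map set")
    pa, pb = maps.maps[a], maps.maps[b]
    support = (pa > 0) & (pb > 0)
    values = np.full(maps.grid.shape, np.nan)
    values[support] = pa[support] / pb[support]
    return RatioMap(
        grid=maps.grid,
        numerator_territory=a,
        denominator_territory=b,
        values=values,
        support_mask=BinaryVolume(maps.grid, support.astype(np.uint8)),
    )


@dataclass
class CIMaps:
    """Per-territory certainty-index volumes; rows sum to 1 on the support."""

    grid: VolumeGrid
    maps: dict[str, np.ndarray]
    support_mask: BinaryVolume


def certainty_index(maps: ProbMapSet) -> CIMaps:
    """CI_s(j) = P_s(j) / sum_s P_s(j) on the support; 0 outside it."""
    total = sum(maps.maps[t] for t in maps.territories)
    support = total > 0
    ci = {}
    for t in maps.territories:
        out = np.zeros(maps.grid.shape)
        out[support] = maps.maps[t][support] / total[support]
        ci[t] = out
    return CIMaps(maps.grid, ci, BinaryVolume(maps.grid, support.astype(np.uint8)))


def mean_ci_by_roi(ci: CIMaps, parcellation: LabelVolume) -> pd.DataFrame:
    """Mean certainty index (in percent) per ROI x territory.

    The mean is taken over ROI ∩ support; ROIs with no support voxels are
    reported with missing values rather than zeros.
    """
    _check_same_grid(ci.grid, parcellation.grid, "CI maps and parcellation")
    support = ci.support_mask.data > 0
    rows = []
    for roi_id in sorted(set(np.unique(parcellation.data)) - {0}):
        roi = parcellation.data == roi_id
        sel = roi & support
        acr = parcellation.scheme.acronym_of(int(roi_id))
        for t, vol in ci.maps.items():
            mean_pct = float(vol[sel].mean() * 100.0) if sel.any() else np.nan
            rows.append({"roi_id": int(roi_id), "roi": acr, "territory": t,
                         "mean_ci_pct": mean_pct})
    return pd.DataFrame(rows)
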