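"""From probability maps to sharp hierarchical territory atlases.

A voxel is "claimed" by a territory when at least one of its mixture
clusters has rate mu with mu + alpha*sqrt(mu(1-mu)) >= 1, i.e. the voxel is
within alpha Bernoulli standard deviations of certainly-lesioned.  For
mu in (0,1) and alpha > 0 this is equivalent to mu >= 1/(1+alpha^2) — at the
default alpha = 3 the claiming threshold is exactly 0.1.

Voxels claimed by several territories go to the one with the largest mu_max;
unclaimed brain voxels are water-spread to the nearest labelled territory
(Euclidean distance in mm).  Exact ties are broken by a fixed territory
priority (MCA > PCA > VB > ACA, descending cohort frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import (
    LABEL_TERRITORIES,
    TERRITORY_LABELS,
    TERRITORY_PRIORITY,
    BinaryVolume,
    LabelScheme,
    LabelVolume,
    VolumeGrid,
    _check_same_grid,
    territory_scheme,
)
from .average_maps import ProbMapSet
from .bmm import BMMFit, mu_max_map

#: extra claim-map codes beyond the four territory labels (1..4)
OVERLAP = 5
UNDEFINED = 6


@dataclass
class ClaimMap:
    """Integer claim volume: territory codes 1..4, OVERLAP=5, UNDEFINED=6, 0 background."""

    grid: VolumeGrid
    data: np.ndarray
    alpha: float

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError("claim data shape does not match grid")
        allowed = set(TERRITORY_LABELS.values()) | {0, OVERLAP, UNDEFINED}
        bad = set(np.unique(data)) - allowed
        if bad:
            raise ValueError(f"claim map contains invalid codes {sorted(bad)}")
        self.data = data.astype(np.int32)


def claim_threshold(alpha: float) -> float:
    """Closed form of the claiming rule: mu + alpha*sqrt(mu(1-mu)) >= 1 iff
    mu >= 1/(1+alpha^2) (for mu in (0,1], alpha > 0)."""
    return 1.0 / (1.0 + alpha**2)


def is_claimed(mu: np.ndarray, alpha: float) -> np.ndarray:
    """Apply the claiming rule voxelwise to a rate volume."""
    mu = np.asarray(mu, dtype=float)
    return mu + alpha * np.sqrt(mu * (1.0 - mu)) >= 1.0


def claim_voxels(
    fits: dict[str, BMMFit], brain_mask: BinaryVolume, alpha: float = 3.0
) -> ClaimMap:
    """Claim each brain voxel for every territory with a cluster rate passing
    the alpha-confidence rule; code OVERLAP where several claim, UNDEFINED
    where none does."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    grids = {f.grid for f in fits.values()}
    if len(grids) != 1 or next(iter(grids)) != brain_mask.grid:
        raise ValueError("all fits and the brain mask must share one grid")
    grid = brain_mask.grid
    brain = brain_mask.data > 0

    claimed_by = {}
    for t, fit in fits.items():
        # claimed if ANY cluster passes; evaluated on unclipped rates so a
        # pre-clip rate of exactly 1 is always claimed
        mu = np.stack(fit.mu_volumes(unclipped=True))
        claimed_by[t] = is_claimed(mu, alpha).any(axis=0) & brain

    n_claims = sum(c.astype(int) for c in claimed_by.values())
    out = np.zeros(grid.shape, dtype=np.int32)
    out[brain] = UNDEFINED
    for t, c in claimed_by.items():
        out[c & (n_claims == 1)] = TERRITORY_LABELS[t]
    out[n_claims > 1] = OVERLAP
    return ClaimMap(grid, out, alpha)


def resolve_overlaps(claim: ClaimMap, fits: dict[str, BMMFit]) -> ClaimMap:
    """Reassign every OVERLAP voxel to the territory with the largest mu_max
    there; exact ties go to the fixed priority order."""
    out = claim.data.copy()
    overlap = out == OVERLAP
    if not overlap.any():
        return ClaimMap(claim.grid, out, claim.alpha)
    # priority-ordered stack; np.argmax keeps the first maximum, so earlier
    # (higher-priority) territories win exact ties
    codes = [t for t in TERRITORY_PRIORITY if t in fits]
    stack = np.stack([mu_max_map(fits[t]) for t in codes])
    winner_idx = np.argmax(stack, axis=0)
    winner_label = np.zeros(claim.grid.shape, dtype=np.int32)
    for i, t in enumerate(codes):
        winner_label[winner_idx == i] = TERRITORY_LABELS[t]
    out[overlap] = winner_label[overlap]
    return ClaimMap(claim.grid, out, claim.alpha)


def _priority_rank_for_label(label: int) -> int:
    return TERRITORY_PRIORITY.index(LABEL_TERRITORIES[label]) if label in LABEL_TERRITORIES else label


def water_spread(
    labels: ClaimMap | LabelVolume, brain_mask: BinaryVolume,
    scheme: LabelScheme | None = None,
) -> LabelVolume:
    """Propagate labels to every unlabelled brain voxel from its nearest
    labelled voxel (Euclidean distance scaled by voxel size in mm).

    UNDEFINED/zero brain voxels receive the nearest label; exact distance
    ties are broken by territory priority (then by ascending label id for
    non-territory schemes).  The result labels every brain voxel.
    """
    grid = labels.grid
    _check_same_grid(grid, brain_mask.grid, "labels and brain mask")
    data = labels.data.copy()
    brain = brain_mask.data > 0
    data[~brain] = 0
    if isinstance(labels, ClaimMap):
        data[data == UNDEFINED] = 0
        if (data == OVERLAP).any():
            raise ValueError("resolve overlaps before water-spreading")
    present = sorted(set(np.unique(data)) - {0})
    if not present:
        raise ValueError("water_spread needs at least one labelled voxel")

    unlabeled = brain & (data == 0)
    if unlabeled.any():
        # per-label distance transform keeps exact ties visible so the
        # priority rule can break them deterministically
        order = sorted(present, key=_priority_rank_for_label)
        dists = np.stack([
            ndimage.distance_transform_edt(data != lab, sampling=grid.voxel_size)
            for lab in order
        ])
        nearest = np.argmin(dists, axis=0)  # first minimum = highest priority
        fill = np.array(order, dtype=np.int32)[nearest]
        data[unlabeled] = fill[unlabeled]

    if scheme is None:
        scheme = labels.scheme if isinstance(labels, LabelVolume) else territory_scheme()
    return LabelVolume(grid, data, scheme)


def sharp_atlas_from_prob(maps: ProbMapSet, brain_mask: BinaryVolume) -> LabelVolume:
    """Sharp territory atlas from average-method maps: per-voxel argmax of
    p_s among positive maps (priority ties), then water-spread the voxels
    where every map is zero.  Partitions the brain mask."""
    _check_same_grid(maps.grid, brain_mask.grid, "maps and brain mask")
    brain = brain_mask.data > 0
    codes = [t for t in TERRITORY_PRIORITY if t in maps.maps]
    stack = np.stack([maps.maps[t] for t in codes])
    any_positive = (stack > 0).any(axis=0)
    winner_idx = np.argmax(stack, axis=0)
    data = np.zeros(maps.grid.shape, dtype=np.int32)
    for i, t in enumerate(codes):
        data[(winner_idx == i) & any_positive & brain] = TERRITORY_LABELS[t]
    interim = LabelVolume(maps.grid, data, territory_scheme())
    return water_spread(interim, brain_mask)


def smooth_labels(labels: LabelVolume, radius: int = 1) -> LabelVolume:
    """Majority (modal) filter within a spherical neighborhood, applied once.

    Only labelled voxels vote, so background never invades the brain; the
    label set can shrink (islands absorbed) but never grow.  Ties go to the
    territory priority order where labels are territories, else to the
    smaller label id.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return labels
    r = int(radius)
    zz = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = (zz**2).sum(axis=0) <= r**2
    data = labels.data
    present = sorted(set(np.unique(data)) - {0})
    counts = np.stack([
        ndimage.convolve((data == lab).astype(np.int32), ball.astype(np.int32),
                         mode="constant", cval=0)
        for lab in present
    ])
    order = np.argsort([_priority_rank_for_label(lab) for lab in present], kind="stable")
    counts_ord = counts[order]
    labs_ord = np.array(present, dtype=np.int32)[order]
    winner = labs_ord[np.argmax(counts_ord, axis=0)]
    out = data.copy()
    labelled = data > 0
    out[labelled] = winner[labelled]
    return LabelVolume(labels.grid, out, labels.scheme)


def merge_to_level2(labels: LabelVolume) -> LabelVolume:
    """Collapse level-1 parcels to their level-2 (major-territory) ids."""
    lut = {i: l2 for i, _, _, l2 in labels.scheme.entries}
    present = set(np.unique(labels.data)) - {0}
    missing = [i for i in present if i not in lut]
    if missing:
        raise ValueError(f"labels {sorted(missing)} have no level-2 mapping")
    out = labels.data.copy()
    for i in present:
        out[labels.data == i] = lut[i]
    return LabelVolume(labels.grid, out, territory_scheme())


def subdivide_by_anatomy(
    labels: LabelVolume,
    anatomical: LabelVolume,
    mapping: dict[tuple[int, int], int],
    scheme: LabelScheme,
) -> LabelVolume:
    """Intersect a territory atlas with an anatomical parcellation.

    Each voxel's output label is mapping[(territory_label, anatomical_label)];
    intersections absent from the mapping keep the territory label (the
    scheme must then contain the pass-through ids too).  Labelled voxel
    coverage is preserved exactly.
    """
    _check_same_grid(labels.grid, anatomical.grid, "territory and anatomical volumes")
    out = labels.data.copy()
    for (terr, anat), sub in mapping.items():
        out[(labels.data == terr) & (anatomical.data == anat)] = sub
    return LabelVolume(labels.grid, out, scheme)


def build_sharp_atlas(
    claim: ClaimMap, fits: dict[str, BMMFit], brain_mask: BinaryVolume,
    smoothing_radius: int = 1,
) -> LabelVolume:
    """Claim map -> sharp label atlas: resolve overlaps, water-spread, smooth."""
    resolved = resolve_overlaps(claim, fits)
    spread = water_spread(resolved, brain_mask)
    return smooth_labels(spread, smoothing_radius)
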