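"""Synthetic phantom templates and lesion cohorts with planted mixture structure.

The phantom emulates the statistical structure the atlas pipeline assumes:
an ellipsoidal brain, contiguous angular-sector territories, and per-territory
Bernoulli mixtures — each cluster k has a prior pi*_k and a voxelwise rate map
mu*_k with a distinct geometric footprint (one compact deep cluster, broader
peripheral ones).  Every downstream stage therefore has recoverable ground
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import (
    TERRITORIES,
    TERRITORY_LABELS,
    BinaryVolume,
    LabelVolume,
    LesionCohort,
    VolumeGrid,
    flip_to_left,
    territory_scheme,
)

#: Canonical planted prior vectors per cluster count.  Fixed study conditions:
#: every cluster holds well over 10% of its group, so the model-selection rule
#: has an unambiguous ground truth.
CANONICAL_PRIORS = {
    1: (1.0,),
    2: (0.7, 0.3),
    3: (0.5, 0.3, 0.2),
    4: (0.4, 0.25, 0.2, 0.15),
}

RATE_LO, RATE_HI = 0.05, 0.95

#: peak voxelwise lesion rate at a cluster footprint's centre.  Moderate by
#: design: empirical lesion-frequency maps are far from deterministic (the
#: average-method maps peak well below 1), and near-deterministic rates would
#: make every mask a near-copy of its cluster footprint.
RATE_PEAK = 0.55


@dataclass
class TerritoryTemplate:
    """Ground-truth phantom: brain/ventricle masks, territory partition, mixture params."""

    grid: VolumeGrid
    brain_mask: BinaryVolume
    ventricle_mask: BinaryVolume
    true_labels: LabelVolume
    #: territory code -> (K*, pi* vector, list of K* rate volumes)
    true_params: dict[str, tuple[int, np.ndarray, list[np.ndarray]]]

    @property
    def territories(self) -> list[str]:
        return list(self.true_params)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


def make_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    n_territories: int = 4,
    clusters_per_territory: list[int] | tuple[int, ...] = (1, 2, 2, 3),
    seed: int = 0,
    priors: dict[str, tuple[float, ...]] | None = None,
) -> TerritoryTemplate:
    """Build a deterministic phantom template.

    Territories are contiguous angular sectors of an ellipsoidal brain in the
    x-y plane; each territory's K* clusters get ellipsoidal footprints at
    distinct depths along the sector axis (the outermost angled toward a
    sector boundary so adjacent territories share a border zone), with rates
    in [0.05, 0.95] inside the footprint and 0 outside.  Fully determined by
    `seed`.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError(f"phantom needs at least 16 voxels per axis, got {shape}")
    if not 2 <= n_territories <= 4:
        raise ValueError("n_territories must be in 2..4")
    clusters_per_territory = tuple(int(k) for k in clusters_per_territory)
    if len(clusters_per_territory) != n_territories:
        raise ValueError("clusters_per_territory must list one K per territory")
    if any(k < 1 or k > 4 for k in clusters_per_territory):
        raise ValueError("cluster counts must be in 1..4")

    rng = np.random.default_rng(seed)
    grid = VolumeGrid(shape)
    center = np.array([(s - 1) / 2 for s in shape])
    radii = np.array([0.42 * s for s in shape])
    brain = _ellipsoid(shape, center, radii)
    if brain.sum() < 100:
        raise ValueError("phantom geometry infeasible: brain mask too small")

    # interior ventricles: small off-center ellipsoid, strictly inside the brain
    vent = _ellipsoid(shape, center + np.array([0, 0, 0.05 * shape[2]]),
                      0.22 * radii)
    vent &= brain

    # contiguous angular sectors around the z-axis; boundary angles offset so
    # the partition is not symmetric under the x-flip
    ix, iy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    theta = np.arctan2(iy - center[1], ix - center[0])  # (-pi, pi]
    offset = 0.37  # radians; fixed asymmetry
    edges = offset + np.linspace(-np.pi, np.pi, n_territories + 1)
    sector2d = np.digitize(np.mod(theta - offset + np.pi, 2 * np.pi) - np.pi,
                           np.linspace(-np.pi, np.pi, n_territories + 1)[1:-1])
    labels = np.zeros(shape, dtype=np.int32)
    labels[brain] = (sector2d[..., None] * np.ones(shape, dtype=int))[brain] + 1

    codes = list(TERRITORIES[:n_territories])
    true_params: dict[str, tuple[int, np.ndarray, list[np.ndarray]]] = {}
    for t_idx, (code, k_star) in enumerate(zip(codes, clusters_per_territory)):
        if priors and code in priors:
            pi_star = np.asarray(priors[code], dtype=float)
        else:
            pi_star = np.asarray(CANONICAL_PRIORS[k_star], dtype=float)
        if len(pi_star) != k_star or not np.isclose(pi_star.sum(), 1.0, atol=1e-12):
            raise ValueError(f"priors for {code} must have length {k_star} and sum to 1")
        pi_star = pi_star / pi_star.sum()

        territory_vox = labels == t_idx + 1
        half_width = (edges[t_idx + 1] - edges[t_idx]) / 2
        mid = edges[t_idx] + half_width
        mus: list[np.ndarray] = []
        for k in range(k_star):
            # footprints at increasing depth->periphery with growing size; the
            # outermost cluster is angled toward a sector boundary so that
            # neighboring territories' lesions overlap there (the border zone)
            ang = mid
            if k_star > 1 and k == k_star - 1:
                ang = mid + (0.95 if t_idx % 2 else -0.95) * half_width
            direction = np.array([np.cos(ang), np.sin(ang), 0.0])
            frac = 0.3 + 0.4 * (k / max(k_star - 1, 1))
            c_k = center + direction * frac * radii.min()
            c_k[2] += rng.uniform(-0.05, 0.05) * shape[2]
            size = (0.11 + 0.045 * k) * radii.min()
            # footprints are clipped to the brain, not to the sector: lesions
            # spill across territory boundaries, which is what creates the
            # border-zone overlap between neighboring probability maps
            foot = _ellipsoid(shape, c_k, (size, size, 1.4 * size))
            foot &= brain
            if not foot.any():  # fall back to the sector core
                foot = territory_vox & _ellipsoid(shape, center, 0.8 * radii)
            # radial rate profile, highest at the footprint centre
            grids = np.ogrid[tuple(slice(0, s) for s in shape)]
            d2 = sum(((g - c) / (size if ax < 2 else 1.4 * size)) ** 2
                     for ax, (g, c) in enumerate(zip(grids, c_k)))
            mu = np.where(foot, np.clip(RATE_PEAK * (1.0 - 0.5 * np.sqrt(d2)), RATE_LO, RATE_PEAK), 0.0)
            mus.append(mu)
        true_params[code] = (k_star, pi_star, mus)

    return TerritoryTemplate(
        grid=grid,
        brain_mask=BinaryVolume(grid, brain.astype(np.uint8)),
        ventricle_mask=BinaryVolume(grid, vent.astype(np.uint8)),
        true_labels=LabelVolume(grid, labels, territory_scheme()),
        true_params=true_params,
    )


def sample_cohort(
    template: TerritoryTemplate,
    n_per_territory: dict[str, int] | int,
    right_fraction: float = 0.0,
    seed: int = 0,
) -> LesionCohort:
    """Draw a lesion cohort from the template's planted Bernoulli mixtures.

    For each subject: cluster k ~ Categorical(pi*), voxels ~ Bernoulli(mu*_k);
    with probability `right_fraction` the mask is mirrored along x and flagged
    as right-hemisphere.  Pure function of (template, counts, seed).  The
    planted cluster of each subject is kept on the returned cohort as
    ``cohort.true_clusters`` for recovery checks.
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_territory, int):
        n_per_territory = {c: n_per_territory for c in template.territories}
    masks, group, hemi, true_k = [], [], [], []
    for code in template.territories:
        n = int(n_per_territory.get(code, 0))
        if n < 1:
            raise ValueError(f"need at least one subject per territory, got {n} for {code}")
        k_star, pi_star, mus = template.true_params[code]
        ks = rng.choice(k_star, size=n, p=pi_star)
        for k in ks:
            draw = (rng.random(template.grid.shape) < mus[k]).astype(np.uint8)
            m = BinaryVolume(template.grid, draw)
            if rng.random() < right_fraction:
                m = flip_to_left(m, "right")  # mirror: phantom truth is left-lateralized
                hemi.append("right")
            else:
                hemi.append("left")
            masks.append(m)
            group.append(code)
            true_k.append(int(k))
    cohort = LesionCohort(masks, group, hemi)
    cohort.true_clusters = true_k  # type: ignore[attr-defined]
    return cohort


#: phantom B0 intensity levels (arbitrary units): background, tissue, CSF
B0_BACKGROUND, B0_TISSUE, B0_VENTRICLE = 0.0, 100.0, 200.0


def make_phantom_b0(
    template: TerritoryTemplate,
    misalignment: tuple[int, int, int] = (0, 0, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-intensity pseudo-B0 volume, integer-shifted, with optional noise.

    Background 0, brain tissue mid level, ventricles high level; translated by
    `misalignment` (voxels, zero-filled at the edges) so mis-deformed voxel
    counts are exactly enumerable.  Noise is applied inside the object only:
    the background of a deformed magnitude image stays exactly zero, which is
    what the intensity-greater-than-zero misregistration criterion assumes.
    """
    shift = tuple(int(s) for s in misalignment)
    if any(abs(s) > 5 for s in shift):
        raise ValueError(f"misalignment must be within 5 voxels per axis, got {shift}")
    vol = np.full(template.grid.shape, B0_BACKGROUND, dtype=float)
    vol[template.brain_mask.data > 0] = B0_TISSUE
    vol[template.ventricle_mask.data > 0] = B0_VENTRICLE
    if any(shift):
        vol = ndimage.shift(vol, shift, order=0, mode="constant", cval=0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inside = vol > 0
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape) * inside
        vol[inside] = np.maximum(vol[inside], 1e-3)  # object stays supra-zero
    return vol
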