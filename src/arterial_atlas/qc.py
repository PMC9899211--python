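"""Registration quality control via strip regions and misalignment ratios.

Three strip regions of a stated bandwidth are built from the template brain
and lateral-ventricle masks: the outside strip of the brain mask (OSBM), the
inside strip of the brain mask (ISBM), and the outside strip of the lateral
ventricles (OSLV).  For a deformed B0 volume, the mis-deformation ratios are

    gamma_OSBM = fraction of OSBM voxels with intensity > 0
                 (tissue spilling outside the template brain),
    gamma_ISBM = fraction of ISBM voxels with intensity == 0
                 (background intruding inside the template brain),
    gamma_OSLV = fraction of OSLV voxels with intensity > lambda
                 (bright CSF-like signal outside the template ventricles),

with lambda derived from the deformed-B0 intensities inside the template
ventricle mask; the default rule is lambda = mean - 0.5 * sd, a lower
CSF-intensity cutoff.  The rule is a pluggable callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .core_io import BinaryVolume, VolumeGrid, _check_same_grid


@dataclass
class QCRegions:
    """OSBM / ISBM / OSLV strip masks of a fixed bandwidth (voxels)."""

    osbm: BinaryVolume
    isbm: BinaryVolume
    oslv: BinaryVolume
    bandwidth: float


def _outside_strip(mask: np.ndarray, bandwidth: float, sampling) -> np.ndarray:
    """Voxels outside `mask` within `bandwidth` (mm-scaled) of its surface."""
    if bandwidth <= 0:
        return np.zeros_like(mask, dtype=bool)
    dist_to_mask = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return (~mask) & (dist_to_mask <= bandwidth)


def _inside_strip(mask: np.ndarray, bandwidth: float, sampling) -> np.ndarray:
    """Voxels inside `mask` within `bandwidth` of its surface (distance to
    the nearest outside voxel)."""
    if bandwidth <= 0:
        return np.zeros_like(mask, dtype=bool)
    dist_to_outside = ndimage.distance_transform_edt(mask, sampling=sampling)
    return mask & (dist_to_outside <= bandwidth)


def make_strips(
    brain_mask: BinaryVolume, ventricle_mask: BinaryVolume, bandwidth: float = 5.0
) -> QCRegions:
    """Build the three QC strips.  Bandwidth is in voxel units on isotropic
    grids (distances are mm-scaled, so anisotropic voxels are honored)."""
    _check_same_grid(brain_mask.grid, ventricle_mask.grid, "brain and ventricle masks")
    if brain_mask.n_voxels == 0 or ventricle_mask.n_voxels == 0:
        raise ValueError("brain and ventricle masks must be non-empty")
    grid = brain_mask.grid
    sampling = grid.voxel_size
    scale = min(sampling)  # bandwidth stated in voxels
    brain = brain_mask.data > 0
    vent = ventricle_mask.data > 0
    osbm = _outside_strip(brain, bandwidth * scale, sampling)
    isbm = _inside_strip(brain, bandwidth * scale, sampling)
    oslv = _outside_strip(vent, bandwidth * scale, sampling)
    as_bin = lambda m: BinaryVolume(grid, m.astype(np.uint8))
    return QCRegions(as_bin(osbm), as_bin(isbm), as_bin(oslv), bandwidth)


@dataclass
class QCResult:
    gamma_osbm: float | None
    gamma_isbm: float | None
    gamma_oslv: float | None
    lam: float

    def as_dict(self) -> dict:
        return {
            "gamma_osbm": self.gamma_osbm,
            "gamma_isbm": self.gamma_isbm,
            "gamma_oslv": self.gamma_oslv,
            "lambda": self.lam,
        }


def lambda_mean_minus_half_sd(intensities: np.ndarray) -> float:
    """Default CSF cutoff: mean - 0.5 * sd of ventricle intensities."""
    return float(np.mean(intensities) - 0.5 * np.std(intensities))


def qc_ratios(
    deformed_b0: np.ndarray,
    regions: QCRegions,
    ventricle_mask: BinaryVolume,
    lambda_rule: Callable[[np.ndarray], float] = lambda_mean_minus_half_sd,
) -> QCResult:
    """Misalignment ratios of a deformed B0 against the template strips.

    An empty strip yields a missing (None) ratio rather than 0.
    """
    vol = np.asarray(deformed_b0, dtype=float)
    if vol.shape != regions.osbm.grid.shape:
        raise ValueError("deformed volume is not on the template grid")
    _check_same_grid(regions.osbm.grid, ventricle_mask.grid, "strips and ventricle mask")

    lam = lambda_rule(vol[ventricle_mask.data > 0])

    def frac(strip: BinaryVolume, condition: np.ndarray) -> float | None:
        sel = strip.data > 0
        n = int(sel.sum())
        return float(condition[sel].sum() / n) if n else None

    return QCResult(
        gamma_osbm=frac(regions.osbm, vol > 0),
        gamma_isbm=frac(regions.isbm, vol == 0),
        gamma_oslv=frac(regions.oslv, vol > lam),
        lam=lam,
    )
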