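"""Domain types and NIfTI I/O for lesion-cohort atlas construction.

All volumes live on a shared :class:`VolumeGrid`.  Binary lesion masks are
validated strictly ({0,1} only); label volumes carry a :class:`LabelScheme`
mirroring the published lookup-table layout (id, acronym, description,
level-2 id).  4D probabilistic maps are written with the territory axis in
the fixed order ACA, MCA, PCA, VB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Canonical territory codes, in the order used for every 4D output.
TERRITORIES = ("ACA", "MCA", "PCA", "VB")

#: Tie-breaking priority (descending cohort frequency: MCA > PCA > VB > ACA).
TERRITORY_PRIORITY = ("MCA", "PCA", "VB", "ACA")


def territory_priority_rank(code: str) -> int:
    """Smaller rank wins ties."""
    return TERRITORY_PRIORITY.index(code)


@dataclass(frozen=True)
class VolumeGrid:
    """A template voxel grid: shape, voxel size in mm, voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)
        if self.affine is None:
            aff = np.diag((*vs, 1.0))
        else:
            aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash(self.shape)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0


def _check_same_grid(a_grid: VolumeGrid, b_grid: VolumeGrid, what: str = "volumes"):
    if a_grid != b_grid:
        raise ValueError(f"{what} are on different grids: {a_grid.shape} vs {b_grid.shape}")


@dataclass
class BinaryVolume:
    """A {0,1} volume (lesion mask, brain mask, ...) on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        bad = np.setdiff1d(np.unique(data), [0, 1])
        if bad.size:
            raise ValueError(
                f"binary volume contains non-binary values: {bad[:10].tolist()}"
            )
        self.data = data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelScheme:
    """Lookup table for a hierarchical label volume.

    Each entry is (label_id, acronym, description, level2_id); level-1 ids are
    unique and each maps to exactly one level-2 id.
    """

    entries: list[tuple[int, str, str, int]]

    def __post_init__(self):
        ids = [int(e[0]) for e in self.entries]
        if any(i <= 0 for i in ids):
            raise ValueError("label ids must be positive integers")
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        self.entries = [(int(i), str(a), str(d), int(l2)) for i, a, d, l2 in self.entries]

    @property
    def ids(self) -> list[int]:
        return [e[0] for e in self.entries]

    def level2_of(self, label_id: int) -> int:
        for i, _, _, l2 in self.entries:
            if i == label_id:
                return l2
        raise KeyError(f"label id {label_id} not in scheme")

    def acronym_of(self, label_id: int) -> str:
        for i, a, _, _ in self.entries:
            if i == label_id:
                return a
        raise KeyError(f"label id {label_id} not in scheme")

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["id", "acronym", "description", "level2_id"]
        )

    def write(self, path: str | Path):
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "LabelScheme":
        t = pd.read_csv(path, sep="\t")
        return cls([tuple(r) for r in t[["id", "acronym", "description", "level2_id"]].itertuples(index=False)])


def territory_scheme() -> LabelScheme:
    """The four-territory (level-2 == level-1) scheme, ids 1..4."""
    return LabelScheme(
        [
            (1, "ACA", "Anterior cerebral artery territory", 1),
            (2, "MCA", "Middle cerebral artery territory", 2),
            (3, "PCA", "Posterior cerebral artery territory", 3),
            (4, "VB", "Vertebro-basilar territory", 4),
        ]
    )


#: territory code <-> integer label used in territory-level label volumes
TERRITORY_LABELS = {code: i + 1 for i, code in enumerate(TERRITORIES)}
LABEL_TERRITORIES = {v: k for k, v in TERRITORY_LABELS.items()}


@dataclass
class LabelVolume:
    """Integer-labelled volume with its lookup scheme; 0 is background."""

    grid: VolumeGrid
    data: np.ndarray
    scheme: LabelScheme

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label volume must contain integers")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("label values must be non-negative")
        present = set(np.unique(data)) - {0}
        unknown = present - set(self.scheme.ids)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from scheme")
        self.data = data.astype(np.int32)

    def counts(self) -> dict[int, int]:
        vals, cnts = np.unique(self.data[self.data > 0], return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))


@dataclass
class LesionCohort:
    """Co-registered binary lesion masks with territory labels and hemisphere flags."""

    masks: list[BinaryVolume]
    group: list[str]
    hemisphere: list[str]

    def __post_init__(self):
        if not (len(self.masks) == len(self.group) == len(self.hemisphere)):
            raise ValueError("masks, group and hemisphere must have equal length")
        for m in self.masks:
            _check_same_grid(m.grid, self.masks[0].grid, "cohort masks")
        bad = set(self.group) - set(TERRITORIES)
        if bad:
            raise ValueError(f"unknown territory codes: {sorted(bad)}")
        bad_h = set(self.hemisphere) - {"left", "right"}
        if bad_h:
            raise ValueError(f"hemisphere flags must be left/right, got {sorted(bad_h)}")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def grid(self) -> VolumeGrid:
        return self.masks[0].grid

    def n_subjects(self, territory: str) -> int:
        return sum(g == territory for g in self.group)

    def territory_masks(self, territory: str) -> np.ndarray:
        """Stacked (N, x, y, z) array of this territory's masks."""
        idx = [i for i, g in enumerate(self.group) if g == territory]
        if not idx:
            raise ValueError(f"no subjects in territory {territory}")
        return np.stack([self.masks[i].data for i in idx])

    def flipped_to_left(self) -> "LesionCohort":
        masks = [flip_to_left(m, h) for m, h in zip(self.masks, self.hemisphere)]
        return LesionCohort(masks, list(self.group), ["left"] * len(self))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_img(img) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(img.shape[:3], tuple(float(z) for z in zooms), np.asarray(img.affine))


def read_volume(path: str | Path, kind: str = "scalar", scheme: LabelScheme | None = None):
    """Read a NIfTI volume as a binary mask, label volume or raw scalar array.

    kind='binary' -> BinaryVolume (values validated to {0,1});
    kind='label'  -> LabelVolume (requires `scheme`);
    kind='scalar' -> (VolumeGrid, ndarray).
    """
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    data = np.asanyarray(img.dataobj)
    if kind == "binary":
        return BinaryVolume(grid, data)
    if kind == "label":
        if scheme is None:
            raise ValueError("reading a label volume requires a LabelScheme")
        return LabelVolume(grid, data, scheme)
    if kind == "scalar":
        return grid, np.asarray(data, dtype=float)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: BinaryVolume | LabelVolume, path: str | Path):
    data = vol.data
    img = nib.Nifti1Image(data.astype(np.int16), vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, str(path))


def write_scalar(grid: VolumeGrid, data: np.ndarray, path: str | Path):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size[: data.ndim])
    nib.save(img, str(path))


def write_prob_maps_4d(maps, path: str | Path):
    """Write a ProbMapSet as one 4D NIfTI, 4th axis fixed to ACA, MCA, PCA, VB.

    Raises if any of the four territories is missing (never silently
    zero-fills an omitted territory).
    """
    missing = [t for t in TERRITORIES if t not in maps.maps]
    if missing:
        raise ValueError(f"cannot write 4D probability maps: missing {missing}")
    grid = maps.grid
    stack = np.stack([np.asarray(maps.maps[t], dtype=np.float32) for t in TERRITORIES], axis=-1)
    img = nib.Nifti1Image(stack, grid.affine)
    img.header.set_zooms((*grid.voxel_size, 1.0))
    nib.save(img, str(path))


def read_prob_maps_4d(path: str | Path):
    """Inverse of :func:`write_prob_maps_4d`; returns (grid, dict code->array)."""
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != len(TERRITORIES):
        raise ValueError(f"expected a 4D file with {len(TERRITORIES)} maps, got shape {data.shape}")
    return grid, {t: data[..., i] for i, t in enumerate(TERRITORIES)}


# ---------------------------------------------------------------------------
# Mask utilities


def flip_to_left(mask: BinaryVolume, hemisphere: str) -> BinaryVolume:
    """Mirror right-hemisphere masks along the x-axis (index i -> dim_x-1-i).

    Left-hemisphere masks are returned unchanged.  The grid x-axis is taken to
    be the left-right axis.  Lesion voxel count is preserved.
    """
    if hemisphere == "left":
        return mask
    if hemisphere != "right":
        raise ValueError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    return BinaryVolume(mask.grid, mask.data[::-1, :, :].copy())


def dice(a: BinaryVolume, b: BinaryVolume) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1.0)."""
    _check_same_grid(a.grid, b.grid, "dice inputs")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# Cohort directory layout: one mask per subject + participants table


def write_cohort(cohort: LesionCohort, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (m, g, h) in enumerate(zip(cohort.masks, cohort.group, cohort.hemisphere)):
        sid = f"sub-{i:04d}"
        write_volume(m, directory / f"{sid}_mask.nii")
        rows.append({"subject_id": sid, "group": g, "hemisphere": h})
    pd.DataFrame(rows).to_csv(directory / "participants.tsv", sep="\t", index=False)
    return directory


def read_cohort(directory: str | Path) -> LesionCohort:
    directory = Path(directory)
    table = pd.read_csv(directory / "participants.tsv", sep="\t")
    masks, group, hemi = [], [], []
    for row in table.itertuples(index=False):
        masks.append(read_volume(directory / f"{row.subject_id}_mask.nii", kind="binary"))
        group.append(row.group)
        hemi.append(row.hemisphere)
    return LesionCohort(masks, group, hemi)
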