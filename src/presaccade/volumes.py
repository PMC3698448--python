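"""Labeled head volumes.

A :class:`LabelVolume` is a 3-D integer grid in which each voxel carries a
tissue class (scalp, skull, CSF, gray, white, eye, air cavity) or an atlas
ROI label.  The affine maps voxel indices to head coordinates in mm, RAS
orientation, with the origin at the anterior commissure (AC).  The same
container is the substrate for conductivity assignment, source-space
construction and ROI morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError

#: Canonical tissue classes.  0 is reserved for background (non-head).
TISSUE_LABELS: dict[int, str] = {
    0: "background",
    1: "scalp",
    2: "skull",
    3: "csf",
    4: "gray",
    5: "white",
    6: "eye",
    7: "air",
}

TISSUE_IDS: dict[str, int] = {name: lab for lab, name in TISSUE_LABELS.items()}


@dataclass
class LabelVolume:
    """3-D integer label grid with voxel size and head-coordinate affine."""

    grid: np.ndarray
    voxel_size_mm: float
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"label grid must be 3-D, got {self.grid.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")
        if self.voxel_size_mm <= 0:
            raise FormatError("voxel size must be positive")

    # -- coordinate helpers -------------------------------------------------
    def voxel_to_head(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to head coordinates in mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz

    def head_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map head coordinates (…, 3) to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Head-coordinate centers of all voxels (or of a boolean mask)."""
        if mask is None:
            mask = np.ones(self.grid.shape, dtype=bool)
        ijk = np.argwhere(mask)
        return self.voxel_to_head(ijk)

    def mask(self, label: int | str) -> np.ndarray:
        """Boolean mask of voxels holding ``label`` (name or integer)."""
        if isinstance(label, str):
            names = {v: k for k, v in self.label_table.items()}
            if label not in names:
                raise KeyError(f"unknown label name {label!r}")
            label = names[label]
        return self.grid == label

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)


def write_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 plus a JSON label-table sidecar."""
    path = Path(path)
    grid = vol.grid
    if np.issubdtype(grid.dtype, np.integer):
        grid = grid.astype(np.int16)
    img = nib.Nifti1Image(grid, vol.affine)
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii / .nii.gz
    sidecar = Path(str(sidecar) + ".labels.json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in vol.label_table.items()}, indent=1)
    )
    return path


def read_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI volume (and its label sidecar, if present)."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D in {path}")
    if np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.int32)
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise FormatError(f"non-invertible affine in {path}")
    zooms = img.header.get_zooms()[:3]
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".labels.json")
    table: dict[int, str] = {}
    if sidecar.exists():
        table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(
        grid=data,
        voxel_size_mm=float(zooms[0]),
        affine=affine,
        label_table=table,
    )


def write_cdr_volume(
    values: np.ndarray,
    node_voxels: np.ndarray,
    template: LabelVolume,
    path: str | Path,
) -> Path:
    """Scatter per-node CDR values into the template grid and save as NIfTI.

    ``values`` is (n_nodes,) for a single slice or (n_nodes, n_times) for a
    series (written as a 4-D volume).
    """
    values = np.asarray(values, dtype=np.float32)
    single = values.ndim == 1
    if single:
        values = values[:, None]
    shape = template.grid.shape + (values.shape[1],)
    out = np.zeros(shape, dtype=np.float32)
    idx = tuple(np.asarray(node_voxels).T)
    out[idx[0], idx[1], idx[2], :] = values
    if single:
        out = out[..., 0]
    img = nib.Nifti1Image(out, template.affine)
    nib.save(img, Path(path))
    return Path(path)
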