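"""Region-of-interest construction and current-density aggregation.

ROIs are built from atlas label volumes by small declarative recipes executed
left to right:

* ``union`` — set union of one or more named atlas labels;
* ``mask_ac`` — keep voxels anterior (y >= 0) and/or superior (z >= 0) to
  the anterior commissure (the head-coordinate origin); ``posterior`` /
  ``inferior`` select the complements.  Inclusive of the AC plane itself;
* ``dilate`` — Euclidean dilation by a distance in mm (ball structuring
  element on voxel centers);
* ``intersect`` — intersection with the result of a nested sub-recipe.

This is exactly the vocabulary needed for composite regions such as an
intraparietal-sulcus ROI defined as the overlap of the 3-mm-dilated inferior
and superior parietal lobules.  Recipes are data (a YAML file ships with the
package), not code.

CDR aggregation sums member-node values per 4-ms slice and divides by ROI
volume (member-voxel count x voxel volume), giving an average current per
mm^3.  Lateralized ROIs can be re-keyed contralateral/central/ipsilateral
relative to the direction of the eye movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt

from .errors import EmptyROIError, PairingError, RecipeError
from .forward import SourceSpace
from .inverse import CDRSeries
from .volumes import LabelVolume


@dataclass
class ROIDefinition:
    name: str
    recipe: list[dict]
    laterality: str = "midline"  # "midline" | "left" | "right"


@dataclass
class ROISeries:
    name: str
    values: np.ndarray  # (n_times,) average current density per mm^3
    times: np.ndarray
    volume_mm3: float
    n_nodes: int


def load_roi_definitions(path: str | Path | None = None) -> list[ROIDefinition]:
    """Load ROI recipes from YAML (default: the shipped phantom recipes)."""
    if path is None:
        text = resources.files("presaccade.data").joinpath("roi_recipes.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = []
    for entry in doc["rois"]:
        out.append(
            ROIDefinition(
                name=entry["name"],
                recipe=entry["recipe"],
                laterality=entry.get("laterality", "midline"),
            )
        )
    return out


def _label_mask(atlas: LabelVolume, label) -> np.ndarray:
    try:
        return atlas.mask(label)
    except KeyError as exc:
        raise RecipeError(str(exc)) from exc


def _head_coords(atlas: LabelVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = atlas.grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    A = atlas.affine
    x = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + A[0, 3]
    y = A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + A[1, 3]
    z = A[2, 0] * ii + A[2, 1] * jj + A[2, 2] * kk + A[2, 3]
    return x, y, z


def dilate_mask(mask: np.ndarray, distance_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Euclidean dilation: add voxels whose center lies within ``distance_mm``."""
    if distance_mm < 0:
        raise RecipeError("dilation distance must be non-negative")
    if distance_mm == 0 or not mask.any():
        return mask.copy()
    dist = distance_transform_edt(~mask, sampling=voxel_size_mm)
    return dist <= distance_mm + 1e-9


def build_roi(atlas: LabelVolume, definition: ROIDefinition | list[dict]) -> np.ndarray:
    """Execute an ROI recipe and return the boolean voxel mask."""
    recipe = definition.recipe if isinstance(definition, ROIDefinition) else definition
    name = definition.name if isinstance(definition, ROIDefinition) else "<anonymous>"
    mask = np.zeros(atlas.grid.shape, dtype=bool)
    for step in recipe:
        op = step.get("op")
        if op == "union":
            for lab in step["labels"]:
                mask |= _label_mask(atlas, lab)
        elif op == "mask_ac":
            x, y, z = _head_coords(atlas)
            keep = np.ones_like(mask)
            for cond in step["keep"]:
                if cond == "anterior":
                    keep &= y >= 0
                elif cond == "posterior":
                    keep &= y <= 0
                elif cond == "superior":
                    keep &= z >= 0
                elif cond == "inferior":
                    keep &= z <= 0
                else:
                    raise RecipeError(f"unknown AC-mask condition {cond!r}")
            mask &= keep
        elif op == "dilate":
            mask = dilate_mask(mask, float(step["mm"]), atlas.voxel_size_mm)
        elif op == "intersect":
            mask &= build_roi(atlas, step["with"])
        else:
            raise RecipeError(f"unknown recipe operation {op!r}")
    if not mask.any():
        raise EmptyROIError(f"ROI {name!r}: recipe produced an empty voxel set")
    return mask


def roi_timecourse(
    cdr: CDRSeries,
    roi_mask: np.ndarray,
    source_space: SourceSpace,
    voxel_size_mm: float,
    name: str = "roi",
) -> ROISeries:
    """Average current density per mm^3 for one ROI, per 4-ms slice.

    Sums the CDR of source nodes whose parent voxels lie in the ROI mask and
    divides by the ROI volume (member-voxel count x voxel volume of the atlas
    grid the mask lives on).
    """
    vox = source_space.voxels
    member = roi_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not member.any():
        raise EmptyROIError(f"ROI {name!r} contains no source nodes")
    volume = float(roi_mask.sum()) * float(voxel_size_mm) ** 3
    values = cdr.values[member].sum(axis=0) / volume
    return ROISeries(
        name=name,
        values=values,
        times=cdr.times.copy(),
        volume_mm3=volume,
        n_nodes=int(member.sum()),
    )


def lateralize(
    roi_values_by_name: dict[str, object], trial_side: str
) -> dict[tuple[str, str], object]:
    """Re-key lateralized ROI values as contralateral / central / ipsilateral.

    Lateral ROI names carry ``_left`` / ``_right`` suffixes and must come in
    pairs; other names are midline and map to "central".  For right-directed
    movements the left ROI is contralateral; for left-directed movements the
    assignment reverses.  Applying the relabeling twice with opposite sides
    restores the original assignment.
    """
    if trial_side not in ("left", "right"):
        raise ValueError(f"trial_side must be 'left' or 'right', got {trial_side!r}")
    out: dict[tuple[str, str], object] = {}
    seen_lateral: set[str] = set()
    for name, value in roi_values_by_name.items():
        if name.endswith("_left") or name.endswith("_right"):
            base, _, side = name.rpartition("_")
            partner = f"{base}_{'right' if side == 'left' else 'left'}"
            if partner not in roi_values_by_name:
                raise PairingError(f"lateral ROI {name!r} has no partner {partner!r}")
            seen_lateral.add(base)
            contra = side != trial_side
            out[(base, "contralateral" if contra else "ipsilateral")] = value
        else:
            out[(name, "central")] = value
    return out
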