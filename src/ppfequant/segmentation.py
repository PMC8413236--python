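"""Lung segmentation, carina localisation, and upper-zone definition.

The upper zone — the region from the carina slice up to 5 mm below the lung
apex — substitutes for the upper lobe in the computerised PPFE score. The
apical 5 mm are excluded so that apical pleural capping or scarring is not
spuriously quantified as fibroelastosis. All mm→slice conversions take the
ceiling so the apical exclusion never under-excludes, and slice 0 is the
most cranial slice throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import CTVolume

DEFAULT_AIR_THRESHOLD_HU = -320.0
# a component this small cannot be a lung on any plausible grid
_MIN_LUNG_VOXELS = 500


class SegmentationError(RuntimeError):
    pass


@dataclass
class LungMask:
    """Label grid aligned to the source volume: 0 background, 1 right lung, 2 left lung."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def lung(self) -> np.ndarray:
        return self.labels > 0

    @property
    def right(self) -> np.ndarray:
        return self.labels == 1

    @property
    def left(self) -> np.ndarray:
        return self.labels == 2


@dataclass
class UpperZone:
    """Axial band from 5 mm below the lung apex down to the carina, within lung."""

    carina_slice: int
    apex_slice: int
    excluded_apex_slices: int
    mask: np.ndarray

    @property
    def first_slice(self) -> int:
        return self.apex_slice + self.excluded_apex_slices


def _body_and_internal_air(hu: np.ndarray, air_threshold_hu: float):
    """Split air below threshold into exterior (border-connected) and internal."""
    air = hu < air_threshold_hu
    # exterior air touches the in-plane borders of the grid
    lab, _ = ndimage.label(air)
    border_labels = np.unique(
        np.concatenate(
            [lab[:, 0, :].ravel(), lab[:, -1, :].ravel(),
             lab[:, :, 0].ravel(), lab[:, :, -1].ravel()]
        )
    )
    border_labels = border_labels[border_labels > 0]
    exterior = np.isin(lab, border_labels)
    internal_air = air & ~exterior
    return internal_air


def _airway_component(internal_air: np.ndarray) -> np.ndarray:
    """Air reachable from the most cranial slices = tracheal/bronchial lumen."""
    lab, n = ndimage.label(internal_air)
    if n == 0:
        return np.zeros_like(internal_air)
    top = np.unique(lab[0])
    top = top[top > 0]
    if top.size == 0:
        return np.zeros_like(internal_air)
    return np.isin(lab, top)


def segment_lungs(volume: CTVolume,
                  air_threshold_hu: float = DEFAULT_AIR_THRESHOLD_HU,
                  solidify: str = "hull") -> LungMask:
    """Threshold-based lung segmentation.

    Air voxels inside the body (not connected to the grid border) are
    labelled; the airway lumen (air reachable from the most cranial slices)
    is removed; the two largest remaining components become the lungs, holes
    are filled slice-wise, and right/left labels are assigned by in-plane
    centroid so they follow anatomy rather than construction order.

    ``solidify`` controls how dense subpleural tissue — which fails the air
    threshold but belongs to the lung — is restored to the mask:
    ``"hull"`` (default) takes the per-slice convex hull of each lung,
    exact for convex cross-sections and required for peripheral lesions to
    fall inside the pleural shell; ``"fill"`` only fills enclosed holes;
    ``"none"`` leaves the raw threshold components.
    """
    if solidify not in ("hull", "fill", "none"):
        raise ValueError("solidify must be 'hull', 'fill' or 'none'")
    internal_air = _body_and_internal_air(volume.hu_grid, air_threshold_hu)
    airway = _airway_component(internal_air)
    candidate = internal_air & ~airway
    lab, n = ndimage.label(candidate)
    if n < 2:
        raise SegmentationError("lungs not found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[1]] < _MIN_LUNG_VOXELS:
        raise SegmentationError("lungs not found")
    comp_a = lab == (order[0] + 1)
    comp_b = lab == (order[1] + 1)

    if solidify == "none":
        filled_a, filled_b = comp_a, comp_b
    elif solidify == "fill":
        filled_a = _fill_holes_slicewise(comp_a)
        filled_b = _fill_holes_slicewise(comp_b)
    else:
        filled_a = _convex_hull_slicewise(comp_a)
        filled_b = _convex_hull_slicewise(comp_b)

    # right lung = smaller column centroid (patient right is image left)
    cx_a = ndimage.center_of_mass(filled_a)[2]
    cx_b = ndimage.center_of_mass(filled_b)[2]
    labels = np.zeros(volume.shape, dtype=np.uint8)
    if cx_a <= cx_b:
        labels[filled_a] = 1
        labels[filled_b] = 2
    else:
        labels[filled_b] = 1
        labels[filled_a] = 2
    return LungMask(labels=labels, spacing=volume.spacing)


def _fill_holes_slicewise(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        if mask[z].any():
            out[z] = ndimage.binary_fill_holes(mask[z])
    return out


def _convex_hull_slicewise(mask: np.ndarray) -> np.ndarray:
    import warnings

    from skimage.morphology import convex_hull_image

    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        section = mask[z]
        if not section.any():
            continue
        if section.sum() < 3:  # qhull needs a non-degenerate simplex
            out[z] = section
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hull = convex_hull_image(section, offset_coordinates=True)
        out[z] = hull if hull.any() else section
    return out


def detect_carina(volume: CTVolume,
                  manual_override: int | None = None,
                  air_threshold_hu: float = DEFAULT_AIR_THRESHOLD_HU) -> int:
    """Locate the axial slice on which the trachea has bifurcated.

    A manual carina slice, when supplied (the normal route for clinical
    scans, where the carina is identified by eye), is returned verbatim.
    Otherwise the cranial airway component is tracked slice by slice
    caudally and the first slice on which its cross-section has split into
    two or more components is returned.
    """
    if manual_override is not None:
        return int(manual_override)
    internal_air = _body_and_internal_air(volume.hu_grid, air_threshold_hu)
    airway = _airway_component(internal_air)
    if not airway.any():
        raise SegmentationError("no airway found and no manual carina supplied")
    for z in range(airway.shape[0]):
        section = airway[z]
        if not section.any():
            continue
        n = measure.label(section, connectivity=1).max()
        if n >= 2:
            return z
    raise SegmentationError("airway never bifurcates; supply a manual carina slice")


def upper_zone(mask: LungMask, carina_slice: int,
               spacing: tuple[float, float, float] | None = None,
               apex_exclusion_mm: float = 5.0,
               include_carina_slice: bool = True) -> UpperZone:
    """Build the upper-zone mask: lung voxels on slices
    [apex + ceil(5 mm / axial spacing), carina], carina inclusive by default."""
    spacing = spacing if spacing is not None else mask.spacing
    lung_any = mask.lung.any(axis=(1, 2))
    if not lung_any.any():
        raise SegmentationError("empty lung mask")
    apex = int(np.argmax(lung_any))
    excl = int(np.ceil(apex_exclusion_mm / spacing[0]))
    first = apex + excl
    last = carina_slice if include_carina_slice else carina_slice - 1
    if last < first:
        raise SegmentationError(
            f"degenerate upper zone: carina slice {carina_slice} is cranial to "
            f"the apical exclusion band ending at slice {first}"
        )
    zone = np.zeros_like(mask.lung)
    zone[first: last + 1] = mask.lung[first: last + 1]
    return UpperZone(carina_slice=carina_slice, apex_slice=apex,
                     excluded_apex_slices=excl, mask=zone)
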