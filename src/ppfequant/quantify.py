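"""Computerised PPFE score (cPPFE).

cPPFE is the percentage of the upper-zone visceral pleural surface occupied
by dense, pleurally-based tissue. The pleural surface is operationalised as
the most peripheral 3-pixel band of the lung cross-section on each axial
slice; dense tissue is isolated by an HU threshold with small-component
noise suppression; the score pools counts over both lungs:

    cPPFE = 100 * (dense shell voxels) / (total shell voxels).

A radiologist-in-the-loop gate sets the score to 0% when the reading
radiologist saw no PPFE, and the gated score is dichotomised at a
configurable pleural-surface cutpoint (1, 2.5 or 5%; 2.5% is the working
threshold for survival analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .segmentation import LungMask, UpperZone
from .volume import CTVolume

_CROSS2D = ndimage.generate_binary_structure(2, 1)


@dataclass
class CPPFEParams:
    """Tunable parameters of the computerised score.

    shell_depth_pixels: peripheral band width in pixels (in-plane).
    dense_threshold_hu: attenuation at or above which shell tissue counts as
        dense; -200 HU separates fibroelastotic/soft tissue from aerated lung.
    min_component_shell_voxels: per-slice 8-connected components of dense
        shell smaller than this are discarded as noise.
    cutpoint_percent: dichotomisation threshold on the gated score (>= is
        positive).
    """

    shell_depth_pixels: int = 3
    dense_threshold_hu: float = -200.0
    min_component_shell_voxels: int = 5
    cutpoint_percent: float = 2.5
    erosion_3d: bool = False

    def __post_init__(self) -> None:
        if self.shell_depth_pixels < 1:
            raise ValueError("shell_depth_pixels must be >= 1")
        if self.cutpoint_percent <= 0:
            raise ValueError("cutpoint_percent must be positive")
        if self.min_component_shell_voxels < 0:
            raise ValueError("min_component_shell_voxels must be >= 0")


@dataclass
class CPPFEResult:
    shell_voxels_total: dict[str, int]  # keys: right, left, pooled
    shell_voxels_dense: dict[str, int]
    cppfe_percent: float
    gated_percent: float
    vppfe_present: bool | None
    dichotomised: bool
    params: CPPFEParams = field(default_factory=CPPFEParams)

    def to_dict(self) -> dict:
        return {
            "shell_voxels_total": self.shell_voxels_total,
            "shell_voxels_dense": self.shell_voxels_dense,
            "cppfe_percent": self.cppfe_percent,
            "gated_percent": self.gated_percent,
            "vppfe_present": self.vppfe_present,
            "dichotomised": self.dichotomised,
            "params": {
                "shell_depth_pixels": self.params.shell_depth_pixels,
                "dense_threshold_hu": self.params.dense_threshold_hu,
                "min_component_shell_voxels": self.params.min_component_shell_voxels,
                "cutpoint_percent": self.params.cutpoint_percent,
            },
        }


def extract_pleural_shell(mask: LungMask, zone: UpperZone, depth: int = 3,
                          erosion_3d: bool = False) -> np.ndarray:
    """Peripheral `depth`-pixel band of the lung, restricted to the zone.

    Per axial slice the band is the lung cross-section minus its 4-connected
    erosion iterated `depth` times; sections thinner than the band are kept
    whole. A 3D-erosion variant (6-connected) is available for comparison.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lung = mask.lung
    if erosion_3d:
        struct = ndimage.generate_binary_structure(3, 1)
        eroded = ndimage.binary_erosion(lung, struct, iterations=depth, border_value=0)
        shell = lung & ~eroded
    else:
        shell = np.zeros_like(lung)
        for z in range(lung.shape[0]):
            section = lung[z]
            if not section.any():
                continue
            eroded = ndimage.binary_erosion(section, _CROSS2D, iterations=depth,
                                            border_value=0)
            shell[z] = section & ~eroded
    return shell & zone.mask


def classify_dense_shell(volume: CTVolume, shell: np.ndarray,
                         params: CPPFEParams) -> np.ndarray:
    """Shell voxels at or above the dense threshold, per-slice 8-connected
    components below the minimum size removed."""
    if shell.shape != volume.shape:
        raise ValueError("shell mask not aligned to volume")
    dense = shell & (volume.hu_grid >= params.dense_threshold_hu)
    if params.min_component_shell_voxels > 1:
        for z in range(dense.shape[0]):
            if not dense[z].any():
                continue
            lab = measure.label(dense[z], connectivity=2)
            counts = np.bincount(lab.ravel())
            small = np.flatnonzero(counts < params.min_component_shell_voxels)
            dense[z][np.isin(lab, small[small > 0])] = False
    return dense


def compute_cppfe(volume: CTVolume, mask: LungMask, zone: UpperZone,
                  params: CPPFEParams | None = None) -> CPPFEResult:
    """Compose shell extraction and dense classification into the pooled score."""
    params = params if params is not None else CPPFEParams()
    shell = extract_pleural_shell(mask, zone, params.shell_depth_pixels,
                                  erosion_3d=params.erosion_3d)
    dense = classify_dense_shell(volume, shell, params)
    totals = {
        "right": int((shell & mask.right).sum()),
        "left": int((shell & mask.left).sum()),
    }
    denses = {
        "right": int((dense & mask.right).sum()),
        "left": int((dense & mask.left).sum()),
    }
    totals["pooled"] = totals["right"] + totals["left"]
    denses["pooled"] = denses["right"] + denses["left"]
    if totals["pooled"] == 0:
        raise ValueError("no pleural surface in zone")
    pct = 100.0 * denses["pooled"] / totals["pooled"]
    return CPPFEResult(
        shell_voxels_total=totals,
        shell_voxels_dense=denses,
        cppfe_percent=pct,
        gated_percent=pct,
        vppfe_present=None,
        dichotomised=dichotomise(pct, params.cutpoint_percent),
        params=params,
    )


def gate_by_radiologist(result: CPPFEResult, vppfe_present: bool) -> CPPFEResult:
    """Zero the score when the radiologist saw no PPFE; recompute the flag."""
    gated = result.cppfe_percent if vppfe_present else 0.0
    return replace(
        result,
        gated_percent=gated,
        vppfe_present=vppfe_present,
        dichotomised=dichotomise(gated, result.params.cutpoint_percent),
    )


def dichotomise(gated_percent: float, cutpoint: float) -> bool:
    """Positive iff the gated score reaches the cutpoint (inclusive)."""
    if cutpoint <= 0:
        raise ValueError("cutpoint must be positive")
    return gated_percent >= cutpoint
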