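"""Analytic CT phantoms with known pleural PPFE coverage.

The phantom is deliberately simple anatomy: an elliptic-cylinder thorax of
soft tissue, two half-ellipsoid lungs of aerated-lung attenuation, a tracheal
air column that bifurcates into two bronchial columns at a known slice, and
subpleural "wedge" lesions rendered at soft-tissue attenuation inside the
peripheral shell band of the lung cross-section. Because lesions are confined
to the same peripheral band that the quantifier measures, the requested
pleural-surface coverage maps directly onto countable ground truth.

Ground truth is computed by exact voxel counting on the noise-free label
grid, never from the HU rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ..volume import CTVolume

# label-grid codes
L_OUTSIDE = 0
L_BODY = 1
L_RIGHT_LUNG = 2
L_LEFT_LUNG = 3
L_AIRWAY = 4
L_WEDGE_RIGHT = 5
L_WEDGE_LEFT = 6

_CROSS2D = ndimage.generate_binary_structure(2, 1)  # 4-connected


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid: centre (slice, row, col) voxels, semi-axes mm."""

    centre: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass
class Wedge:
    """A subpleural lesion: an angular sector of the peripheral shell band.

    Angles are degrees measured anticlockwise from the +col axis about the
    lung's in-plane cross-section centroid; the sector spans
    [theta_start, theta_stop) with wrap-around allowed.
    """

    side: str  # "right" | "left"
    slice_range: tuple[int, int]  # inclusive axial slice interval
    theta_start_deg: float
    theta_stop_deg: float
    radial_depth_vox: int = 3
    parenchymal_extension_vox: int = 0  # extra depth beyond the shell band


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (120, 128, 128)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    right_lung: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((68.0, 72.0, 40.0), (46.0, 26.0, 18.0))
    )
    left_lung: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((68.0, 72.0, 88.0), (46.0, 26.0, 18.0))
    )
    body_semi_axes_mm: tuple[float, float] = (52.0, 60.0)  # (row, col)
    body_centre: tuple[float, float] = (64.0, 64.0)
    trachea_centre: tuple[float, float] = (40.0, 64.0)  # (row, col)
    trachea_radius_mm: float = 4.0
    bifurcation_slice: int = 60
    bronchus_offset_mm: float = 5.0  # keeps bronchi 3D-connected to the trachea yet in-plane disjoint
    bronchus_length_slices: int = 12
    hu_air: float = -1000.0
    hu_lung: float = -850.0
    hu_body: float = 40.0
    hu_ppfe: float = 40.0
    wedge_list: list[Wedge] = field(default_factory=list)
    noise_sd: float = 30.0
    shell_depth_vox: int = 3  # band used for both rendering and ground truth
    apex_exclusion_mm: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape components must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing components must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        apex = self.apex_slice()
        if self.bifurcation_slice <= apex:
            raise ValueError("bifurcation slice must be strictly caudal to the lung apex")
        for i, w in enumerate(self.wedge_list):
            if w.side not in ("right", "left"):
                raise ValueError(f"wedge {i}: side must be 'right' or 'left'")
            lung = self.right_lung if w.side == "right" else self.left_lung
            dz = self.voxel_spacing[0]
            z_lo = lung.centre[0] - lung.semi_axes_mm[0] / dz
            z_hi = lung.centre[0] + lung.semi_axes_mm[0] / dz
            if w.slice_range[0] > w.slice_range[1]:
                raise ValueError(f"wedge {i}: empty slice range")
            if w.slice_range[0] < z_lo or w.slice_range[1] > z_hi:
                raise ValueError(
                    f"wedge {i} ({w.side}, slices {w.slice_range}) lies outside "
                    f"its lung's axial extent [{z_lo:.1f}, {z_hi:.1f}]"
                )

    def apex_slice(self) -> int:
        """Most cranial slice index containing lung tissue."""
        dz = self.voxel_spacing[0]
        tops = [
            lung.centre[0] - lung.semi_axes_mm[0] / dz
            for lung in (self.right_lung, self.left_lung)
        ]
        return int(np.ceil(min(tops)))


@dataclass
class GroundTruthPPFE:
    """Exact voxel counts over the upper-zone pleural shell, per lung and pooled."""

    shell_voxels: dict[str, int]
    dense_shell_voxels: dict[str, int]
    true_cppfe_percent: float
    carina_slice: int
    apex_slice: int
    zone_slices: tuple[int, int]
    label_grid: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "shell_voxels": self.shell_voxels,
            "dense_shell_voxels": self.dense_shell_voxels,
            "true_cppfe_percent": self.true_cppfe_percent,
            "carina_slice": self.carina_slice,
            "apex_slice": self.apex_slice,
            "zone_slices": list(self.zone_slices),
        }


def _ellipsoid_mask(shape, spacing, ell: Ellipsoid) -> np.ndarray:
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = ell.centre
    az, ay, ax = (s / sp for s, sp in zip(ell.semi_axes_mm, spacing))
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def _disk2d(shape2d, spacing2d, centre, radius_mm) -> np.ndarray:
    y, x = np.ogrid[: shape2d[0], : shape2d[1]]
    cy, cx = centre
    ry, rx = radius_mm / spacing2d[0], radius_mm / spacing2d[1]
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _shell_band_2d(section: np.ndarray, depth: int) -> np.ndarray:
    """Peripheral band: lung cross-section minus its 4-connected erosion `depth` times."""
    if not section.any():
        return section
    eroded = ndimage.binary_erosion(section, _CROSS2D, iterations=depth, border_value=0)
    return section & ~eroded


def build_label_grid(spec: PhantomSpec) -> np.ndarray:
    """Render the noise-free anatomical label grid."""
    shape, sp = spec.grid_shape, spec.voxel_spacing
    labels = np.zeros(shape, dtype=np.uint8)

    y, x = np.ogrid[: shape[1], : shape[2]]
    cy, cx = spec.body_centre
    by, bx = spec.body_semi_axes_mm[0] / sp[1], spec.body_semi_axes_mm[1] / sp[2]
    body2d = ((y - cy) / by) ** 2 + ((x - cx) / bx) ** 2 <= 1.0
    labels[:, body2d] = L_BODY

    right = _ellipsoid_mask(shape, sp, spec.right_lung)
    left = _ellipsoid_mask(shape, sp, spec.left_lung)
    labels[right] = L_RIGHT_LUNG
    labels[left] = L_LEFT_LUNG

    # trachea from the top slice down to (and including) the last pre-bifurcation
    # slice; two bronchial columns from the bifurcation slice caudally.
    trachea2d = _disk2d(shape[1:], sp[1:], spec.trachea_centre, spec.trachea_radius_mm)
    for z in range(0, min(spec.bifurcation_slice, shape[0])):
        labels[z][trachea2d] = L_AIRWAY
    off = spec.bronchus_offset_mm / sp[2]
    bron_r = _disk2d(
        shape[1:], sp[1:], (spec.trachea_centre[0], spec.trachea_centre[1] - off),
        spec.trachea_radius_mm * 0.75,
    )
    bron_l = _disk2d(
        shape[1:], sp[1:], (spec.trachea_centre[0], spec.trachea_centre[1] + off),
        spec.trachea_radius_mm * 0.75,
    )
    z_end = min(spec.bifurcation_slice + spec.bronchus_length_slices, shape[0])
    for z in range(spec.bifurcation_slice, z_end):
        labels[z][bron_r | bron_l] = L_AIRWAY

    _render_wedges(labels, spec)
    return labels


def _render_wedges(labels: np.ndarray, spec: PhantomSpec) -> None:
    for w in spec.wedge_list:
        lung_code = L_RIGHT_LUNG if w.side == "right" else L_LEFT_LUNG
        wedge_code = L_WEDGE_RIGHT if w.side == "right" else L_WEDGE_LEFT
        depth = w.radial_depth_vox + w.parenchymal_extension_vox
        for z in range(w.slice_range[0], w.slice_range[1] + 1):
            if z < 0 or z >= labels.shape[0]:
                continue
            section = labels[z] == lung_code
            if not section.any():
                continue
            band = _shell_band_2d(section, depth)
            rows, cols = np.nonzero(band)
            cyx = ndimage.center_of_mass(section)
            theta = np.degrees(np.arctan2(rows - cyx[0], cols - cyx[1])) % 360.0
            span = (w.theta_stop_deg - w.theta_start_deg) % 360.0
            if span == 0.0 and w.theta_stop_deg != w.theta_start_deg:
                span = 360.0
            rel = (theta - w.theta_start_deg) % 360.0
            sel = rel < span
            labels[z, rows[sel], cols[sel]] = wedge_code


def ground_truth_from_labels(spec: PhantomSpec, labels: np.ndarray) -> GroundTruthPPFE:
    """Count dense vs total shell voxels in the upper zone on the label grid."""
    apex = int(np.argmax((np.isin(labels, _LUNG_OR_WEDGE)).any(axis=(1, 2))))
    excl = int(np.ceil(spec.apex_exclusion_mm / spec.voxel_spacing[0]))
    carina = spec.bifurcation_slice
    z0, z1 = apex + excl, carina
    shell = {"right": 0, "left": 0}
    dense = {"right": 0, "left": 0}
    for side, lung_code, wedge_code in (
        ("right", L_RIGHT_LUNG, L_WEDGE_RIGHT),
        ("left", L_LEFT_LUNG, L_WEDGE_LEFT),
    ):
        for z in range(z0, min(z1 + 1, labels.shape[0])):
            section = (labels[z] == lung_code) | (labels[z] == wedge_code)
            band = _shell_band_2d(section, spec.shell_depth_vox)
            shell[side] += int(band.sum())
            dense[side] += int((band & (labels[z] == wedge_code)).sum())
    total = shell["right"] + shell["left"]
    total_dense = dense["right"] + dense["left"]
    pct = 100.0 * total_dense / total if total else 0.0
    return GroundTruthPPFE(
        shell_voxels=shell,
        dense_shell_voxels=dense,
        true_cppfe_percent=pct,
        carina_slice=carina,
        apex_slice=apex,
        zone_slices=(z0, z1),
    )


_LUNG_OR_WEDGE = (L_RIGHT_LUNG, L_LEFT_LUNG, L_WEDGE_RIGHT, L_WEDGE_LEFT)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruthPPFE]:
    """Render a phantom CT and its exactly counted pleural-coverage ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    labels = build_label_grid(spec)
    hu = np.full(spec.grid_shape, spec.hu_air, dtype=np.float32)
    hu[labels == L_BODY] = spec.hu_body
    hu[(labels == L_RIGHT_LUNG) | (labels == L_LEFT_LUNG)] = spec.hu_lung
    hu[labels == L_AIRWAY] = spec.hu_air
    hu[(labels == L_WEDGE_RIGHT) | (labels == L_WEDGE_LEFT)] = spec.hu_ppfe
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)
        np.clip(hu, -1090.0, 2990.0, out=hu)
    truth = ground_truth_from_labels(spec, labels)
    truth.label_grid = labels
    volume = CTVolume(hu_grid=hu, spacing=spec.voxel_spacing,
                      meta={"phantom_seed": spec.seed})
    return volume, truth


def spec_for_coverage(coverage_percent: float, *, seed: int = 0,
                      base: PhantomSpec | None = None,
                      n_foci_per_lung: int = 5,
                      theta_start_deg: float = 10.0) -> PhantomSpec:
    """Build a PhantomSpec whose wedges cover ≈ `coverage_percent` of the
    upper-zone pleural shell of both lungs.

    Lesions are laid down as several narrow angular foci per lung (PPFE is
    typically multifocal). The angular extent of an elliptical
    cross-section's shell is not uniform in central angle, so each focus'
    sector bound is chosen from the empirical quantile of the shell-voxel
    angle distribution on the lesion-free label grid. Each focus extends a
    couple of voxels deeper than the measured shell band so that small
    boundary-reconstruction errors in downstream segmentation do not push
    the band outside the lesion. Ground truth is still exact counting on the
    label grid; this helper only aims the request.
    """
    if not 0.0 <= coverage_percent <= 100.0:
        raise ValueError("coverage_percent must be in [0, 100]")
    base = base if base is not None else PhantomSpec()
    spec = replace(base, wedge_list=[], seed=seed)
    if coverage_percent == 0.0:
        return spec
    labels = build_label_grid(spec)
    truth = ground_truth_from_labels(spec, labels)
    z0, z1 = truth.zone_slices
    frac = coverage_percent / 100.0
    # fewer foci at low coverage so individual arcs stay above the
    # per-slice noise-suppression size used downstream
    k_foci = max(1, min(n_foci_per_lung, int(np.ceil(coverage_percent / 8.0))))
    sp = spec.voxel_spacing
    wedges = []
    for side, lung_code, lung in (
        ("right", L_RIGHT_LUNG, spec.right_lung),
        ("left", L_LEFT_LUNG, spec.left_lung),
    ):
        thetas = []
        for z in range(z0, z1 + 1):
            section = labels[z] == lung_code
            band = _shell_band_2d(section, spec.shell_depth_vox)
            rows, cols = np.nonzero(band)
            if rows.size == 0:
                continue
            cyx = ndimage.center_of_mass(section)
            thetas.append(
                np.degrees(np.arctan2(rows - cyx[0], cols - cyx[1])) % 360.0
            )
        th = np.concatenate(thetas)
        # largest in-plane curvature radius of the elliptical cross-section
        # (a^2/b at the minor-axis ends), in voxels: chord-sagitta bound for
        # convex-boundary reconstruction is governed by the flattest arc
        ry = lung.semi_axes_mm[1] / sp[1]
        rx = lung.semi_axes_mm[2] / sp[2]
        a, b = max(ry, rx), min(ry, rx)
        r_vox = a * a / b
        spacing_deg = 360.0 / k_foci
        for j in range(k_foci):
            start = (theta_start_deg + j * spacing_deg) % 360.0
            rel = np.sort((th - start) % 360.0)
            target = frac * th.size / k_foci
            k = max(1, int(round(target)))
            width = rel[min(k, rel.size) - 1] + 1e-6
            if width > 0.92 * spacing_deg:
                raise ValueError(
                    "requested coverage too high for the number of foci; "
                    "increase n_foci_per_lung"
                )
            # convex-boundary reconstruction misses at most the chord sagitta
            sagitta = r_vox * (1.0 - np.cos(np.radians(width / 2.0)))
            ext = int(np.ceil(sagitta)) + 1
            wedges.append(
                Wedge(side=side, slice_range=(z0, z1),
                      theta_start_deg=start, theta_stop_deg=start + width,
                      radial_depth_vox=spec.shell_depth_vox,
                      parenchymal_extension_vox=ext)
            )
    return replace(spec, wedge_list=wedges, seed=seed)
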