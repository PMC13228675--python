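"""Seeded synthetic ultrasound phantoms with ground-truth synovial labels.

Real musculoskeletal scans of the thumb base show a hypoechoic (dark)
synovial recess lying between two hyperechoic (bright) curved bone
surfaces, over a mid-grey speckled soft-tissue background, with occasional
attenuation shadows below bone. The generator emulates exactly those
first-order features:

* two bright curved bands (bone surrogates) with optional shadows beneath,
* a hypoechoic target region between them — an in-plane crescent (the
  synovial recess) or an ellipsoid (for analytic volume checks),
* multiplicative gamma speckle.

It makes no attempt at wave-physics realism (no beamforming, no frequency-
dependent attenuation); the aim is a controllable, fully deterministic
stand-in for the clinical data with exact per-voxel ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import DEFAULT_SPACING, LabelVolume, UltrasoundVolume

__all__ = [
    "PhantomParams",
    "RaterPerturbation",
    "GeometryError",
    "generate_phantom",
    "simulate_second_rater",
    "draw_params",
    "generate_dataset",
]


class GeometryError(ValueError):
    """Target does not fit inside the volume with the required clearance."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, echogenicity and noise settings of one phantom.

    Echogenicity means must be ordered target < background < bone
    (hypoechoic synovium, hyperechoic bone).
    """

    shape: tuple[int, int, int] = (40, 64, 64)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = DEFAULT_SPACING  # (dz, dy, dx) mm
    target_kind: str = "crescent"  # or "ellipsoid"
    # ellipsoid semi-axes (a, b, c) mm along (x, y, z)
    semi_axes_mm: tuple[float, float, float] = (2.0, 1.5, 3.5)
    # crescent: max in-plane thickness (mm) and outer radius (mm)
    crescent_thickness_mm: float = 1.2
    crescent_radius_mm: float = 2.5
    # fractional target centre within the volume, (z, y, x)
    center_frac: tuple[float, float, float] = (0.5, 0.55, 0.5)
    speckle_amount: float = 0.35  # 0 disables speckle entirely
    speckle_shape: float = 3.0  # gamma shape of the multiplicative field
    shadow_probability: float = 0.15  # per-column chance of a shadow strip
    shadow_width_mm: float = 0.6
    shadow_attenuation: float = 0.5
    level_target: float = 0.15
    level_background: float = 0.45
    level_bone: float = 0.85
    bone_half_width_mm: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.level_target < self.level_background < self.level_bone:
            raise ValueError(
                "echogenicity must be ordered target < background < bone"
            )
        if self.target_kind not in ("crescent", "ellipsoid"):
            raise ValueError(f"unknown target_kind {self.target_kind!r}")
        if min(self.semi_axes_mm) <= 0 or self.crescent_thickness_mm <= 0:
            raise ValueError("semi-axes and thickness must be strictly positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass(frozen=True)
class RaterPerturbation:
    """Simulated second-rater disagreement.

    ``jitter_voxels`` is the amplitude of a smooth per-slice boundary
    displacement (spatially correlated, zero-mean); ``radius_voxels`` is a
    uniform dilation (mode ``"dilate"``) or erosion (``"erode"``) applied
    after the jitter, modelling a rater's systematic over/under-contouring.
    """

    jitter_voxels: float = 0.0
    radius_voxels: int = 0
    mode: str = "dilate"
    jitter_correlation_voxels: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_voxels < 0 or self.radius_voxels < 0:
            raise ValueError("jitter amplitude and radius must be >= 0")
        if self.mode not in ("dilate", "erode"):
            raise ValueError(f"mode must be 'dilate' or 'erode', got {self.mode!r}")


# ---------------------------------------------------------------------------
# geometry helpers

def _physical_grids(shape, spacing):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    return z, y, x


def _target_mask(p: PhantomParams) -> np.ndarray:
    """Voxelised target region; centre of each voxel tested against the solid."""
    z, y, x = _physical_grids(p.shape, p.spacing)
    nz, ny, nx = p.shape
    dz, dy, dx = p.spacing
    cz = p.center_frac[0] * (nz - 1) * dz
    cy = p.center_frac[1] * (ny - 1) * dy
    cx = p.center_frac[2] * (nx - 1) * dx

    if p.target_kind == "ellipsoid":
        a, b, c = p.semi_axes_mm  # along (x, y, z)
        m = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
        extent = np.array([c, b, a])
    else:
        # crescent: difference of two discs per slice; the inner disc is
        # shifted toward the bone below, leaving a concave-down recess whose
        # thickness tapers smoothly along z (sinusoidal profile).
        half_span = p.semi_axes_mm[2]  # z half-extent, mm
        r_out = p.crescent_radius_mm
        zprof = np.clip(1.0 - ((z[:, 0, 0] - cz) / half_span) ** 2, 0.0, None)
        thick = p.crescent_thickness_mm * np.sqrt(zprof)  # mm per slice
        r2_out = (x - cx) ** 2 + (y - cy) ** 2
        # inner disc centre shifted down (larger y) by the slice thickness
        yin = cy + thick[:, None, None]
        r2_in = (x - cx) ** 2 + (y - yin) ** 2
        m = (r2_out <= r_out**2) & (r2_in > r_out**2) & (thick[:, None, None] > 0)
        extent = np.array([half_span, r_out, r_out])

    lo = np.array([cz, cy, cx]) - extent
    hi = np.array([cz, cy, cx]) + extent
    clear = 2 * np.array(p.spacing)
    dims = (np.array(p.shape) - 1) * np.array(p.spacing)
    if (lo < clear - 1e-9).any() or (hi > dims - clear + 1e-9).any():
        raise GeometryError(
            f"{p.target_kind} target (extent {extent} mm about centre "
            f"({cz:.2f},{cy:.2f},{cx:.2f})) does not fit the "
            f"{p.shape} volume with 2-voxel clearance"
        )
    return m


def _bone_masks(p: PhantomParams, label: np.ndarray) -> np.ndarray:
    """Two bright curved bands, one above and one below the target."""
    z, y, x = _physical_grids(p.shape, p.spacing)
    nz, ny, nx = p.shape
    dz, dy, dx = p.spacing
    cx = p.center_frac[2] * (nx - 1) * dx
    width_x = (nx - 1) * dx

    ys = np.nonzero(label.any(axis=(0, 2)))[0]
    y_top = ys.min() * dy
    y_bot = ys.max() * dy
    gap = 4 * dy  # keep bone clear of the label
    # gentle parabola in x with a slow z modulation, like curved bone surfaces
    curve = 0.08 * ((x - cx) ** 2) / max(width_x, 1e-9)
    wobble = 0.15 * np.sin(2 * np.pi * z / max((nz - 1) * dz, 1e-9))
    band_upper = np.abs(y - (y_top - gap - curve + wobble)) <= p.bone_half_width_mm
    band_lower = np.abs(y - (y_bot + gap + curve + wobble)) <= p.bone_half_width_mm
    bone = (band_upper | band_lower) & ~label.astype(bool)
    return bone


def generate_phantom(p: PhantomParams) -> tuple[UltrasoundVolume, LabelVolume]:
    """Render one phantom volume and its exact label; deterministic per seed."""
    rng = np.random.default_rng(p.seed)
    label = _target_mask(p)
    bone = _bone_masks(p, label)

    img = np.full(p.shape, p.level_background, dtype=np.float64)
    img[label] = p.level_target
    img[bone] = p.level_bone

    # attenuation shadows: dark strips below bone, per (z, x) column
    if p.shadow_probability > 0:
        nz, ny, nx = p.shape
        dx = p.spacing[2]
        w = max(int(round(p.shadow_width_mm / dx)), 1)
        hit = rng.random((nz, nx)) < p.shadow_probability
        for zi, xi in np.argwhere(hit):
            col = bone[zi, :, xi]
            if not col.any():
                continue
            y0 = int(np.nonzero(col)[0].max()) + 1
            x1 = min(xi + w, nx)
            sl = img[zi, y0:, xi:x1]
            keep = ~label[zi, y0:, xi:x1]  # never darken the ground-truth region
            sl[keep] *= p.shadow_attenuation

    if p.speckle_amount > 0:
        g = rng.gamma(p.speckle_shape, 1.0 / p.speckle_shape, size=p.shape)
        img *= 1.0 + p.speckle_amount * (g - 1.0)

    img = np.clip(img, 0.0, 1.0)
    vol = UltrasoundVolume(voxels=img, spacing=p.spacing)
    lab = LabelVolume(voxels=label.astype(np.uint8), spacing=p.spacing)
    return vol, lab


# ---------------------------------------------------------------------------
# second rater

def simulate_second_rater(
    label: LabelVolume, pert: RaterPerturbation
) -> tuple[LabelVolume, list[int]]:
    """Perturb a manual segmentation the way a second human rater would.

    Each nonempty slice boundary is displaced by a smooth zero-mean random
    field (spatially correlated jitter), then uniformly dilated or eroded.
    Returns the perturbed label and the indices of slices the perturbation
    emptied (left empty, flagged rather than fatal).
    """
    if not label.voxels.any():
        raise ValueError("cannot perturb an empty label")
    rng = np.random.default_rng(pert.seed)
    out = np.zeros_like(label.voxels)
    emptied: list[int] = []
    struct = ndimage.generate_binary_structure(2, 1)

    for zi in range(label.shape[0]):
        sl = label.voxels[zi].astype(bool)
        if not sl.any():
            continue
        m = sl
        if pert.jitter_voxels > 0:
            # signed distance to the boundary, positive inside
            sdt = ndimage.distance_transform_edt(m) - ndimage.distance_transform_edt(~m)
            noise = rng.standard_normal(m.shape)
            noise = ndimage.gaussian_filter(noise, pert.jitter_correlation_voxels)
            sd = noise.std()
            if sd > 0:
                noise *= pert.jitter_voxels / (2.0 * sd)  # ~95% within +-amplitude
            m = (sdt + noise) > 0
        if pert.radius_voxels > 0:
            op = (
                ndimage.binary_dilation
                if pert.mode == "dilate"
                else ndimage.binary_erosion
            )
            m = op(m, structure=struct, iterations=pert.radius_voxels)
        if not m.any():
            emptied.append(zi)
            continue
        # keep exactly one perturbed component per original component: the
        # largest one overlapping it (or the global largest if none overlap)
        lab_m, n = ndimage.label(m)
        if n > 1:
            lab_o, n_o = ndimage.label(sl)
            sizes = ndimage.sum_labels(m, lab_m, index=np.arange(1, n + 1))
            keep: set[int] = set()
            for i in range(1, n_o + 1):
                over = np.unique(lab_m[(lab_o == i) & m])
                over = over[over > 0]
                if over.size:
                    keep.add(int(over[np.argmax(sizes[over - 1])]))
            if not keep:
                keep = {1 + int(np.argmax(sizes))}
            m = np.isin(lab_m, sorted(keep))
        out[zi] = m
    return LabelVolume(out, spacing=label.spacing, origin=label.origin), emptied


# ---------------------------------------------------------------------------
# datasets

def draw_params(template: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """One per-volume parameter draw: jittered centre, size and seed."""
    scale = rng.uniform(0.75, 1.10)
    center = (
        float(rng.uniform(0.47, 0.53)),
        float(rng.uniform(0.50, 0.56)),
        float(rng.uniform(0.47, 0.53)),
    )
    return replace(
        template,
        semi_axes_mm=tuple(s * scale for s in template.semi_axes_mm),
        crescent_thickness_mm=template.crescent_thickness_mm * scale,
        crescent_radius_mm=template.crescent_radius_mm * scale,
        center_frac=center,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n_volumes: int, template: PhantomParams, seed: int
) -> list[tuple[UltrasoundVolume, LabelVolume]]:
    """Seeded collection of phantoms with varied target geometry."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    return [generate_phantom(draw_params(template, rng)) for _ in range(n_volumes)]
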