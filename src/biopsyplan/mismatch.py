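"""Intra-procedure spatial mismatch simulation.

Two error sources are modelled between the pre-procedure plan and the
intra-procedure anatomy:

* rigid target registration error (TRE): zero-mean isotropic Gaussian
  translations whose RMS magnitude equals the configured level in mm;
* nonrigid organ motion: a free-form deformation defined by displacements at
  a 10x10x10 equidistant control-point grid spanning the image, smoothed into
  a dense per-voxel field by Gaussian splines. Its severity is set by a
  *rate* (fraction of control points displaced per time step) and a *scale*
  (bound in mm on each sampled displacement component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantoms_io import MaskVolume

__all__ = [
    "CONTROL_SHAPE",
    "TREConfig",
    "DeformationConfig",
    "DeformationField",
    "sample_tre",
    "sample_deformation",
    "densify",
    "warp_mask",
    "translate_mask",
    "field_to_volume",
]

CONTROL_SHAPE = (10, 10, 10)
N_CONTROL = int(np.prod(CONTROL_SHAPE))


@dataclass
class TREConfig:
    """Rigid registration-error model.

    ``level_mm`` is the expected (RMS) displacement magnitude; each axis is
    N(0, level_mm^2/3) so that E[|d|^2] = level_mm^2. With ``per_structure``
    the gland and lesion receive independent translations, modelling
    independent errors on anatomy and target.
    """

    level_mm: float = 0.0
    per_structure: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.level_mm < 0:
            raise ValueError("level_mm must be >= 0")


@dataclass
class DeformationConfig:
    """Free-form deformation severity: rate, scale and spline width."""

    rate: float = 0.0
    scale: float = 0.0
    kernel_sigma_mm: float | None = None  # default: control-point spacing
    accumulate: bool = False  # compose across steps instead of fresh-per-step
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must be in [0, 1]")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.rate > 0 and self.scale > 0


@dataclass
class DeformationField:
    """Sparse control-point displacements plus the Gaussian kernel width."""

    displacements: np.ndarray  # (10, 10, 10, 3) mm
    image_extent_mm: tuple[float, float, float]
    kernel_sigma_mm: float
    rate: float = 0.0
    scale: float = 0.0

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != CONTROL_SHAPE + (3,):
            raise ValueError(
                f"displacements must have shape {CONTROL_SHAPE + (3,)}"
            )

    def n_displaced(self) -> int:
        return int(np.any(self.displacements != 0, axis=-1).sum())

    def control_coords(self, axis: int) -> np.ndarray:
        """World mm positions of control points along one axis (equidistant,
        spanning [0, extent])."""
        n = CONTROL_SHAPE[axis]
        return np.linspace(0.0, self.image_extent_mm[axis], n)


def sample_tre(config: TREConfig, rng: np.random.Generator | None = None):
    """Draw rigid translation(s) in mm.

    Returns a dict with keys ``gland`` and ``lesion``; with
    ``per_structure=False`` both entries are the same vector. Level 0 yields
    exact zero vectors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.level_mm == 0:
        z = np.zeros(3)
        return {"gland": z, "lesion": z.copy()}
    sigma = config.level_mm / np.sqrt(3.0)
    g = rng.normal(0.0, sigma, 3)
    l = rng.normal(0.0, sigma, 3) if config.per_structure else g.copy()
    return {"gland": g, "lesion": l}


def sample_deformation(
    rate: float,
    scale: float,
    kernel_sigma_mm: float | None,
    image_extent_mm: tuple[float, float, float],
    seed: int | np.random.Generator | None = None,
) -> DeformationField:
    """Sample a control-point field: ceil(rate*1000) points displaced.

    Displaced points are chosen uniformly without replacement; each of their
    displacement components is uniform in [-scale, +scale] mm. Remaining
    control points stay at zero.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if kernel_sigma_mm is None:
        kernel_sigma_mm = float(
            np.mean([e / (CONTROL_SHAPE[d] - 1) for d, e in enumerate(image_extent_mm)])
        )
    disp = np.zeros(CONTROL_SHAPE + (3,), dtype=float)
    n_move = int(np.ceil(rate * N_CONTROL))
    if n_move > 0 and scale > 0:
        chosen = rng.choice(N_CONTROL, size=n_move, replace=False)
        flat = disp.reshape(N_CONTROL, 3)
        flat[chosen] = rng.uniform(-scale, scale, size=(n_move, 3))
    return DeformationField(
        displacements=disp,
        image_extent_mm=tuple(float(e) for e in image_extent_mm),
        kernel_sigma_mm=float(kernel_sigma_mm),
        rate=rate,
        scale=scale,
    )


def densify(
    field: DeformationField,
    target_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Evaluate the Gaussian-spline field at every voxel centre.

    Returns a ``target_shape + (3,)`` array of mm displacements:
    ``u(x) = sum_c d_c * exp(-|x - x_c|^2 / (2 sigma^2))`` with a unit-peak
    kernel, so a voxel at a control point recovers that point's displacement
    up to neighbour overlap. The isotropic kernel separates per axis, so the
    sum is evaluated as three successive tensor contractions; linear in the
    control displacements by construction. The dense magnitude is bounded by
    ``max|d_c|`` times the sum of kernel weights along each axis.
    """
    ext = field.image_extent_mm
    sig = field.kernel_sigma_mm
    basis = []
    for d in range(3):
        x = np.arange(target_shape[d]) * spacing[d]  # voxel centres, mm
        c = field.control_coords(d)
        basis.append(np.exp(-((x[:, None] - c[None, :]) ** 2) / (2.0 * sig**2)))
    if any(abs(ext[d] - (target_shape[d] - 1) * spacing[d]) > max(spacing) for d in range(3)):
        raise ValueError(
            f"field extent {ext} does not match image extent "
            f"{tuple((target_shape[d] - 1) * spacing[d] for d in range(3))}"
        )
    # dense[i,j,k,c] = sum_abc Bx[i,a] By[j,b] Bz[k,c'] D[a,b,c',c]
    out = np.tensordot(basis[0], field.displacements, axes=([1], [0]))
    out = np.tensordot(basis[1], out, axes=([1], [1]))  # (ny, nx, 10, 3)
    out = np.tensordot(basis[2], out, axes=([1], [2]))  # (nz, ny, nx, 3)
    return np.ascontiguousarray(out.transpose(2, 1, 0, 3))


def warp_mask(mask: MaskVolume, dense_field_mm: np.ndarray) -> MaskVolume:
    """Backward-warp a binary mask through a dense displacement field.

    The field gives the forward displacement u(x) in mm; the output samples
    the input at ``x - u(x)`` with trilinear interpolation and thresholds at
    0.5, so a uniform field of +k voxels translates the mask by +k voxels.
    Output is binary with the input's shape, spacing and origin.
    """
    if dense_field_mm.shape != mask.shape + (3,):
        raise ValueError("dense field shape must be mask.shape + (3,)")
    if not np.all(np.isfinite(dense_field_mm)):
        raise ValueError("non-finite values in deformation field")
    if not dense_field_mm.any():
        return mask.copy()
    coords = np.meshgrid(
        *[np.arange(n, dtype=float) for n in mask.shape], indexing="ij"
    )
    sample = [
        coords[d] - dense_field_mm[..., d] / mask.spacing[d] for d in range(3)
    ]
    warped = ndimage.map_coordinates(
        mask.voxels.astype(np.float32), sample, order=1, mode="constant", cval=0.0
    )
    return MaskVolume((warped > 0.5).astype(np.uint8), mask.spacing, mask.origin)


def translate_mask(mask: MaskVolume, translation_mm: np.ndarray) -> MaskVolume:
    """Rigidly translate a binary mask by a world-mm vector (linear resample,
    0.5 threshold). Used to inject TRE into observed masks."""
    t = np.asarray(translation_mm, dtype=float)
    if not t.any():
        return mask.copy()
    shift_vox = t / np.asarray(mask.spacing)
    out = ndimage.shift(
        mask.voxels.astype(np.float32), shift_vox, order=1, mode="constant", cval=0.0
    )
    return MaskVolume((out > 0.5).astype(np.uint8), mask.spacing, mask.origin)


def field_to_volume(field: DeformationField, shape, spacing, origin=(0, 0, 0)):
    """Dense field as a 4D NIfTI-ready array plus affine (for export)."""
    dense = densify(field, tuple(shape), tuple(spacing))
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return dense, affine


def write_field(field: DeformationField, shape, spacing, path, origin=(0, 0, 0)):
    """Export a dense displacement field as 4D NIfTI (x/y/z components in
    the fourth dimension, mm)."""
    import nibabel as nib

    dense, affine = field_to_volume(field, shape, spacing, origin)
    nib.save(nib.Nifti1Image(dense.astype(np.float32), affine), str(path))
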