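"""Synthetic patient phantoms, NIfTI mask I/O, and patient-level dataset splits.

A *case* is one prostate gland mask paired with one target lesion mask.
Real transperineal-biopsy cohorts are built from radiologist-annotated binary
masks on T2-weighted MR; this module generates ellipsoidal stand-ins with the
same structural guarantees (lesion strictly inside the gland, one case per
lesion, several lesions per patient sharing a gland) so that the planning
environment, learning code and metrics can be exercised end to end on purely
synthetic data.

World coordinates are millimetres, with ``world = origin + index * spacing``
at voxel centres; voxel indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MaskVolume",
    "PatientCase",
    "DatasetSplit",
    "generate_phantom",
    "generate_cohort",
    "read_mask",
    "write_mask",
    "split_dataset",
    "write_cohort",
    "read_cohort",
]

DEFAULT_SHAPE = (96, 96, 64)
DEFAULT_SPACING = (1.0, 1.0, 1.0)

#: image axis along which biopsy needles travel (inferior-superior on the
#: patient; the template grid lives in the transverse plane of axes 0 and 1)
NEEDLE_AXIS = 2


@dataclass
class MaskVolume:
    """A 3D binary mask with voxel spacing and world origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        v = self.voxels
        if v.dtype == bool:
            ok = True
        elif v.dtype == np.uint8:
            ok = v.max(initial=0) <= 1
        else:
            ok = bool(((v == 0) | (v == 1)).all())
        if not ok:
            raise ValueError("mask voxels must be binary (0/1)")
        self.voxels = v.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        """Sum of voxel volumes inside the mask."""
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Voxel indices (n,3) -> world mm coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def centroid_mm(self) -> np.ndarray:
        """Voxel-count-weighted centroid of the mask in world mm."""
        idx = np.argwhere(self.voxels > 0)
        if idx.size == 0:
            raise ValueError("centroid of an empty mask is undefined")
        return self.world_coords(idx.mean(axis=0))[0]

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.voxels.copy(), self.spacing, self.origin)


@dataclass
class PatientCase:
    """One gland plus one target lesion; the unit of episodes and splits.

    Patients with several lesions contribute several cases that share
    ``patient_id`` and gland geometry.
    """

    patient_id: str
    gland: MaskVolume
    lesion: MaskVolume
    lesion_id: str = "lesion-0"

    def __post_init__(self) -> None:
        if self.gland.shape != self.lesion.shape:
            raise ValueError("gland and lesion masks must share a shape")
        if self.gland.voxels.sum() == 0:
            raise ValueError("gland mask is empty")
        if self.lesion.voxels.sum() == 0:
            raise ValueError("lesion mask is empty")
        outside = self.lesion.voxels & ~self.gland.voxels.astype(bool)
        if outside.any():
            raise ValueError(
                f"lesion protrudes outside gland by {int(outside.sum())} voxels"
            )

    @property
    def case_id(self) -> str:
        return f"{self.patient_id}/{self.lesion_id}"


@dataclass
class DatasetSplit:
    """Patient-level train/validation/test partition of cases."""

    train: list[PatientCase] = field(default_factory=list)
    val: list[PatientCase] = field(default_factory=list)
    test: list[PatientCase] = field(default_factory=list)

    def patient_ids(self, which: str) -> set[str]:
        return {c.patient_id for c in getattr(self, which)}

    def validate(self) -> None:
        sets = [self.patient_ids(w) for w in ("train", "val", "test")]
        for i in range(3):
            for j in range(i + 1, 3):
                common = sets[i] & sets[j]
                if common:
                    raise ValueError(f"patients in multiple splits: {sorted(common)}")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    centre_mm: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    """Rasterize a world-space ellipsoid onto the voxel grid (centre-in test)."""
    axes = [
        (origin[d] + np.arange(shape[d]) * spacing[d] - centre_mm[d]) / radii_mm[d]
        for d in range(3)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx**2 + yy**2 + zz**2 <= 1.0).astype(np.uint8)


def generate_phantom(
    seed: int,
    gland_radii_mm: tuple[float, float, float] = (25.0, 20.0, 22.0),
    lesion_radius_mm: float | tuple[float, float, float] = 6.0,
    lesion_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    jitter_mm: float = 0.0,
    patient_id: str = "phantom-0",
    lesion_id: str = "lesion-0",
) -> PatientCase:
    """Generate one synthetic case: ellipsoidal gland with an embedded lesion.

    The gland is centred in the image. ``lesion_offset_mm`` displaces the
    lesion centre from the gland centre. With ``jitter_mm`` > 0, uniform
    jitter in [-jitter_mm, +jitter_mm] drawn from ``seed`` is added to the
    gland radii and lesion offset. Deterministic for fixed arguments and seed.

    Raises
    ------
    ValueError
        If the requested lesion would protrude outside the gland.
    """
    rng = np.random.default_rng(seed)
    gland_radii = np.asarray(gland_radii_mm, dtype=float)
    lesion_radii = np.broadcast_to(
        np.asarray(lesion_radius_mm, dtype=float), (3,)
    ).copy()
    offset = np.asarray(lesion_offset_mm, dtype=float)
    if jitter_mm > 0:
        gland_radii = gland_radii + rng.uniform(-jitter_mm, jitter_mm, 3)
        offset = offset + rng.uniform(-jitter_mm, jitter_mm, 3)
    if (gland_radii <= 0).any() or (lesion_radii <= 0).any():
        raise ValueError("all radii must be positive")

    centre_mm = np.array(
        [(shape[d] - 1) * spacing[d] / 2.0 for d in range(3)], dtype=float
    )
    gland_vox = _ellipsoid_mask(shape, spacing, (0, 0, 0), centre_mm, gland_radii)
    lesion_vox = _ellipsoid_mask(
        shape, spacing, (0, 0, 0), centre_mm + offset, lesion_radii
    )
    protruding = int((lesion_vox & ~gland_vox.astype(bool)).sum())
    if protruding:
        raise ValueError(
            f"lesion (radii {lesion_radii}, offset {offset}) protrudes outside "
            f"gland radii {gland_radii} by {protruding} voxels"
        )
    gland = MaskVolume(gland_vox, spacing)
    lesion = MaskVolume(lesion_vox, spacing)
    return PatientCase(patient_id, gland, lesion, lesion_id)


def generate_cohort(
    n_patients: int,
    lesions_per_patient: int = 2,
    seed: int = 0,
    gland_radii_range: tuple[float, float] = (18.0, 28.0),
    lesion_radius_range: tuple[float, float] = (4.0, 9.0),
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> list[PatientCase]:
    """Generate a cohort of ``n_patients * lesions_per_patient`` cases.

    Cases of one patient share the gland geometry but differ in lesion
    placement. Gland semi-axes are drawn uniformly per patient from
    ``gland_radii_range`` and lesion radii per lesion from
    ``lesion_radius_range``; lesion centres are placed uniformly inside the
    feasible offset box. Defaults emulate clinically plausible gland semi-axes
    (18-28 mm) and lesion radii spanning roughly one to a few 5 mm grid cells.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    lo_g, hi_g = gland_radii_range
    lo_l, hi_l = lesion_radius_range
    if not (0 < lo_g <= hi_g) or not (0 < lo_l <= hi_l):
        raise ValueError("invalid parameter ranges")
    if lo_g <= hi_l:
        raise ValueError(
            "infeasible ranges: largest lesion radius must be smaller than the "
            "smallest gland semi-axis"
        )
    rng = np.random.default_rng(seed)
    cases: list[PatientCase] = []
    for p in range(n_patients):
        pid = f"patient-{p:04d}"
        gland_radii = tuple(rng.uniform(lo_g, hi_g, 3))
        for k in range(lesions_per_patient):
            r = float(rng.uniform(lo_l, hi_l))
            room = np.asarray(gland_radii) - r
            # rejection-sample offsets satisfying the conservative containment
            # condition sum(((|o_d|+r)/g_d)^2) <= 1 (always admits o = 0)
            while True:
                offset = rng.uniform(-room, room)
                if (((np.abs(offset) + r) / np.asarray(gland_radii)) ** 2).sum() <= 1:
                    break
            offset = tuple(offset)
            case = generate_phantom(
                # derived seed keeps every case reproducible in isolation
                seed=int(rng.integers(0, 2**31 - 1)),
                gland_radii_mm=gland_radii,
                lesion_radius_mm=r,
                lesion_offset_mm=offset,
                shape=shape,
                spacing=spacing,
                patient_id=pid,
                lesion_id=f"lesion-{k}",
            )
            cases.append(case)
    return cases


def read_mask(path) -> MaskVolume:
    """Read a NIfTI volume as a binary mask.

    Non-binary data are thresholded at 0.5 with a warning.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    vals = np.unique(data)
    if not np.isin(vals, (0.0, 1.0)).all():
        warnings.warn(
            f"{path}: non-binary values found; thresholding at 0.5", stacklevel=2
        )
    voxels = (data > 0.5).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return MaskVolume(voxels, spacing, origin)


def write_mask(volume: MaskVolume, path) -> None:
    """Write a mask as NIfTI; round-trips voxels, spacing and origin."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def split_dataset(
    cases: list[PatientCase],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Partition cases into train/val/test at the patient level.

    ``ratios`` are either integer patient counts summing to the number of
    distinct patients, or proportions (normalized internally). All cases of a
    patient land in the same split; deterministic under ``seed`` and invariant
    to the input ordering of cases.
    """
    by_patient: dict[str, list[PatientCase]] = {}
    for c in cases:
        by_patient.setdefault(c.patient_id, []).append(c)
    patients = sorted(by_patient)
    n = len(patients)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (3,) or (ratios < 0).any():
        raise ValueError("ratios must be three non-negative numbers")
    if np.allclose(ratios, np.round(ratios)) and int(ratios.sum()) == n:
        counts = ratios.astype(int)
    else:
        frac = ratios / ratios.sum()
        counts = np.floor(frac * n).astype(int)
        # distribute the remainder to the largest fractional parts
        rem = n - counts.sum()
        order = np.argsort(-(frac * n - counts))
        counts[order[:rem]] += 1
    if (counts == 0).any():
        raise ValueError(f"split counts {tuple(counts)} would leave a split empty")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [patients[i] for i in perm]
    bounds = np.cumsum(counts)
    groups = (
        shuffled[: bounds[0]],
        shuffled[bounds[0] : bounds[1]],
        shuffled[bounds[1] : bounds[2]],
    )
    split = DatasetSplit(
        train=[c for p in groups[0] for c in by_patient[p]],
        val=[c for p in groups[1] for c in by_patient[p]],
        test=[c for p in groups[2] for c in by_patient[p]],
    )
    split.validate()
    return split


def write_cohort(cases: list[PatientCase], out_dir, split: DatasetSplit | None = None):
    """Write cohort masks as NIfTI plus a CSV manifest; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    assignment: dict[str, str] = {}
    if split is not None:
        for name in ("train", "val", "test"):
            for c in getattr(split, name):
                assignment[c.case_id] = name
    rows = []
    written_glands: set[str] = set()
    for c in cases:
        gland_path = out / "masks" / f"{c.patient_id}_gland.nii.gz"
        lesion_path = out / "masks" / f"{c.patient_id}_{c.lesion_id}.nii.gz"
        if c.patient_id not in written_glands:
            write_mask(c.gland, gland_path)
            written_glands.add(c.patient_id)
        write_mask(c.lesion, lesion_path)
        rows.append(
            {
                "patient_id": c.patient_id,
                "lesion_id": c.lesion_id,
                "gland_path": str(gland_path.relative_to(out)),
                "lesion_path": str(lesion_path.relative_to(out)),
                "split": assignment.get(c.case_id, ""),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_cohort(cohort_dir) -> tuple[list[PatientCase], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    cases = []
    for _, row in manifest.iterrows():
        cases.append(
            PatientCase(
                patient_id=row["patient_id"],
                gland=read_mask(root / row["gland_path"]),
                lesion=read_mask(root / row["lesion_path"]),
                lesion_id=row["lesion_id"],
            )
        )
    return cases, manifest
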