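"""Shared fixtures: small phantoms sized for fast episodes.

Test phantoms use 64x64x48 voxels at 1 mm isotropic spacing — large enough
for the 13x13 template (60 mm span) to sit inside the field of view, small
enough for whole-suite runtimes.
"""

from __future__ import annotations

import numpy as np
import pytest

from biopsyplan.phantoms_io import MaskVolume, PatientCase, generate_phantom

SMALL_SHAPE = (64, 64, 48)


@pytest.fixture(scope="session")
def centred_case() -> PatientCase:
    """Ellipsoidal gland with a centred 6 mm lesion."""
    return generate_phantom(
        seed=0,
        gland_radii_mm=(25.0, 22.0, 20.0),
        lesion_radius_mm=6.0,
        lesion_offset_mm=(0.0, 0.0, 0.0),
        shape=SMALL_SHAPE,
    )


@pytest.fixture(scope="session")
def offset_case() -> PatientCase:
    """Gland with a lesion displaced from the centre."""
    return generate_phantom(
        seed=1,
        gland_radii_mm=(25.0, 22.0, 20.0),
        lesion_radius_mm=5.0,
        lesion_offset_mm=(8.0, -6.0, 4.0),
        shape=SMALL_SHAPE,
    )


@pytest.fixture(scope="session")
def full_gland_case() -> PatientCase:
    """Degenerate toy case where the lesion fills the whole gland, so every
    fired needle inside the gland is a hit."""
    return generate_phantom(
        seed=2,
        gland_radii_mm=(24.0, 22.0, 20.0),
        lesion_radius_mm=(24.0, 22.0, 20.0),
        lesion_offset_mm=(0.0, 0.0, 0.0),
        shape=SMALL_SHAPE,
    )


@pytest.fixture(scope="session")
def random_phantoms() -> list[PatientCase]:
    """Fifty phantoms with randomized lesion size and placement."""
    rng = np.random.default_rng(1234)
    cases = []
    for k in range(50):
        r = float(rng.uniform(4.0, 8.0))
        offset = tuple(rng.uniform(-9.0, 9.0, 3))
        cases.append(
            generate_phantom(
                seed=int(rng.integers(2**31)),
                gland_radii_mm=(26.0, 24.0, 21.0),
                lesion_radius_mm=r,
                lesion_offset_mm=offset,
                shape=SMALL_SHAPE,
                patient_id=f"rp-{k:02d}",
            )
        )
    return cases


def box_case(
    lesion_extent=(10, 10, 10), gland_extent=(40, 40, 30), shape=SMALL_SHAPE
) -> PatientCase:
    """Rectangular gland/lesion masks with known projected area and chords."""
    gland = np.zeros(shape, dtype=np.uint8)
    lesion = np.zeros(shape, dtype=np.uint8)
    c = [s // 2 for s in shape]

    def put(arr, ext):
        sl = tuple(
            slice(c[d] - ext[d] // 2, c[d] - ext[d] // 2 + ext[d]) for d in range(3)
        )
        arr[sl] = 1

    put(gland, gland_extent)
    put(lesion, lesion_extent)
    return PatientCase("box", MaskVolume(gland), MaskVolume(lesion))
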