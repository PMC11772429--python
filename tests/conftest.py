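import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tapse3d.measurement import AnnulusFrame, AnnulusSequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def circle_points(radius: float = 20.0, n: int = 16, z: float = 0.0,
                  center=(0.0, 0.0, 0.0)) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.full(n, float(z))])
    return pts + np.asarray(center, dtype=float)


def ring_landmarks(n: int = 16) -> dict[str, int]:
    return {"septal": 0, "anterior": n // 4, "lateral": n // 2, "posterior": 3 * n // 4}


@pytest.fixture
def frame_factory():
    """Build a valid annulus frame from a circle, with optional translation."""

    def make(phase: float, rv_volume: float, translate=(0.0, 0.0, 0.0),
             radius: float = 20.0, n: int = 16) -> AnnulusFrame:
        return AnnulusFrame(
            phase_fraction=phase,
            contour=circle_points(radius=radius, n=n, center=translate),
            landmarks=ring_landmarks(n),
            rv_volume=rv_volume,
        )

    return make


@pytest.fixture
def sequence_factory(frame_factory):
    """Build a two-frame ED/ES sequence: ED at phase 0.0, ES at 0.4."""

    def make(es_translate=(0.0, 0.0, 0.0), ed_translate=(0.0, 0.0, 0.0),
             radius: float = 20.0, n: int = 16) -> AnnulusSequence:
        frames = [
            frame_factory(0.0, 180.0, translate=ed_translate, radius=radius, n=n),
            frame_factory(0.4, 110.0, translate=es_translate, radius=radius, n=n),
        ]
        return AnnulusSequence("test-patient", frames)

    return make


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
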