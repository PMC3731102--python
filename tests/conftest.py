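"""Shared fixtures: random well-conditioned landmark sets and rigid motions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ceph3d import LandmarkSet, Point3, symmetric_template

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ceph3d.landmarks import LANDMARKS
from ceph3d.simulate import TEMPLATE_COORDINATES


def make_random_set(rng: np.random.Generator, subject_id: str = "R",
                    jitter_mm: float = 8.0) -> LandmarkSet:
    """A random non-degenerate landmark set: template plus bounded jitter.

    The jitter is large relative to digitization noise but small enough
    that no triangle collapses, so every analysis quantity stays
    well-conditioned.
    """
    pts = {}
    for code in LANDMARKS:
        base = np.array(TEMPLATE_COORDINATES[code])
        pts[code] = Point3(*(base + rng.uniform(-jitter_mm, jitter_mm, 3)))
    return LandmarkSet(subject_id=subject_id, points=pts)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100, 100, 3)
    return q, t


def transform_set(s: LandmarkSet, rotation: np.ndarray,
                  translation: np.ndarray) -> LandmarkSet:
    """Apply a rigid motion to every landmark."""
    return LandmarkSet(
        subject_id=s.subject_id,
        points={
            c: Point3(*(rotation @ np.array(p.as_tuple()) + translation))
            for c, p in s.points.items()
        },
    )


def mirror_relabel(s: LandmarkSet) -> LandmarkSet:
    """Reflect across x=0 and swap right/left landmark codes.

    For any configuration this produces the subject as it would appear
    if left and right anatomy were exchanged.
    """
    from ceph3d.landmarks import mirror_code

    return LandmarkSet(
        subject_id=s.subject_id,
        points={
            mirror_code(c): Point3(-p.x, p.y, p.z) for c, p in s.points.items()
        },
    )


@pytest.fixture
def template() -> LandmarkSet:
    return symmetric_template()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def random_set(rng) -> LandmarkSet:
    return make_random_set(rng)
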