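"""3D embedding of the floret-generator driven by a chemotaxic gradient.

The abstract generator's bias parameter is reinterpreted spatially: an
extracellular substance has concentration constant in x and y and
linearly increasing along z, so its gradient is ``v = (0, 0, slope)``
with ``||v|| = slope = bias``.  At each bifurcation the growth cone
senses the gradient noisily — ``z = ||v|| + U(0,1) * (1 - ||v||)``,
i.e. exactly ``z ~ U[bias, 1]`` — and allocates the larger resource
share to the daughter whose direction encloses the smaller angle with
the gradient.  Daughter directions are the parent direction rotated by
+/-30 degrees about a random axis orthogonal to it, giving exactly 60
degrees between daughters.

Because the split fraction has the same distribution and the share
assignment only relabels two exchangeable daughters, every length and
topology statistic of the spatial model matches the abstract generator
at the same parameters; the embedding adds geometry only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidFieldError, ZeroVectorError
from .generator import (
    DEFAULT_EVENT_CAP,
    GrowthParams,
    generate_dataset,
    generate_floret,
)
from .morphology import Floret

__all__ = [
    "GradientField",
    "noisy_bias",
    "branch_directions",
    "generate_spatial",
    "generate_spatial_dataset",
    "validate_geometry",
]

BRANCH_HALF_ANGLE = np.deg2rad(30.0)


@dataclass(frozen=True)
class GradientField:
    """Linear concentration field along +z with gradient norm ``slope``."""

    slope: float

    def __post_init__(self) -> None:
        if not 0.5 < self.slope < 1.0:
            raise InvalidFieldError("slope must be in (0.5, 1)")

    @property
    def vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.slope])

    @property
    def norm(self) -> float:
        return self.slope


def noisy_bias(field: GradientField, rng: np.random.Generator) -> float:
    """Noisy gradient-norm readout: uniform on ``[||v||, 1]``."""
    if not isinstance(field, GradientField):
        raise InvalidFieldError("field must be a GradientField")
    return field.norm + float(rng.random()) * (1.0 - field.norm)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ZeroVectorError("zero direction vector")
    return v / n


def branch_directions(
    parent_dir: np.ndarray,
    rng: np.random.Generator,
    half_angle: float = BRANCH_HALF_ANGLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit daughter directions at +/-``half_angle`` from the parent.

    The rotation axis is drawn uniformly among directions orthogonal to
    the parent, so the daughters subtend ``2 * half_angle`` (60 degrees
    by default) exactly, in a uniformly random plane containing the
    parent direction.
    """
    d = _unit(np.asarray(parent_dir, dtype=float))
    # random unit vector orthogonal to d (Gram-Schmidt on a Gaussian draw)
    while True:
        raw = rng.standard_normal(3)
        axis = raw - np.dot(raw, d) * d
        norm = np.linalg.norm(axis)
        if norm > 1e-12:
            axis /= norm
            break
    # Rodrigues rotation of d about axis by +/- half_angle; axis _|_ d
    # so the formula collapses to cos/sin components
    cross = np.cross(axis, d)
    d1 = np.cos(half_angle) * d + np.sin(half_angle) * cross
    d2 = np.cos(half_angle) * d - np.sin(half_angle) * cross
    return d1, d2


class _GradientPolicy:
    """Growth policy: gradient-noise split, up-gradient larger share."""

    def __init__(self, field: GradientField):
        self.field = field

    def root_state(self):
        return np.zeros(3), np.array([0.0, 0.0, 1.0])

    def draw_z(self, params: GrowthParams, rng) -> float:
        return noisy_bias(self.field, rng)

    def branch_states(self, state, length, rng):
        origin, direction = state
        tip = origin + direction * length
        d1, d2 = branch_directions(direction, rng)
        a1 = float(np.dot(d1, self.field.vector))
        a2 = float(np.dot(d2, self.field.vector))
        if a1 == a2:  # tie: random assignment
            if rng.random() < 0.5:
                d1, d2 = d2, d1
        elif a1 < a2:
            d1, d2 = d2, d1
        # d1 now encloses the smaller angle with the gradient -> larger share
        return (tip, d1), (tip, d2)

    def larger_first(self, state_l, state_s, rng) -> bool:
        return bool(rng.random() < 0.5)


def generate_spatial(
    params: GrowthParams,
    field: GradientField | None = None,
    rng: np.random.Generator | int | None = None,
    cap: int = DEFAULT_EVENT_CAP,
) -> Floret | None:
    """Grow one spatially embedded floret (``None`` if it retracted away).

    The field defaults to ``GradientField(params.bias)`` so the spatial
    run is the exact re-parameterization of the abstract one.  The
    returned floret carries per-segment polylines in ``coords``.
    """
    field = field or GradientField(params.bias)
    floret = generate_floret(params, rng, policy=_GradientPolicy(field), cap=cap)
    if floret is not None:
        floret.meta["field_slope"] = field.slope
    return floret


def generate_spatial_dataset(
    params: GrowthParams,
    n_florets: int,
    seed: int | None = None,
    field: GradientField | None = None,
    cap: int = DEFAULT_EVENT_CAP,
) -> list[Floret]:
    """Grow ``n_florets`` spatially embedded florets."""
    field = field or GradientField(params.bias)
    florets = generate_dataset(
        params, n_florets, seed=seed, policy=_GradientPolicy(field), cap=cap
    )
    for f in florets:
        f.meta["field_slope"] = field.slope
    return florets


def validate_geometry(floret: Floret, atol: float = 1e-6) -> bool:
    """Check polyline arc lengths equal segment lengths within ``atol``."""
    if floret.coords is None:
        raise InvalidFieldError("floret carries no coordinates")
    for seg in floret:
        pts = floret.coords[seg.id]
        arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if abs(arc - seg.length) > atol:
            return False
    return True
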