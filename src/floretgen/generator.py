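"""The floret-generator: a resource-budgeted stochastic growth model.

Each floret starts with a resource budget ``r`` drawn from a gamma
distribution (an abstract proxy for tubulin supply delivered to the
growth cone).  A new branch first elongates by a fixed offset ``os``
(the minimal length contributed by basic building blocks) and pays one
resource unit.  While ``r >= 1`` the growth cone then repeatedly:

* with probability ``p_growth`` elongates the current segment by a
  gamma-distributed length and pays one resource unit;
* otherwise, with probability ``p_retract``, shortens the segment by a
  gamma-distributed length (retraction is free — it does not return or
  consume resource); if the remaining length falls below 1 um the
  segment is removed and that growth cone dies;
* otherwise it bifurcates: a split fraction ``z ~ U[bias, 1]`` allocates
  ``r_f = 1 + (1 - z)(r - 2)`` and ``r_s = 1 + z(r - 2)`` to the two
  daughters (``r_f + r_s = r`` exactly); both daughters recurse as new
  branches if both shares exceed 1, else the segment terminates as a tip.

Which daughter receives the larger share ``r_s`` is a fair coin flip
here; the spatial embedding (:mod:`floretgen.spatial`) replaces both the
``z`` draw and this choice with a gradient rule, without changing the
distribution of any length/topology statistic.

When a pruned (retracted-away) segment leaves its parent with a single
child, the surviving child is merged into the parent (lengths summed) so
the finished tree is strictly binary — equivalently: a segment is the
stretch between branch points, and removing a branch point's sibling
removes the branch point.  Florets whose root retracts away entirely are
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidParamsError, IterationCapError
from .morphology import Floret, Segment

__all__ = [
    "GrowthParams",
    "OPTIMIZED_PARAMS",
    "NO_RETRACTION_PARAMS",
    "PARAM_BOUNDS",
    "generate_floret",
    "generate_dataset",
]


@dataclass(frozen=True)
class GrowthParams:
    """The ten free parameters of the floret-generator.

    Gamma distributions are parametrized as (shape, scale), mean =
    shape * scale.  Lengths in um; resource in abstract units.
    """

    g_shape: float = 1.26    #: elongation length gamma shape
    g_scale: float = 21.18   #: elongation length gamma scale (um)
    r_shape: float = 1.69    #: retraction length gamma shape
    r_scale: float = 17.82   #: retraction length gamma scale (um)
    rs_shape: float = 14.99  #: initial resource gamma shape
    rs_scale: float = 11.29  #: initial resource gamma scale
    p_growth: float = 0.11   #: per-step probability of elongation
    p_retract: float = 0.58  #: probability of retraction given no growth
    bias: float = 0.63       #: lower bound of the resource split fraction
    offset: float = 1.76     #: mandatory initial elongation of a branch (um)

    def __post_init__(self) -> None:
        for name in ("g_shape", "g_scale", "r_shape", "r_scale",
                     "rs_shape", "rs_scale"):
            if getattr(self, name) <= 0:
                raise InvalidParamsError(f"{name} must be > 0")
        for name in ("p_growth", "p_retract"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidParamsError(f"{name} must be in [0, 1]")
        if not 0.5 <= self.bias <= 1.0:
            raise InvalidParamsError("bias must be in [0.5, 1]")
        if not 1.0 <= self.offset <= 2.0:
            raise InvalidParamsError("offset must be in [1, 2] um")

    _FIELDS = ("g_shape", "g_scale", "r_shape", "r_scale", "rs_shape",
               "rs_scale", "p_growth", "p_retract", "bias", "offset")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        return cls(**{k: float(d[k]) for k in cls._FIELDS})

    @classmethod
    def from_vector(cls, v) -> "GrowthParams":
        return cls(**dict(zip(cls._FIELDS, (float(x) for x in v))))

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._FIELDS])


#: Calibrated defaults (genetic-algorithm optimum for the cat
#: thalamocortical floret dataset).
OPTIMIZED_PARAMS = GrowthParams()

#: Retraction-free variant of the calibrated parameter set.
NO_RETRACTION_PARAMS = replace(OPTIMIZED_PARAMS, p_retract=0.0)

#: Optimization ranges per parameter (lower bounds of shapes/scales set
#: slightly above zero so the gamma distributions stay proper).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "g_shape": (1e-3, 100.0),
    "g_scale": (1e-3, 100.0),
    "r_shape": (1e-3, 100.0),
    "r_scale": (1e-3, 100.0),
    "rs_shape": (1e-3, 20.0),
    "rs_scale": (1e-3, 20.0),
    "p_growth": (0.0, 1.0),
    "p_retract": (0.0, 1.0),
    "bias": (0.5, 1.0),
    "offset": (1.0, 2.0),
}

#: Guard against non-terminating parameter sets.
DEFAULT_EVENT_CAP = 1_000_000


class _AbstractPolicy:
    """Default (non-spatial) branching policy.

    A policy supplies the split fraction ``z`` and, for spatial models,
    per-branch growth states ``(origin, direction)``.  The abstract
    policy has no geometry and assigns the larger resource share by a
    fair coin.
    """

    def root_state(self):
        return None

    def draw_z(self, params: GrowthParams, rng: np.random.Generator) -> float:
        return float(rng.uniform(params.bias, 1.0))

    def branch_states(self, state, length, rng):
        # (state_for_larger_share, state_for_smaller_share)
        return None, None

    def larger_first(self, state_l, state_s, rng) -> bool:
        # creation order of the two daughters
        return bool(rng.random() < 0.5)


@dataclass
class _Node:
    length: float
    parent: Optional[int]
    children: list = field(default_factory=list)
    pruned: bool = False
    absorbed: bool = False
    state: object = None          # spatial policy state (direction, origin)
    geometry: list = field(default_factory=list)  # (origin, direction, length)


def _simulate_nodes(params, rng, policy, cap):
    """One growth attempt; returns (nodes, root_index, events, splits)."""
    events = {"growth": 0, "retraction": 0, "bifurcation": 0, "prune": 0}
    splits: list[tuple[float, float, float]] = []
    nodes: list[_Node] = []
    n_events = 0

    r0 = float(rng.gamma(params.rs_shape) * params.rs_scale)
    stack = [(None, r0, policy.root_state())]
    while stack:
        parent, r, state = stack.pop()
        idx = len(nodes)
        node = _Node(length=params.offset, parent=parent, state=state)
        nodes.append(node)
        if parent is not None:
            nodes[parent].children.append(idx)
        r -= 1.0
        while r >= 1.0:
            n_events += 1
            if n_events > cap:
                raise IterationCapError(
                    f"floret exceeded {cap} growth events; "
                    "parameters are likely non-terminating"
                )
            if rng.random() <= params.p_growth:
                node.length += float(rng.gamma(params.g_shape) * params.g_scale)
                r -= 1.0
                events["growth"] += 1
            elif rng.random() < params.p_retract:
                node.length -= float(rng.gamma(params.r_shape) * params.r_scale)
                events["retraction"] += 1
                if node.length < 1.0:
                    node.pruned = True
                    events["prune"] += 1
                    break
            else:
                events["bifurcation"] += 1
                z = policy.draw_z(params, rng)
                r_f = 1.0 + (1.0 - z) * (r - 2.0)
                r_s = 1.0 + z * (r - 2.0)
                splits.append((r, r_f, r_s))
                if r_f > 1.0 and r_s > 1.0:
                    state_l, state_s = policy.branch_states(
                        node.state, node.length, rng
                    )
                    if policy.larger_first(state_l, state_s, rng):
                        stack.append((idx, r_f, state_s))
                        stack.append((idx, r_s, state_l))
                    else:
                        stack.append((idx, r_s, state_l))
                        stack.append((idx, r_f, state_s))
                break
        if not node.pruned and node.state is not None:
            origin, direction = node.state
            node.geometry = [(origin, direction, node.length)]

    # merge pass: children were created after their parent, so walking
    # in reverse creation order resolves grandchildren before parents
    for i in range(len(nodes) - 1, -1, -1):
        node = nodes[i]
        if node.pruned or node.absorbed:
            continue
        live = [c for c in node.children if not nodes[c].pruned]
        if node.children and len(live) == 1:
            child = nodes[live[0]]
            node.length += child.length
            node.geometry = node.geometry + child.geometry
            node.children = child.children
            child.absorbed = True
        else:
            node.children = live

    root = 0
    if nodes[root].pruned:
        return None, events, splits
    return (nodes, root), events, splits


def _to_floret(nodes, root, meta, policy=None) -> Floret:
    segments: list[Segment] = []
    coords: dict[int, np.ndarray] | None = None
    ids: dict[int, int] = {}
    stack = [(root, None)]
    while stack:
        idx, parent_sid = stack.pop()
        sid = len(segments) + 1
        ids[idx] = sid
        segments.append(Segment(sid, parent_sid, nodes[idx].length))
        for child in reversed(nodes[idx].children):
            stack.append((child, sid))
    if any(n.geometry for n in nodes):
        coords = {}
        for idx, sid in ids.items():
            pieces = nodes[idx].geometry
            if not pieces:
                continue
            pts = [pieces[0][0]]
            for origin, direction, length in pieces:
                pts.append(origin + direction * length)
            coords[sid] = np.array(pts)
    return Floret(segments, meta=meta, coords=coords)


def generate_floret(
    params: GrowthParams,
    rng: np.random.Generator | int | None = None,
    policy=None,
    cap: int = DEFAULT_EVENT_CAP,
) -> Optional[Floret]:
    """Grow a single floret; ``None`` if the root retracted away.

    ``rng`` may be a :class:`numpy.random.Generator` or a seed.  The
    floret's ``meta`` records event counts and the resource triples
    ``(r, r_f, r_s)`` of every bifurcation.
    """
    if not isinstance(params, GrowthParams):
        raise InvalidParamsError("params must be a GrowthParams")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    policy = policy or _AbstractPolicy()
    result, events, splits = _simulate_nodes(params, rng, policy, cap)
    if result is None:
        return None
    nodes, root = result
    meta = {"params": params.to_dict(), "events": events, "splits": splits}
    return _to_floret(nodes, root, meta)


def generate_dataset(
    params: GrowthParams,
    n_florets: int,
    seed: int | None = None,
    policy=None,
    cap: int = DEFAULT_EVENT_CAP,
) -> list[Floret]:
    """Grow ``n_florets`` non-empty florets.

    One independent random stream per floret, derived from the master
    seed, so datasets are reproducible and florets independent.  Empty
    outcomes (root retracted away) are resampled within the floret's own
    stream; the number of attempts is recorded in ``meta``.
    """
    if n_florets < 1:
        raise InvalidParamsError("n_florets must be >= 1")
    florets: list[Floret] = []
    streams = np.random.SeedSequence(seed).spawn(n_florets)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        attempts = 1
        floret = generate_floret(params, rng, policy=policy, cap=cap)
        while floret is None:
            attempts += 1
            floret = generate_floret(params, rng, policy=policy, cap=cap)
        floret.meta.update(index=i, attempts=attempts, master_seed=seed)
        florets.append(floret)
    return florets
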