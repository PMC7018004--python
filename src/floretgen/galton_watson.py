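"""Galton-Watson baseline growth model.

The classical comparison model for neurite growth: at each step a
growth cone either elongates by a fixed step length (probability
``p_growth``), bifurcates (``p_branch``) or halts
(``1 - p_growth - p_branch``), all probabilities constant throughout.
Per-segment lengths are therefore ``step_length`` times a geometric
count of consecutive growth events — an exponential-like distribution,
which is the model's structural failure mode against the log-normal
lengths of real floret data.

Subcriticality ``2 p_branch + p_growth < 1`` guarantees finite trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParamsError, IterationCapError, SupercriticalError
from .morphology import Floret, Segment

__all__ = ["GWParams", "GW_OPTIMIZED", "gw_generate", "gw_generate_dataset"]


@dataclass(frozen=True)
class GWParams:
    p_growth: float = 0.98    #: per-step elongation probability
    p_branch: float = 0.0031  #: per-step bifurcation probability
    step_length: float = 1.0  #: elongation per growth event, um

    def __post_init__(self) -> None:
        if self.p_growth < 0 or self.p_branch < 0:
            raise InvalidParamsError("probabilities must be non-negative")
        if self.p_growth + self.p_branch > 1:
            raise InvalidParamsError("p_growth + p_branch must be <= 1")
        if 2 * self.p_branch + self.p_growth >= 1:
            raise SupercriticalError(
                "need 2*p_branch + p_growth < 1 to prevent infinite growth"
            )
        if self.step_length <= 0:
            raise InvalidParamsError("step_length must be > 0")

    @property
    def p_halt(self) -> float:
        return 1.0 - self.p_growth - self.p_branch


#: Calibrated values for the cat thalamocortical floret dataset.
GW_OPTIMIZED = GWParams()


def gw_generate(
    params: GWParams,
    rng: np.random.Generator | int | None = None,
    cap: int = 100_000,
) -> Floret:
    """Grow one Galton-Watson floret.

    Segment lengths may be 0 (a tip that bifurcates or halts before any
    growth event); such florets fail the 1-um finalizer but are returned
    as-is, matching the model's definition.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # Segment-wise sampling via the geometric equivalence of the
    # per-step trinomial scheme: the number of consecutive growth events
    # is geometric with success probability 1 - p_growth, after which
    # the segment branches with probability p_branch / (p_branch +
    # p_halt).  Identical in distribution to stepping one event at a
    # time, at a fraction of the cost.
    p_stop = params.p_branch + params.p_halt  # > 0 under subcriticality
    p_branch_given_stop = params.p_branch / p_stop
    segments: list[Segment] = []
    stack: list[int | None] = [None]
    while stack:
        parent = stack.pop()
        sid = len(segments) + 1
        if sid > cap:
            raise IterationCapError(f"exceeded {cap} segments")
        steps = int(rng.geometric(p_stop)) - 1
        if rng.random() < p_branch_given_stop:
            stack.append(sid)
            stack.append(sid)
        segments.append(Segment(sid, parent, steps * params.step_length))
    return Floret(segments, meta={"model": "galton_watson",
                                  "params": params.__dict__.copy()})


def gw_generate_dataset(
    params: GWParams,
    n_florets: int,
    seed: int | None = None,
    cap: int = 100_000,
) -> list[Floret]:
    """Grow ``n_florets`` independent Galton-Watson florets."""
    if n_florets < 1:
        raise InvalidParamsError("n_florets must be >= 1")
    out = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_florets)):
        floret = gw_generate(params, np.random.default_rng(ss), cap=cap)
        floret.meta.update(index=i, master_seed=seed)
        out.append(floret)
    return out
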