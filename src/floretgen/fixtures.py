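"""Deterministic fixture florets and synthetic reference samples.

Used by the test suite and the documentation examples; every object here
is constructed programmatically, so nothing external is required.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .generator import OPTIMIZED_PARAMS, GrowthParams, generate_dataset
from .morphology import Floret, build_floret, write_segment_table, write_swc

__all__ = [
    "make_fixtures",
    "caterpillar",
    "perfect_tree",
    "write_fixtures",
    "table3_dataset",
    "reference_length_sample",
]

#: Parameters of the synthetic reference length distribution: a shifted
#: log-normal matching the fit reported for pooled biological floret
#: segment lengths.
REFERENCE_LOGNORMAL = dict(gamma=-2.9157, mu=3.52, sigma=1.03)


def caterpillar(n_terminals: int, length: float = 1.0) -> Floret:
    """Maximally asymmetric tree: every bifurcation splits 1 vs rest."""
    if n_terminals < 1:
        raise ValueError("need at least one terminal")
    rows: list[tuple[int, int | None, float]] = [(1, None, length)]
    spine = 1
    next_id = 2
    for _ in range(n_terminals - 1):
        rows.append((next_id, spine, length))      # terminal leaf
        rows.append((next_id + 1, spine, length))  # continues the spine
        spine = next_id + 1
        next_id += 2
    return build_floret(rows, meta={"name": f"caterpillar{n_terminals}"})


def perfect_tree(depth: int, length: float = 1.0) -> Floret:
    """Perfectly balanced binary tree of the given depth, equal lengths."""
    rows: list[tuple[int, int | None, float]] = [(1, None, length)]
    frontier = [1]
    next_id = 2
    for _ in range(depth - 1):
        new_frontier = []
        for parent in frontier:
            for _ in range(2):
                rows.append((next_id, parent, length))
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return build_floret(rows, meta={"name": f"perfect{depth}"})


def make_fixtures() -> dict[str, Floret]:
    """Named worked-example florets.

    * ``trivial``: one segment of 10 um.
    * ``y3``: the smallest non-trivial tree (lengths 10, 5, 7).
    * ``asym5``: 5 segments — root (len 2) with a terminal child of len 4
      and an internal child of len 1 whose two terminals have len 1;
      its length-weighted asymmetry is 0.4 while its partition asymmetry
      is 0.5.
    * ``equal5``: same topology with all lengths 1 (both indices 0.5).
    * ``perfect7``: balanced 7-segment tree, equal lengths (asymmetry 0).
    * ``caterpillar7``: 4-terminal caterpillar (partition asymmetry 2/3,
      the maximum for its size).
    """
    asym5_rows = [(1, None, 2.0), (2, 1, 4.0), (3, 1, 1.0),
                  (4, 3, 1.0), (5, 3, 1.0)]
    equal5_rows = [(i, p, 1.0) for i, p, _ in asym5_rows]
    return {
        "trivial": build_floret([(1, None, 10.0)], meta={"name": "trivial"}),
        "y3": build_floret(
            [(1, None, 10.0), (2, 1, 5.0), (3, 1, 7.0)], meta={"name": "y3"}
        ),
        "asym5": build_floret(asym5_rows, meta={"name": "asym5"}),
        "equal5": build_floret(equal5_rows, meta={"name": "equal5"}),
        "perfect7": perfect_tree(3),
        "caterpillar7": caterpillar(4),
    }


def write_fixtures(outdir: str | Path) -> dict[str, Floret]:
    """Write every fixture as SWC + segment-table CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures = make_fixtures()
    for name, floret in fixtures.items():
        write_swc([floret], outdir / f"{name}.swc")
        write_segment_table([floret], outdir / f"{name}.csv")
    return fixtures


def table3_dataset(
    n_florets: int = 500,
    seed: int = 0,
    params: GrowthParams = OPTIMIZED_PARAMS,
):
    """A seeded dataset at the calibrated parameter set."""
    return generate_dataset(params, n_florets, seed=seed)


def reference_length_sample(
    n: int = 2059,
    seed: int = 0,
    gamma: float = REFERENCE_LOGNORMAL["gamma"],
    mu: float = REFERENCE_LOGNORMAL["mu"],
    sigma: float = REFERENCE_LOGNORMAL["sigma"],
    floor: float = 1.0,
) -> np.ndarray:
    """Synthetic pooled segment-length sample (shifted log-normal).

    A stand-in for a measured pooled length sample: values are drawn
    from ``gamma + exp(N(mu, sigma))`` and redrawn while below ``floor``
    (the 1-um measurement floor applied to reconstructed data; about 2%
    of the mass).
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = gamma + np.exp(rng.normal(mu, sigma, size=n))
        draw = draw[draw >= floor]
        take = min(n - filled, draw.size)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out
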