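"""Morphometric indicators for florets.

Individual (per-floret) indicators: segment count, mean/SD of segment
lengths and log-lengths, mean and maximal depth, and two asymmetry
indices in [0, 1]:

* the classical partition (Van Pelt / Colless) asymmetry, built from the
  terminal counts of the two sub-trees at each branch point, and
* a length-weighted asymmetry that additionally weights each sub-tree's
  terminal count by its mean segment length, so that two sub-trees with
  equal branch counts but very different segment lengths register as
  asymmetric.

For a bifurcating segment whose child sub-trees have terminal counts
``t_l``, ``t_r`` and mean segment lengths ``w_l``, ``w_r``:

    A_p  = |t_r - t_l| / (t_r + t_l - 2)
    A_pw = 2 |w_r t_r - w_l t_l| / [(t_r + t_l - 2) (w_r + w_l)]

both defined as 0 when ``t_r + t_l <= 2`` (a cherry of two terminals).
The floret-level index is the mean over all ``(n-1)/2`` internal
segments; a trivial floret scores 0.  With identical segment lengths
``A_pw`` reduces exactly to ``A_p``.  ``A_pw`` as written can exceed 1
for extreme weight ratios at small cherries; it is clamped at 1 (and the
clamp counted) to preserve the stated [0, 1] codomain.

Dataset-level ("global") statistics pool segment lengths over all
florets and summarize indicator distributions over all, non-trivial
("NT") and trivial ("T") florets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError
from .morphology import Floret

__all__ = [
    "IndividualStats",
    "DatasetStats",
    "van_pelt_asymmetry",
    "length_weighted_asymmetry",
    "partition_asymmetries",
    "individual_stats",
    "dataset_stats",
]

logger = logging.getLogger(__name__)


def _subtree_tables(f: Floret):
    """Terminal count, segment count and total length per sub-floret."""
    order = f.preorder()
    t: dict[int, int] = {}
    n: dict[int, int] = {}
    total: dict[int, float] = {}
    for sid in reversed(order):
        kids = f.children(sid)
        seg = f.segment(sid)
        if not kids:
            t[sid], n[sid], total[sid] = 1, 1, seg.length
        else:
            t[sid] = sum(t[k] for k in kids)
            n[sid] = 1 + sum(n[k] for k in kids)
            total[sid] = seg.length + sum(total[k] for k in kids)
    return t, n, total


def _partition_values(f: Floret) -> tuple[list[float], list[float], list[bool]]:
    """Per-branch-point (A_p, A_pw) values and per-value clamp flags.

    Fast core shared by the asymmetry indices and the per-floret stats;
    see the module docstring for the formulas and conventions.
    """
    t, n, total = _subtree_tables(f)
    aps: list[float] = []
    apws: list[float] = []
    clamped: list[bool] = []
    for sid in f.preorder():
        kids = f.children(sid)
        if not kids:
            continue
        left, right = kids
        tl, tr = t[left], t[right]
        if tl + tr <= 2:
            aps.append(0.0)
            apws.append(0.0)
            clamped.append(False)
            continue
        wl = total[left] / n[left]
        wr = total[right] / n[right]
        ap = abs(tr - tl) / (tr + tl - 2)
        aps.append(ap)
        if wl + wr == 0.0:
            # zero mean lengths on both sides (possible for unit-step
            # baselines mid-simulation): equal-weight limit = A_p
            apws.append(ap)
            clamped.append(False)
            continue
        apw = 2.0 * abs(wr * tr - wl * tl) / ((tr + tl - 2) * (wr + wl))
        clamped.append(apw > 1.0)
        if apw > 1.0:
            apw = 1.0
        apws.append(apw)
    return aps, apws, clamped


def partition_asymmetries(f: Floret) -> pd.DataFrame:
    """Per-branch-point partition asymmetries.

    Returns one row per internal segment with columns ``segment_id``,
    ``t_left``, ``t_right``, ``a_p`` (topological) and ``a_pw``
    (length-weighted, clamped at 1) plus ``clamped``.
    """
    t, n, total = _subtree_tables(f)
    aps, apws, clamps = _partition_values(f)
    internal = [sid for sid in f.preorder() if f.children(sid)]
    rows = []
    for sid, ap, apw, cl in zip(internal, aps, apws, clamps):
        left, right = f.children(sid)
        rows.append(
            dict(segment_id=sid, t_left=t[left], t_right=t[right],
                 a_p=ap, a_pw=apw, clamped=cl)
        )
    return pd.DataFrame(
        rows, columns=["segment_id", "t_left", "t_right", "a_p", "a_pw", "clamped"]
    )


def van_pelt_asymmetry(f: Floret) -> float:
    """Mean partition asymmetry over internal sub-florets; 0 if trivial."""
    aps, _, _ = _partition_values(f)
    return sum(aps) / len(aps) if aps else 0.0


def length_weighted_asymmetry(f: Floret) -> float:
    """Mean length-weighted partition asymmetry; 0 if trivial."""
    _, apws, clamps = _partition_values(f)
    if any(clamps):
        logger.debug(
            "length_weighted_asymmetry: clamped %d partition value(s) at 1.0",
            sum(clamps),
        )
    return sum(apws) / len(apws) if apws else 0.0


@dataclass(frozen=True)
class IndividualStats:
    """Per-floret indicator values (lengths in um, logs natural)."""

    n_segments: int
    n_terminals: int
    total_len: float
    mean_len: float
    sd_len: float
    mean_loglen: float
    sd_loglen: float
    van_pelt_asymmetry: float
    length_weighted_asymmetry: float
    mean_depth: float
    max_depth: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _sd(values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator); 0 for n == 1."""
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def individual_stats(f: Floret) -> IndividualStats:
    lens = f.lengths
    depth_vals = np.array(list(f.depths().values()))
    logs = np.log(lens) if np.all(lens > 0) else np.full_like(lens, np.nan)
    aps, apws, _ = _partition_values(f)
    vp = sum(aps) / len(aps) if aps else 0.0
    aw = sum(apws) / len(apws) if apws else 0.0
    return IndividualStats(
        n_segments=f.n_segments,
        n_terminals=f.n_terminals,
        total_len=float(lens.sum()),
        mean_len=float(lens.mean()),
        sd_len=_sd(lens),
        mean_loglen=float(np.mean(logs)),
        sd_loglen=_sd(logs),
        van_pelt_asymmetry=vp,
        length_weighted_asymmetry=aw,
        mean_depth=float(depth_vals.mean()),
        max_depth=int(depth_vals.max()),
    )


@dataclass
class DatasetStats:
    """Global statistics of a floret dataset.

    ``per_floret`` holds one :class:`IndividualStats` row per floret;
    ``pooled_lengths`` is the concatenation of all segment lengths;
    ``summary`` mirrors the usual summary-table rows, with ``_nt`` /
    ``_t`` suffixes restricting to non-trivial / trivial florets.
    """

    per_floret: pd.DataFrame
    pooled_lengths: np.ndarray
    summary: dict = field(default_factory=dict)

    @property
    def n_florets(self) -> int:
        return len(self.per_floret)

    @property
    def n_trivial(self) -> int:
        return int((self.per_floret["n_segments"] == 1).sum())


def dataset_stats(florets: list[Floret]) -> DatasetStats:
    """Individual and pooled statistics for a dataset of florets.

    Length rows of the summary pool segments (``mean_length`` is the
    mean over all segments of the dataset); depth, SD and asymmetry rows
    average per-floret values, with trivial florets contributing depth 1,
    asymmetry 0 and SD 0.
    """
    if not florets:
        raise EmptyDatasetError("dataset_stats needs at least one floret")
    per = pd.DataFrame.from_records(
        [individual_stats(f).as_dict() for f in florets]
    )
    pooled = np.concatenate([f.lengths for f in florets])
    nt = per["n_segments"] > 1
    tv = ~nt

    def seg_weighted_mean(mask) -> float:
        sub = per[mask]
        if sub["n_segments"].sum() == 0:
            return float("nan")
        return float(sub["total_len"].sum() / sub["n_segments"].sum())

    summary = {
        "n_florets": int(len(per)),
        "n_trivial": int(tv.sum()),
        "n_segments": int(per["n_segments"].sum()),
        "trivial_fraction": float(tv.mean()),
        "mean_n_segments_nt": float(per.loc[nt, "n_segments"].mean()) if nt.any() else float("nan"),
        "mean_length": float(pooled.mean()),
        "mean_length_nt": seg_weighted_mean(nt),
        "mean_length_t": seg_weighted_mean(tv),
        "mean_sd_length": float(per["sd_len"].mean()),
        "mean_sd_length_nt": float(per.loc[nt, "sd_len"].mean()) if nt.any() else float("nan"),
        "mean_depth": float(per["mean_depth"].mean()),
        "mean_depth_nt": float(per.loc[nt, "mean_depth"].mean()) if nt.any() else float("nan"),
        "mean_vp_asymmetry": float(per["van_pelt_asymmetry"].mean()),
        "mean_vp_asymmetry_nt": float(per.loc[nt, "van_pelt_asymmetry"].mean()) if nt.any() else float("nan"),
        "mean_lw_asymmetry": float(per["length_weighted_asymmetry"].mean()),
        "mean_lw_asymmetry_nt": float(per.loc[nt, "length_weighted_asymmetry"].mean()) if nt.any() else float("nan"),
    }
    assert summary["n_segments"] == pooled.size
    return DatasetStats(per_floret=per, pooled_lengths=pooled, summary=summary)
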