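"""Side-by-side comparison of two floret datasets.

Produces the pooled-length Jensen-Shannon divergence, two-sample
Kolmogorov-Smirnov tests on the pooled lengths and on every individual
indicator distribution, and the summary rows of both datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .distfit import js_divergence, ks_two_sample
from .errors import EmptyDatasetError
from .metrics import DatasetStats, dataset_stats
from .morphology import Floret

__all__ = ["ComparisonReport", "compare_datasets", "INDICATORS"]

#: Individual indicators compared distribution-wise (KS) between datasets.
INDICATORS = (
    "mean_len",
    "sd_len",
    "mean_loglen",
    "sd_loglen",
    "n_segments",
    "van_pelt_asymmetry",
    "length_weighted_asymmetry",
    "mean_depth",
    "max_depth",
)


@dataclass
class ComparisonReport:
    js_lengths: float
    ks_lengths: tuple[float, float]            #: (D, p) on pooled lengths
    ks_indicators: dict[str, tuple[float, float]]
    summary: pd.DataFrame                      #: ref/gen summary side by side
    n_ref: int
    n_gen: int
    alpha: float = 0.05

    @property
    def lengths_equal(self) -> bool:
        """KS fails to reject equality of pooled lengths at ``alpha``."""
        return self.ks_lengths[1] > self.alpha

    def to_dict(self) -> dict:
        return dict(
            js_lengths=self.js_lengths,
            ks_lengths=dict(zip(("D", "p"), self.ks_lengths)),
            ks_indicators={
                k: dict(zip(("D", "p"), v)) for k, v in self.ks_indicators.items()
            },
            summary=self.summary.to_dict(orient="index"),
            n_ref=self.n_ref,
            n_gen=self.n_gen,
            alpha=self.alpha,
        )


def _as_stats(data) -> DatasetStats:
    if isinstance(data, DatasetStats):
        return data
    if not data:
        raise EmptyDatasetError("empty dataset")
    return dataset_stats(list(data))


def compare_datasets(
    ref: Sequence[Floret] | DatasetStats,
    gen: Sequence[Floret] | DatasetStats,
    bins: str | int = "fd",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare a reference and a generated dataset.

    Tests are performed at the 5% significance level by default.
    """
    rs = _as_stats(ref)
    gs = _as_stats(gen)
    ks_ind = {
        name: ks_two_sample(rs.per_floret[name], gs.per_floret[name])
        for name in INDICATORS
    }
    summary = pd.DataFrame({"reference": rs.summary, "generated": gs.summary})
    return ComparisonReport(
        js_lengths=js_divergence(rs.pooled_lengths, gs.pooled_lengths, bins=bins),
        ks_lengths=ks_two_sample(rs.pooled_lengths, gs.pooled_lengths),
        ks_indicators=ks_ind,
        summary=summary,
        n_ref=rs.n_florets,
        n_gen=gs.n_florets,
        alpha=alpha,
    )
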