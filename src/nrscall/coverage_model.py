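"""Binomial occupancy model for off-site long-fragment pile-up.

Reconstruction of the claim that barcode-recruited long fragments
rarely stack up in any genomic region other than the insertion site:
the genome is modelled as ``n_bins`` equal non-intersecting regions and
``n_fragments`` fragments land in bins independently and uniformly, so
the count in a fixed bin is Binomial(n_fragments, 1/n_bins). A region
is deemed assemblable once it holds at least ``threshold_m`` fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class FragmentModelParams:
    n_fragments: int
    n_bins: int
    threshold_m: int

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_fragments < 0 or self.threshold_m < 0:
            raise ValueError("counts must be non-negative")


def prob_bin_count_at_least(params: FragmentModelParams) -> float:
    """P[X >= m] for X ~ Binomial(n_fragments, 1/n_bins), stable tail sum."""
    if params.threshold_m == 0:
        return 1.0
    if params.threshold_m > params.n_fragments:
        return 0.0
    return float(
        stats.binom.sf(params.threshold_m - 1, params.n_fragments, 1.0 / params.n_bins)
    )


def expected_max_bin_count(
    params: FragmentModelParams, n_trials: int, seed: int
) -> dict:
    """Monte-Carlo summary of the maximum bin occupancy (seeded)."""
    rng = np.random.default_rng(seed)
    maxima = np.zeros(n_trials, dtype=np.int64)
    if params.n_fragments > 0:
        for t in range(n_trials):
            counts = rng.multinomial(
                params.n_fragments, np.full(params.n_bins, 1.0 / params.n_bins)
            )
            maxima[t] = counts.max()
    frac_ge_m = float(np.mean(maxima >= params.threshold_m))
    return {
        "mean_max": float(maxima.mean()),
        "max_max": int(maxima.max()),
        "frac_any_bin_ge_m": frac_ge_m,
        "n_trials": n_trials,
    }


def probability_table(
    n_fragments_grid: list[int], n_bins_grid: list[int], m_grid: list[int]
) -> list[dict]:
    """Grid of tail probabilities for the CLI table printer."""
    rows = []
    for n in n_fragments_grid:
        for b in n_bins_grid:
            for m in m_grid:
                p = prob_bin_count_at_least(FragmentModelParams(n, b, m))
                rows.append({"n_fragments": n, "n_bins": b, "m": m, "p_ge_m": p})
    return rows
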