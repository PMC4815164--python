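"""Top-k capture and detection statistics over simulation replicates.

*Capture*: a single-variable importance measure places **both** interacting
SNPs in the top k of all SNPs.  *Detection*: a pairwise measure places the
true interacting **pair** in the top k of the evaluated pair set.  A third
criterion tracks whether all marginal-only SNPs (or all their pairs) reach
the top k.  Fractions are proportions of replicates meeting the criterion,
reported over an inclusive k-range.

Ties receive the worst rank in their tie group (competition ranking), so a
criterion is never awarded on a tie; this matters because unused SNPs often
share an exact zero score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RankSummary",
    "rank_items",
    "capture_fraction",
    "detection_fraction",
    "marginal_topk",
]


@dataclass
class RankSummary:
    measure: str
    k_values: np.ndarray  # inclusive integer range
    fractions: np.ndarray  # proportion of replicates meeting the criterion
    n_replicates: int
    criterion: str  # capture_both_snps | detect_true_pair | marginal_topk

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(self.fractions) < 0):
            raise ValueError("fractions must be non-decreasing in k")


def rank_items(
    scores, direction: str = "higher", tie_policy: str = "worst"
) -> np.ndarray:
    """Rank scores (1 = most important); ties take the worst rank in their
    group.  ``direction='lower'`` ranks small scores first; ``'abs'`` ranks
    large magnitudes first."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if tie_policy != "worst":
        raise ValueError("only the worst-rank tie policy is supported")
    if direction == "higher":
        key = -scores
    elif direction == "lower":
        key = scores
    elif direction == "abs":
        key = -np.abs(scores)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return rankdata(key, method="max").astype(int)


def _fractions(worst_ranks: np.ndarray, k_values: np.ndarray) -> np.ndarray:
    return np.array([(worst_ranks <= k).mean() for k in k_values])


def capture_fraction(
    interacting_ranks, k_values=range(2, 11), measure: str = ""
) -> RankSummary:
    """Proportion of replicates in which both interacting SNPs rank in the
    top k, i.e. max(rank1, rank2) <= k, for each k (k >= 2)."""
    k_values = np.asarray(list(k_values), dtype=int)
    if np.any(k_values < 2):
        raise ValueError("capture requires k >= 2 (two SNPs must fit)")
    ranks = np.asarray(interacting_ranks, dtype=int)
    if ranks.ndim != 2 or ranks.shape[1] != 2:
        raise ValueError("expected one (rank1, rank2) pair per replicate")
    worst = ranks.max(axis=1)
    return RankSummary(
        measure=measure,
        k_values=k_values,
        fractions=_fractions(worst, k_values),
        n_replicates=ranks.shape[0],
        criterion="capture_both_snps",
    )


def detection_fraction(
    true_pair_ranks, k_values=range(1, 11), measure: str = ""
) -> RankSummary:
    """Proportion of replicates in which the true interacting pair ranks in
    the top k of the (noise-excluded) pair set."""
    k_values = np.asarray(list(k_values), dtype=int)
    ranks = np.asarray(true_pair_ranks, dtype=int)
    if ranks.ndim != 1:
        raise ValueError("expected one true-pair rank per replicate")
    return RankSummary(
        measure=measure,
        k_values=k_values,
        fractions=_fractions(ranks, k_values),
        n_replicates=ranks.shape[0],
        criterion="detect_true_pair",
    )


def marginal_topk(
    tracked_ranks, k_values, criterion: str = "marginal_topk", measure: str = ""
) -> RankSummary:
    """Proportion of replicates in which *all* tracked items (marginal-only
    SNPs, or all their pairs) rank in the top k."""
    k_values = np.asarray(list(k_values), dtype=int)
    ranks = np.asarray(tracked_ranks, dtype=int)
    if ranks.ndim != 2 or ranks.shape[1] == 0:
        raise ValueError("expected a replicate x tracked-items rank matrix")
    worst = ranks.max(axis=1)
    return RankSummary(
        measure=measure,
        k_values=k_values,
        fractions=_fractions(worst, k_values),
        n_replicates=ranks.shape[0],
        criterion=criterion,
    )
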