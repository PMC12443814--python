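"""Fixed-marginal null models and z-score standardization of network metrics.

The null family is the uniform distribution over nonnegative integer matrices
with the observed row and column totals (the distribution underlying Fisher's
exact test).  Observed metrics are standardized against a seeded ensemble of
draws via z = (obs - mean_null) / sd_null, with empirical tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import InteractionMatrix


@dataclass(frozen=True)
class NullEnsembleResult:
    metric: str
    obs: float
    null_values: np.ndarray
    exp_null: float
    sd_null: float
    z: float  # NaN when sd_null == 0
    p_upper: float  # P(null >= obs), the study's one-sided rule
    p_lower: float  # P(null <= obs)
    p_two: float
    note: str = ""


def sample_fixed_marginals(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    seed: int | np.random.Generator = 0,
) -> InteractionMatrix:
    """Draw one matrix uniformly conditional on both marginal totals.

    Implementation: write each of the m events as a row token and a column
    token, shuffle the row tokens, and pair them positionally with the column
    tokens — equivalent to random bipartite matching, which yields the
    multivariate-hypergeometric (r2dtable) distribution.  Marginals are
    preserved exactly on every draw.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if r.sum() != c.sum():
        raise ValueError(
            f"marginal mismatch: rows sum to {r.sum()}, columns to {c.sum()}"
        )
    if r.sum() <= 0:
        raise ValueError("marginal totals must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row_tokens = np.repeat(np.arange(len(r)), r)
    col_tokens = np.repeat(np.arange(len(c)), c)
    rng.shuffle(row_tokens)
    w = np.zeros((len(r), len(c)), dtype=np.int64)
    np.add.at(w, (row_tokens, col_tokens), 1)
    rows = tuple(f"P{i+1}" for i in range(len(r)))
    cols = tuple(f"B{j+1}" for j in range(len(c)))
    return InteractionMatrix(rows, cols, w)


def null_test(
    matrix: InteractionMatrix,
    metric: Callable[[InteractionMatrix], float],
    n: int = 1000,
    seed: int = 0,
    name: str | None = None,
) -> NullEnsembleResult:
    """Standardize a network metric against the fixed-marginal null ensemble.

    ``p_upper`` follows the upper-tail convention (share of null draws scoring
    at least the observed value); the lower tail and a two-sided summary are
    reported alongside because a metric observed below the null is only
    significant in the lower tail.
    """
    matrix.require_nonempty()
    rng = np.random.default_rng(seed)
    obs = float(metric(matrix))
    r = matrix.row_totals()
    c = matrix.col_totals()
    null_values = np.empty(n)
    for k in range(n):
        null_values[k] = metric(sample_fixed_marginals(r, c, rng))
    exp_null = float(null_values.mean())
    sd_null = float(null_values.std(ddof=0))
    if sd_null > 0:
        z = (obs - exp_null) / sd_null
        note = ""
    else:
        z = float("nan")
        note = "sd_null = 0: metric is constant under the null; z undefined"
    p_upper = float(np.mean(null_values >= obs))
    p_lower = float(np.mean(null_values <= obs))
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return NullEnsembleResult(
        metric=name or getattr(metric, "__name__", "metric"),
        obs=obs,
        null_values=null_values,
        exp_null=exp_null,
        sd_null=sd_null,
        z=z,
        p_upper=p_upper,
        p_lower=p_lower,
        p_two=p_two,
        note=note,
    )


def null_test_suite(
    matrix: InteractionMatrix,
    metrics: Mapping[str, Callable[[InteractionMatrix], float]],
    n: int = 1000,
    seed: int = 0,
) -> dict[str, NullEnsembleResult]:
    """Run :func:`null_test` for several metrics with independent sub-seeds."""
    seeds = np.random.SeedSequence(seed).spawn(len(metrics))
    return {
        key: null_test(matrix, fn, n=n, seed=sub.generate_state(1)[0] % (2**31), name=key)
        for (key, fn), sub in zip(metrics.items(), seeds)
    }
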