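"""Sample-coverage estimation for interactions and species.

Coverage is the estimated probability that the next sampled event belongs to
an already-recorded link (or species), computed from singleton and doubleton
frequencies (Chao's abundance-based estimator).  Values near 1 indicate the
inventory is close to complete at the observed effort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import InteractionMatrix


@dataclass(frozen=True)
class CoverageResult:
    target: str  # 'interactions', 'birds' or 'plants'
    n: int
    f1: int
    f2: int
    C_hat: float


def sample_coverage(abundances: Sequence[int], target: str = "interactions") -> CoverageResult:
    """Estimated sample coverage from an abundance (frequency) vector.

    C_hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2), where n is the total
    count and f1, f2 the numbers of singletons and doubletons; 1 exactly when
    there are no singletons.
    """
    a = np.asarray(abundances, dtype=np.int64)
    if a.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(a < 1):
        raise ValueError("abundances must be positive integers")
    n = int(a.sum())
    f1 = int(np.count_nonzero(a == 1))
    f2 = int(np.count_nonzero(a == 2))
    if f1 == 0:
        c_hat = 1.0
    else:
        denom = (n - 1) * f1 + 2 * f2
        # denom is 0 only when n == 1 (a single singleton): coverage 0
        ratio = (n - 1) * f1 / denom if denom > 0 else 1.0
        c_hat = 1.0 - (f1 / n) * ratio
    return CoverageResult(target=target, n=n, f1=f1, f2=f2, C_hat=float(c_hat))


def network_coverage(matrix: InteractionMatrix) -> dict[str, CoverageResult]:
    """Coverage of links, birds and plants for one interaction matrix.

    Link abundances are the nonzero cell values; species abundances are the
    marginal totals of that species' side.
    """
    matrix.require_nonempty()
    cells = matrix.w[matrix.w > 0]
    return {
        "interactions": sample_coverage(cells, "interactions"),
        "birds": sample_coverage(matrix.col_totals()[matrix.col_totals() > 0], "birds"),
        "plants": sample_coverage(matrix.row_totals()[matrix.row_totals() > 0], "plants"),
    }
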