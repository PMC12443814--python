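"""Network- and species-level metrics for weighted bipartite networks.

Network level: connectance C, weighted nestedness wNODF, standardized
two-dimensional Shannon specialization H2', and Barber bipartite modularity Q.
Species level: degree k, species strength s (sum of partner dependencies), and
standardized Kullback-Leibler specialization d'.

Conventions: plants are rows, birds are columns; all entropies use natural
logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InteractionMatrix


@dataclass(frozen=True)
class H2Result:
    H2: float
    H2max: float
    H2min: float
    H2prime: float


@dataclass(frozen=True)
class ModularityResult:
    Q: float
    #: module id per species, keyed by label; rows and columns share the id space
    partition: dict[str, int]


@dataclass(frozen=True)
class NetworkMetrics:
    """The four network-level metrics plus the modularity partition."""

    connectance: float
    wnodf: float
    h2: H2Result
    modularity: ModularityResult


# ---------------------------------------------------------------------------
# Connectance
# ---------------------------------------------------------------------------


def connectance(matrix: InteractionMatrix) -> float:
    """Realized fraction of possible plant-bird links, L / (A_p * A_b).

    The numerator is the count of distinct observed links (nonzero cells), so
    C lies in [0, 1] with 1 meaning every species pair interacts.
    """
    matrix.require_nonempty()
    return matrix.n_links / (matrix.n_plants * matrix.n_birds)


# ---------------------------------------------------------------------------
# Weighted nestedness (wNODF)
# ---------------------------------------------------------------------------


def _axis_contributions(w: np.ndarray) -> float:
    """Sum of pairwise wNODF contributions over rows of ``w`` (sorted)."""
    totals = w.sum(axis=1)
    n = w.shape[0]
    acc = 0.0
    for u in range(n):
        for v in range(u + 1, n):
            if totals[v] >= totals[u]:
                continue
            filled = w[v] > 0
            nv = int(filled.sum())
            if nv == 0:
                continue
            overlap = int(np.count_nonzero(filled & (w[v] < w[u])))
            acc += 100.0 * overlap / nv
    return acc


def wnodf(matrix: InteractionMatrix) -> float:
    """Weighted nestedness based on overlap and decreasing fill, in [0, 100].

    Rows and columns are sorted by decreasing marginal totals (ties broken by
    label, stably).  An ordered pair (u above v) contributes nothing when v's
    total is not strictly smaller than u's; otherwise it contributes the
    percentage of v's filled cells whose value is positive but strictly below
    u's value in the same position.  The score averages contributions over all
    row pairs and column pairs.
    """
    matrix.require_nonempty()
    if matrix.n_plants < 2 or matrix.n_birds < 2:
        raise ValueError("wNODF requires at least 2 rows and 2 columns")
    w = matrix.w.astype(np.int64)

    def sort_order(totals: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
        return np.array(
            sorted(range(len(labels)), key=lambda i: (-totals[i], labels[i]))
        )

    r_ord = sort_order(w.sum(axis=1), matrix.rows)
    c_ord = sort_order(w.sum(axis=0), matrix.cols)
    ws = w[np.ix_(r_ord, c_ord)]

    total = _axis_contributions(ws) + _axis_contributions(ws.T)
    n_p, n_b = matrix.n_plants, matrix.n_birds
    n_pairs = n_p * (n_p - 1) / 2 + n_b * (n_b - 1) / 2
    return total / n_pairs


# ---------------------------------------------------------------------------
# H2' specialization
# ---------------------------------------------------------------------------


def _shannon(w: np.ndarray) -> float:
    p = w[w > 0] / w.sum()
    return float(-(p * np.log(p)).sum())


def _even_fill(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Most-even integer matrix consistent with both marginals.

    Starts from the floor of the independence expectation r_i c_j / m and
    distributes the remaining units by largest fractional remainder among
    cells whose row and column still have a deficit.
    """
    m = int(row_totals.sum())
    expect = np.outer(row_totals, col_totals) / m
    fill = np.floor(expect).astype(np.int64)
    frac = expect - fill
    row_def = row_totals - fill.sum(axis=1)
    col_def = col_totals - fill.sum(axis=0)
    # Deficit repair: each remaining unit goes to the emptiest eligible cell
    # (largest fractional remainder as tie-break), keeping the fill even.
    while row_def.sum() > 0:
        rows = np.where(row_def > 0)[0]
        cols = np.where(col_def > 0)[0]
        best = min(
            ((int(fill[r, c]), -frac[r, c], r, c) for r in rows for c in cols),
        )
        _, _, r, c = best
        fill[r, c] += 1
        frac[r, c] -= 1.0
        row_def[r] -= 1
        col_def[c] -= 1
    return fill


def _concentrated_fill(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Most-concentrated integer matrix consistent with both marginals.

    Greedy: repeatedly pair the largest remaining row total with the largest
    remaining column total and place the smaller of the two.
    """
    r = row_totals.astype(np.int64).copy()
    c = col_totals.astype(np.int64).copy()
    fill = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        amount = min(r[i], c[j])
        fill[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return fill


def h2prime(matrix: InteractionMatrix) -> H2Result:
    """Standardized two-dimensional Shannon specialization H2' in [0, 1].

    H2 is the Shannon entropy of the interaction proportions p_ij = w_ij / m.
    H2max (most-even) and H2min (most-concentrated) are the entropy extremes
    attainable by integer matrices with the observed marginals; H2' rescales
    the observed entropy between them, 1 = maximally specialized.
    """
    matrix.require_nonempty()
    r = matrix.row_totals()
    c = matrix.col_totals()
    h2 = _shannon(matrix.w)
    h2max = _shannon(_even_fill(r, c))
    h2min = _shannon(_concentrated_fill(r, c))
    if h2max <= h2min:
        prime = 0.0
    else:
        prime = float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))
    return H2Result(H2=h2, H2max=h2max, H2min=h2min, H2prime=prime)


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------


def barber_q(matrix: InteractionMatrix, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Evaluate Barber's weighted bipartite modularity for a given partition.

    Q = (1/m) * sum_ij [w_ij - r_i c_j / m] * 1(g_i == g_j), where r and c are
    the marginal totals and g the joint module labels of plants and birds.
    """
    m = matrix.m
    b = matrix.w - np.outer(matrix.row_totals(), matrix.col_totals()) / m
    same = row_labels[:, None] == col_labels[None, :]
    return float(b[same].sum() / m)


def _assign_side(b: np.ndarray, other_labels: np.ndarray, n_modules: int) -> np.ndarray:
    """Give each row of ``b`` the module that maximizes its within-module sum.

    ``b`` is the modularity-matrix slice oriented so that axis 0 is the side
    being relabelled; a node whose best attainable sum is negative gets a fresh
    singleton module (contribution 0).
    """
    gains = np.zeros((b.shape[0], n_modules))
    for g in range(n_modules):
        mask = other_labels == g
        if mask.any():
            gains[:, g] = b[:, mask].sum(axis=1)
    labels = np.argmax(gains, axis=1).astype(np.int64)
    fresh = n_modules
    out = labels.copy()
    for i in range(b.shape[0]):
        if gains[i, labels[i]] < 0:
            out[i] = fresh
            fresh += 1
    return out


def _relabel(row_labels: np.ndarray, col_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    joint = np.concatenate([row_labels, col_labels])
    uniq, inv = np.unique(joint, return_inverse=True)
    return inv[: len(row_labels)], inv[len(row_labels):], len(uniq)


def _merge_stage(
    matrix: InteractionMatrix, row_labels: np.ndarray, col_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exhaustive pairwise module merging until no merge improves Q."""
    m = matrix.m
    b = matrix.w - np.outer(matrix.row_totals(), matrix.col_totals()) / m
    row_labels, col_labels, k = _relabel(row_labels, col_labels)
    # cross[g, h] = sum of b over (row in g, col in h)
    while True:
        cross = np.zeros((k, k))
        for g in range(k):
            rmask = row_labels == g
            if rmask.any():
                for h in range(k):
                    cmask = col_labels == h
                    if cmask.any():
                        cross[g, h] = b[np.ix_(rmask, cmask)].sum()
        # merging g and h adds cross[g, h] + cross[h, g] to the within sum
        gain = cross + cross.T
        np.fill_diagonal(gain, -np.inf)
        g, h = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[g, h] <= 1e-12:
            break
        row_labels = np.where(row_labels == h, g, row_labels)
        col_labels = np.where(col_labels == h, g, col_labels)
        row_labels, col_labels, k = _relabel(row_labels, col_labels)
    q = barber_q(matrix, row_labels, col_labels)
    return row_labels, col_labels, q


def modularity(
    matrix: InteractionMatrix, n_restarts: int = 20, seed: int = 0
) -> ModularityResult:
    """Maximize Barber bipartite weighted modularity.

    Seeded stochastic label propagation (alternating best-module assignment of
    birds and plants from a random initial plant partition) followed by
    exhaustive pairwise module merging; the best of ``n_restarts`` runs is
    returned.  Reproducible for a fixed seed.
    """
    matrix.require_nonempty()
    rng = np.random.default_rng(seed)
    m = matrix.m
    b = matrix.w - np.outer(matrix.row_totals(), matrix.col_totals()) / m
    n_p, n_b = matrix.w.shape

    best_q = -np.inf
    best = None
    for _ in range(max(1, n_restarts)):
        # random initial partition of plants into up to n_p modules
        row_labels = rng.integers(0, n_p, size=n_p).astype(np.int64)
        col_labels = np.zeros(n_b, dtype=np.int64)
        q_prev = -np.inf
        for _ in range(60):
            row_labels, col_labels, k = _relabel(row_labels, col_labels)
            col_labels = _assign_side(b.T, row_labels, k)
            row_labels, col_labels, k = _relabel(row_labels, col_labels)
            row_labels = _assign_side(b, col_labels, k)
            q = barber_q(matrix, row_labels, col_labels)
            if q <= q_prev + 1e-12:
                break
            q_prev = q
        row_labels, col_labels, q = _merge_stage(matrix, row_labels, col_labels)
        if q > best_q:
            best_q = q
            best = (row_labels.copy(), col_labels.copy())

    row_labels, col_labels = best
    if best_q < 1e-12:
        # no structure beyond the marginal-product expectation: single module
        row_labels = np.zeros(n_p, dtype=np.int64)
        col_labels = np.zeros(n_b, dtype=np.int64)
        best_q = max(best_q, barber_q(matrix, row_labels, col_labels))
    row_labels, col_labels, _ = _relabel(row_labels, col_labels)
    partition = {lab: int(g) for lab, g in zip(matrix.rows, row_labels)}
    partition.update({lab: int(g) for lab, g in zip(matrix.cols, col_labels)})
    return ModularityResult(Q=float(best_q), partition=partition)


def network_metrics(
    matrix: InteractionMatrix, n_restarts: int = 20, seed: int = 0
) -> NetworkMetrics:
    """Compute all four network-level metrics."""
    return NetworkMetrics(
        connectance=connectance(matrix),
        wnodf=wnodf(matrix),
        h2=h2prime(matrix),
        modularity=modularity(matrix, n_restarts=n_restarts, seed=seed),
    )


# ---------------------------------------------------------------------------
# Species-level metrics
# ---------------------------------------------------------------------------


def species_degree(matrix: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """Partner counts: (plant degrees, bird degrees)."""
    plant = pd.Series(
        np.count_nonzero(matrix.w, axis=1), index=list(matrix.rows), name="degree"
    )
    bird = pd.Series(
        np.count_nonzero(matrix.w, axis=0), index=list(matrix.cols), name="degree"
    )
    return plant, bird


def species_strength(matrix: InteractionMatrix) -> tuple[pd.Series, pd.Series]:
    """Sum of partner dependencies: (plant strengths, bird strengths).

    A bird's strength is the sum over plants of the fraction of that plant's
    visits it accounts for; bird strengths therefore sum exactly to plant
    richness (and vice versa).
    """
    matrix.require_nonempty()
    w = matrix.w.astype(float)
    r = matrix.row_totals().astype(float)
    c = matrix.col_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dep_on_plant = np.where(r[:, None] > 0, w / r[:, None], 0.0)  # w_ij / r_i
        dep_on_bird = np.where(c[None, :] > 0, w / c[None, :], 0.0)  # w_ij / c_j
    bird = pd.Series(dep_on_plant.sum(axis=0), index=list(matrix.cols), name="strength")
    plant = pd.Series(dep_on_bird.sum(axis=1), index=list(matrix.rows), name="strength")
    return plant, bird


def _largest_remainder_allocation(total: int, weights: np.ndarray) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``."""
    share = total * weights / weights.sum()
    alloc = np.floor(share).astype(np.int64)
    rem = total - alloc.sum()
    if rem > 0:
        order = np.argsort(-(share - alloc), kind="stable")
        alloc[order[:rem]] += 1
    return alloc


def _dprime_one(use: np.ndarray, avail_totals: np.ndarray, m: int) -> tuple[float, float, float, float]:
    """d, d_min, d_max, d' for one species.

    ``use`` is the species' interaction vector, ``avail_totals`` the partner
    marginal totals (availability weights), ``m`` the grand total.
    """
    t = int(use.sum())
    p = use / t
    q = avail_totals / m
    nz = use > 0
    d = float((p[nz] * np.log(p[nz] / q[nz])).sum())
    d_max = float(np.log(m / t))

    def kl(alloc: np.ndarray) -> float:
        pa = alloc[alloc > 0] / t
        return float((pa * np.log(pa / q[alloc > 0])).sum())

    # nearest-to-proportional start, then single-unit exchange descent (the
    # divergence is convex, so this reaches the integer minimum)
    alloc = _largest_remainder_allocation(t, avail_totals.astype(float))
    d_min = kl(alloc)
    improved = True
    while improved:
        improved = False
        for i in np.nonzero(alloc)[0]:
            for j in range(len(alloc)):
                if i == j or q[j] == 0:
                    continue
                alloc[i] -= 1
                alloc[j] += 1
                trial = kl(alloc)
                if trial < d_min - 1e-15:
                    d_min = trial
                    improved = True
                else:
                    alloc[i] += 1
                    alloc[j] -= 1
    if d_max <= d_min:
        prime = 0.0
    else:
        prime = float(np.clip((d - d_min) / (d_max - d_min), 0.0, 1.0))
    return d, d_min, d_max, prime


def dprime(matrix: InteractionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized species-level specialization d' for (plants, birds).

    d is the Kullback-Leibler divergence of the species' partner-use
    distribution from partner availability (marginal proportions); it is
    rescaled between d_min (the closest integer allocation to proportional
    use) and d_max = ln(m / t) where t is the species' total.  Species with no
    interactions are reported as missing.
    """
    matrix.require_nonempty()
    m = matrix.m
    r = matrix.row_totals().astype(float)
    c = matrix.col_totals().astype(float)

    def side(vectors: np.ndarray, avail: np.ndarray, labels: tuple[str, ...]) -> pd.DataFrame:
        out = []
        for i, lab in enumerate(labels):
            use = vectors[i].astype(float)
            if use.sum() == 0:
                out.append((lab, np.nan, np.nan, np.nan, np.nan))
                continue
            d, d_min, d_max, prime = _dprime_one(use, avail, m)
            out.append((lab, d, d_min, d_max, prime))
        return pd.DataFrame(
            out, columns=["species_id", "d", "d_min", "d_max", "dprime"]
        ).set_index("species_id")

    plants = side(matrix.w, c, matrix.rows)
    birds = side(matrix.w.T, r, matrix.cols)
    return plants, birds


def species_metrics(matrix: InteractionMatrix) -> pd.DataFrame:
    """Species-level table: role, degree, strength, d' per species."""
    p_deg, b_deg = species_degree(matrix)
    p_str, b_str = species_strength(matrix)
    p_dp, b_dp = dprime(matrix)
    plants = pd.DataFrame(
        {"role": "plant", "degree": p_deg, "strength": p_str, "dprime": p_dp["dprime"]}
    )
    birds = pd.DataFrame(
        {"role": "bird", "degree": b_deg, "strength": b_str, "dprime": b_dp["dprime"]}
    )
    out = pd.concat([birds, plants])
    out.index.name = "species_id"
    return out
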