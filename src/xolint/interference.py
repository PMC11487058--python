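"""The interference length L_int and its pair-count bookkeeping.

Crossover (CO) interference widens the spacing between COs on the same
chromosome and narrows the distribution of CO counts relative to independent
placement. The interference length summarizes both effects in one number
with units of length:

    L_int = d_int − d_noInt

where ``d_noInt`` is the mean distance between two COs drawn from the pool of
all observed positions (the no-interference null, which keeps the empirical
positional density), and ``d_int`` is a weighted mean over observed and
*missing* CO pairs. A chromosome with N COs carries N(N−1)/2 pairs; under a
Poisson null with the same mean count ⟨N⟩ the expected pair count is ⟨N⟩²/2.
The shortfall — missing pairs — is charged the maximal observable distance,
the chromosome length L. Writing φ = N̄_obs_pair / N̄_noInt_pair, the
operative form is

    L_int = φ·(d_obs − d_noInt) + (1 − φ)·(L − d_noInt).

L_int = 0 without interference, ≈ 2/3·L under complete interference with a
single uniformly placed CO, and at most L. The normalized variant
L_int^norm = L_int·⟨N⟩/L measures the regularity of CO placement and is
comparable across chromosomes and species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ChromosomeDataset, CLASS_I, CLASS_II
from .errors import ClusteringWarning, DegenerateDataError

__all__ = [
    "PairStatistics",
    "InterferenceResult",
    "mean_pairwise_distance",
    "mean_cross_distance",
    "compute_pair_statistics",
    "interference_length",
    "mixed_interference_length",
]


@dataclass(frozen=True)
class PairStatistics:
    """Pair-count and pair-distance bookkeeping for one chromosome.

    Attributes
    ----------
    mean_count
        ⟨N⟩, mean CO count per sample (zero-CO samples included).
    n_obs_pair
        Mean observed pair count, mean of N(N−1)/2 over samples.
    n_noint_pair
        Expected pair count under the Poisson null, ⟨N⟩²/2.
    n_mis_pair
        Missing pairs, ``n_noint_pair − n_obs_pair``; negative when COs are
        clustered beyond the null.
    phi
        Ratio of observed to expected pairs, ``n_obs_pair / n_noint_pair``.
    d_obs
        Mean distance over all observed same-sample CO pairs, each pair
        weighted equally; ``None`` if no sample has two COs.
    d_noint
        Mean distance over all pairs of distinct entries in the pooled
        position multiset (same-sample pairs included).
    d_mis
        Distance charged to each missing pair; equals the chromosome length.
    d_int
        Weighted average (n_obs·d_obs + n_mis·d_mis)/(n_obs + n_mis);
        ``None`` when ``n_mis_pair < 0`` (negative weight — the operative
        formula is evaluated instead).
    """

    mean_count: float
    n_obs_pair: float
    n_noint_pair: float
    n_mis_pair: float
    phi: float
    d_obs: float | None
    d_noint: float
    d_mis: float
    d_int: float | None


@dataclass(frozen=True)
class InterferenceResult:
    """Interference length for one chromosome dataset."""

    l_int: float
    l_int_norm: float
    n_samples: int
    pair_stats: PairStatistics
    sem: float | None = None


def mean_pairwise_distance(positions: np.ndarray) -> float:
    """Mean |x_i − x_j| over all unordered pairs of distinct entries.

    Sorting plus rank weighting gives the exact pair sum in O(M log M):
    with x sorted ascending, Σ_{i<j}(x_j − x_i) = Σ_k x_k·(2k − M + 1).
    """
    x = np.sort(np.asarray(positions, dtype=np.float64))
    m = x.size
    if m < 2:
        raise DegenerateDataError("mean pairwise distance needs at least two positions")
    coef = 2.0 * np.arange(m) - (m - 1)
    return float(coef @ x) / (m * (m - 1) / 2.0)


def mean_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean |a_i − b_j| over all pairs with one entry from each array."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("mean cross distance needs both arrays non-empty")
    prefix = np.concatenate(([0.0], np.cumsum(a)))
    total_a = prefix[-1]
    k = np.searchsorted(a, b, side="left")  # entries of a strictly below each b
    below_sum = prefix[k]
    # Σ_i |a_i − b| = b·k − Σ_{a<b} a + Σ_{a≥b} a − b·(m−k)
    sums = b * k - below_sum + (total_a - below_sum) - b * (a.size - k)
    return float(sums.sum()) / (a.size * b.size)


def _within_sample_pair_sums(dataset: ChromosomeDataset) -> tuple[float, int]:
    """Total pairwise distance and total pair count over same-sample pairs.

    Vectorized over samples: positions are sorted within each sample, so the
    rank-weight identity applies per sample on the flat array.
    """
    flat, counts = dataset.flat()
    total_pairs = int((counts * (counts - 1) // 2).sum())
    if total_pairs == 0:
        return 0.0, 0
    nz = counts[counts > 0]
    starts = np.repeat(np.concatenate(([0], np.cumsum(nz)))[:-1], nz)
    rank = np.arange(flat.size) - starts
    coef = 2.0 * rank - (np.repeat(nz, nz) - 1)
    return float(coef @ flat), total_pairs


def compute_pair_statistics(dataset: ChromosomeDataset) -> PairStatistics:
    """All Eq.-level quantities entering the interference length.

    Requires at least two pooled CO positions (otherwise the null distance
    ``d_noint`` is undefined).
    """
    counts = dataset.counts()
    mean_count = float(counts.mean())
    if mean_count == 0.0:
        raise DegenerateDataError(
            f"chromosome {dataset.chromosome_id!r}: all samples are empty (⟨N⟩ = 0)"
        )
    pooled = dataset.pooled_positions()
    if pooled.size < 2:
        raise DegenerateDataError(
            f"chromosome {dataset.chromosome_id!r}: fewer than two pooled CO "
            "positions; the null distance is undefined"
        )
    n_obs_pair = float((counts * (counts - 1) / 2.0).mean())
    n_noint_pair = mean_count**2 / 2.0
    n_mis_pair = n_noint_pair - n_obs_pair
    phi = n_obs_pair / n_noint_pair

    pair_sum, total_pairs = _within_sample_pair_sums(dataset)
    d_obs = pair_sum / total_pairs if total_pairs else None
    d_noint = mean_pairwise_distance(pooled)
    d_mis = float(dataset.length_L)

    if n_mis_pair >= 0.0 and (n_obs_pair + n_mis_pair) > 0.0:
        d_int = ((n_obs_pair * (d_obs or 0.0)) + n_mis_pair * d_mis) / (
            n_obs_pair + n_mis_pair
        )
    else:
        d_int = None

    return PairStatistics(
        mean_count=mean_count,
        n_obs_pair=n_obs_pair,
        n_noint_pair=n_noint_pair,
        n_mis_pair=n_mis_pair,
        phi=phi,
        d_obs=d_obs,
        d_noint=d_noint,
        d_mis=d_mis,
        d_int=d_int,
    )


def interference_length(
    dataset: ChromosomeDataset, *, bivalent_correction: bool = False
) -> InterferenceResult:
    """Interference length L_int and normalized L_int^norm for one chromosome.

    Parameters
    ----------
    dataset
        Per-chromosome CO data; zero-CO samples must be present if they were
        assayed.
    bivalent_correction
        Double ⟨N⟩ in the normalization. Genetic data detect a CO on only one
        of the two involved chromatids, so counts per gamete are about half
        the counts per bivalent; set this flag for genetic data when
        comparing L_int^norm against cytological values.

    Notes
    -----
    When φ = 0 (no sample has two COs) the observed-pair term vanishes and
    L_int = L − d_noint. When the observed pair count exceeds the Poisson
    expectation (clustering), φ > 1 and L_int can be negative; a
    ``ClusteringWarning`` is emitted and the value reported as-is.
    """
    ps = compute_pair_statistics(dataset)
    if ps.n_mis_pair < 0.0:
        warnings.warn(
            f"chromosome {dataset.chromosome_id!r}: more CO pairs than the "
            "Poisson null (negative missing-pair count); COs appear clustered "
            "and L_int may be negative",
            ClusteringWarning,
            stacklevel=2,
        )
    obs_term = ps.phi * (ps.d_obs - ps.d_noint) if ps.d_obs is not None else 0.0
    l_int = obs_term + (1.0 - ps.phi) * (dataset.length_L - ps.d_noint)
    mean_for_norm = ps.mean_count * (2.0 if bivalent_correction else 1.0)
    l_int_norm = l_int * mean_for_norm / dataset.length_L
    return InterferenceResult(
        l_int=l_int,
        l_int_norm=l_int_norm,
        n_samples=dataset.n_samples,
        pair_stats=ps,
    )


def _class_positions(sample, label: str) -> np.ndarray:
    if sample.classes is None:
        return np.empty(0, dtype=np.float64)
    return sample.positions[sample.classes == label]


def mixed_interference_length(
    dataset: ChromosomeDataset, class_a: str = CLASS_I, class_b: str = CLASS_II
) -> InterferenceResult:
    """Interference between two CO classes (e.g. class I vs class II).

    Measures whether COs of one pathway repel COs of the other. Observed
    cross-class pairs per sample number N_a·N_b; under independence the
    expectation is ⟨N_a⟩·⟨N_b⟩, giving φ_mix = ⟨N_a·N_b⟩/(⟨N_a⟩⟨N_b⟩).
    ``d_obs`` averages over observed cross-class pairs, ``d_noint`` over one
    draw from each pooled class, and

        L_int^mix = φ_mix·(d_obs − d_noint) + (1 − φ_mix)·(L − d_noint).

    Unlabeled ("unknown") COs are excluded. With ``class_a == class_b`` the
    standard single-class estimator is applied to the class-restricted data.
    """
    if class_a == class_b:
        samples = [
            type(s)(s.sample_id, _class_positions(s, class_a))
            for s in dataset.samples
        ]
        restricted = ChromosomeDataset(
            dataset.chromosome_id, dataset.length_L, dataset.space, samples
        )
        return interference_length(restricted)

    pos_a = [_class_positions(s, class_a) for s in dataset.samples]
    pos_b = [_class_positions(s, class_b) for s in dataset.samples]
    pool_a = np.concatenate(pos_a) if pos_a else np.empty(0)
    pool_b = np.concatenate(pos_b) if pos_b else np.empty(0)
    for pool, label in ((pool_a, class_a), (pool_b, class_b)):
        if pool.size == 0:
            raise DegenerateDataError(
                f"chromosome {dataset.chromosome_id!r}: no class {label!r} COs"
            )

    counts_a = np.array([p.size for p in pos_a], dtype=np.float64)
    counts_b = np.array([p.size for p in pos_b], dtype=np.float64)
    n_samples = len(dataset.samples)
    mean_a = counts_a.mean()
    mean_b = counts_b.mean()
    n_obs_pair = float((counts_a * counts_b).mean())
    n_noint_pair = mean_a * mean_b
    n_mis_pair = n_noint_pair - n_obs_pair
    phi = n_obs_pair / n_noint_pair

    pair_sum = 0.0
    total_pairs = 0
    for pa, pb in zip(pos_a, pos_b):
        if pa.size and pb.size:
            pair_sum += mean_cross_distance(pa, pb) * (pa.size * pb.size)
            total_pairs += pa.size * pb.size
    d_obs = pair_sum / total_pairs if total_pairs else None
    d_noint = mean_cross_distance(pool_a, pool_b)
    d_mis = float(dataset.length_L)

    if n_mis_pair >= 0.0 and (n_obs_pair + n_mis_pair) > 0.0:
        d_int = ((n_obs_pair * (d_obs or 0.0)) + n_mis_pair * d_mis) / (
            n_obs_pair + n_mis_pair
        )
    else:
        d_int = None
    ps = PairStatistics(
        mean_count=float(mean_a + mean_b),
        n_obs_pair=n_obs_pair,
        n_noint_pair=n_noint_pair,
        n_mis_pair=n_mis_pair,
        phi=phi,
        d_obs=d_obs,
        d_noint=d_noint,
        d_mis=d_mis,
        d_int=d_int,
    )
    obs_term = phi * (d_obs - d_noint) if d_obs is not None else 0.0
    l_int = obs_term + (1.0 - phi) * (dataset.length_L - d_noint)
    l_int_norm = l_int * ps.mean_count / dataset.length_L
    return InterferenceResult(
        l_int=l_int, l_int_norm=l_int_norm, n_samples=n_samples, pair_stats=ps
    )
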