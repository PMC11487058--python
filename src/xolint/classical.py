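"""Classical interference measures: coefficient of coincidence and gamma shape.

The coefficient of coincidence (CoC) compares the observed frequency of
double crossovers in two intervals to the product of the single-interval
frequencies. Without interference the ratio is ≈ 1 at every separation; with
interference it drops toward 0 at short separations. The interference
distance d_CoC is the separation at which the rising curve first exceeds 0.5.

The gamma shape parameter ν is the maximum-likelihood shape of a gamma
distribution fitted to the distances between *adjacent* crossovers, pooled
over samples with at least two crossovers. ν = 1 corresponds to exponential
spacing (no interference); larger ν means more even spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .datatypes import ChromosomeDataset
from .errors import DegenerateDataError, InsufficientDataError, ParameterError

__all__ = ["CoCCurve", "GammaFit", "coc_curve", "interference_distance", "gamma_shape"]

#: Fraction of the chromosome length used to replace exactly-zero adjacent
#: distances so the gamma likelihood stays finite.
ZERO_DISTANCE_JITTER = 1e-9


@dataclass(frozen=True)
class CoCCurve:
    """Binned coefficient-of-coincidence curve for one chromosome.

    ``separations`` are the distinct center-to-center bin distances (length
    units), strictly increasing; ``coc_values`` are the ratio-of-sums CoC at
    each separation; ``n_bin_pairs`` counts contributing bin pairs. ``d_coc``
    is the interference distance (``None`` when the curve never reaches 0.5).
    """

    bin_count: int
    separations: np.ndarray
    coc_values: np.ndarray
    n_bin_pairs: np.ndarray
    d_coc: float | None


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit to adjacent inter-crossover distances."""

    shape_nu: float
    scale: float
    n_distances: int


def coc_curve(dataset: ChromosomeDataset, bin_count: int = 15) -> CoCCurve:
    """Coefficient-of-coincidence curve on equal-width bins.

    The chromosome is split into ``bin_count`` equal intervals. For each bin
    the single frequency f_i is the fraction of samples with at least one CO
    in it; for each bin pair the joint frequency f_ij is the fraction with a
    CO in both. CoC at separation s pools every bin pair at center distance
    s as a ratio of sums, Σ f_ij / Σ f_i f_j, which stays stable when the
    individual expected frequencies are tiny. Separations whose expected sum
    is zero are dropped.
    """
    if bin_count < 2:
        raise ParameterError("bin_count must be at least 2")
    flat, counts = dataset.flat()
    if flat.size == 0:
        raise DegenerateDataError(
            f"chromosome {dataset.chromosome_id!r}: no COs; CoC undefined"
        )
    n = dataset.n_samples
    bin_width = dataset.length_L / bin_count
    bin_idx = np.minimum((flat / bin_width).astype(np.int64), bin_count - 1)
    nz = counts[counts > 0]
    sample_idx = np.repeat(np.flatnonzero(counts > 0), nz)

    presence = np.zeros((n, bin_count), dtype=np.float64)
    presence[sample_idx, bin_idx] = 1.0
    f = presence.mean(axis=0)
    if not f.any():
        raise DegenerateDataError(
            f"chromosome {dataset.chromosome_id!r}: every bin frequency is zero"
        )
    joint = presence.T @ presence / n  # f_ij on the off-diagonal

    separations, cocs, n_pairs = [], [], []
    for k in range(1, bin_count):
        idx = np.arange(bin_count - k)
        observed = joint[idx, idx + k].sum()
        expected = (f[idx] * f[idx + k]).sum()
        if expected > 0.0:
            separations.append(k * bin_width)
            cocs.append(observed / expected)
            n_pairs.append(bin_count - k)
    separations = np.asarray(separations)
    cocs = np.asarray(cocs)
    curve = CoCCurve(
        bin_count=bin_count,
        separations=separations,
        coc_values=cocs,
        n_bin_pairs=np.asarray(n_pairs, dtype=np.int64),
        d_coc=None,
    )
    return CoCCurve(
        bin_count=bin_count,
        separations=separations,
        coc_values=cocs,
        n_bin_pairs=curve.n_bin_pairs,
        d_coc=interference_distance(curve),
    )


def interference_distance(curve: CoCCurve) -> float | None:
    """Separation at which the CoC curve first reaches 0.5.

    Scans separations in increasing order for the first upward crossing from
    below 0.5 to at or above it and linearly interpolates the crossing point.
    A curve that starts at or above 0.5 yields 0.0 by convention (no
    resolvable interference zone); a curve that never reaches 0.5 yields
    ``None`` with a warning.
    """
    if curve.coc_values.size == 0:
        return None
    if curve.coc_values[0] >= 0.5:
        return 0.0
    for i in range(1, curve.coc_values.size):
        lo, hi = curve.coc_values[i - 1], curve.coc_values[i]
        if lo < 0.5 <= hi:
            s_lo, s_hi = curve.separations[i - 1], curve.separations[i]
            return float(s_lo + (0.5 - lo) / (hi - lo) * (s_hi - s_lo))
    warnings.warn(
        "CoC curve never reaches 0.5; interference distance undefined",
        stacklevel=2,
    )
    return None


def adjacent_distances(dataset: ChromosomeDataset) -> np.ndarray:
    """Distances between neighbouring COs, pooled over samples with ≥ 2 COs."""
    gaps = [
        np.diff(s.positions) for s in dataset.samples if s.positions.size >= 2
    ]
    if not gaps:
        return np.empty(0, dtype=np.float64)
    return np.concatenate(gaps)


def gamma_shape(dataset: ChromosomeDataset) -> GammaFit:
    """Fit a two-parameter gamma distribution to adjacent CO distances.

    Only samples with at least two COs contribute; at least 10 pooled
    distances are required for a stable fit. Exactly-zero distances
    (coincident foci) are replaced by ``ZERO_DISTANCE_JITTER · L`` to keep
    the log-likelihood finite. Distances are not corrected for censoring at
    chromosome ends, which biases the fit slightly when the chromosome holds
    only a few COs.
    """
    gaps = adjacent_distances(dataset)
    if gaps.size < 10:
        raise InsufficientDataError(
            f"chromosome {dataset.chromosome_id!r}: {gaps.size} adjacent "
            "distances; at least 10 required for a gamma fit"
        )
    gaps = np.where(gaps <= 0.0, ZERO_DISTANCE_JITTER * dataset.length_L, gaps)
    shape, _, scale = scipy.stats.gamma.fit(gaps, floc=0.0)
    return GammaFit(shape_nu=float(shape), scale=float(scale), n_distances=int(gaps.size))
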