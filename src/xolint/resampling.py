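"""Bootstrap uncertainty and resampling significance tests.

The exchangeable unit is the sample (cell / gamete / meiotic product):
standard errors come from a nonparametric bootstrap over whole samples,
which preserves within-sample CO patterns; the two-group comparison is a
permutation test on sample labels; the test against "no interference"
parametrically bootstraps the fitted null (Poisson counts with the observed
mean, positions redrawn i.i.d. from the pooled empirical positions, which
preserves the CO density along the chromosome).

All procedures are pure functions of (data, seed, replicates). p-values use
the add-one rule (k + 1)/(B + 1) and can therefore never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .classical import coc_curve, gamma_shape
from .datatypes import ChromosomeDataset, CrossoverSample
from .errors import (
    ClusteringWarning,
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
    ResamplingError,
)
from .interference import interference_length

__all__ = [
    "ResampleResult",
    "TestResult",
    "ESTIMATORS",
    "bootstrap_sem",
    "test_two_sample",
    "test_vs_null",
]

MIN_REPLICATES = 100
#: Maximum total draws per resampling run, as a multiple of `replicates`;
#: beyond this, persistent degeneracy raises instead of looping.
MAX_DRAW_INFLATION = 10


def _estimate_lint(ds: ChromosomeDataset) -> float:
    return interference_length(ds).l_int


def _estimate_lintnorm(ds: ChromosomeDataset) -> float:
    return interference_length(ds).l_int_norm


def _estimate_dcoc(ds: ChromosomeDataset, bin_count: int = 15) -> float:
    d = coc_curve(ds, bin_count=bin_count).d_coc
    if d is None:
        raise DegenerateDataError("CoC curve never reaches 0.5")
    return d


def _estimate_gamma(ds: ChromosomeDataset) -> float:
    return gamma_shape(ds).shape_nu


ESTIMATORS: dict[str, Callable[..., float]] = {
    "lint": _estimate_lint,
    "lintnorm": _estimate_lintnorm,
    "dcoc": _estimate_dcoc,
    "gamma": _estimate_gamma,
}


@dataclass(frozen=True)
class ResampleResult:
    """Point estimate with bootstrap standard error."""

    point_estimate: float
    sem: float
    replicates: int
    seed: int
    estimator: str


@dataclass(frozen=True)
class TestResult:
    """Resampling significance test outcome."""

    statistic: float
    p_value: float
    replicates: int
    seed: int
    kind: str  # "two_sample" | "vs_null"
    estimator: str


def _resolve(estimator: str | Callable[..., float]) -> tuple[Callable[..., float], str]:
    if callable(estimator):
        return estimator, getattr(estimator, "__name__", "custom")
    try:
        return ESTIMATORS[estimator], estimator
    except KeyError:
        raise ParameterError(
            f"unknown estimator {estimator!r}; choose from {sorted(ESTIMATORS)}"
        ) from None


def _check_replicates(replicates: int) -> None:
    if replicates < MIN_REPLICATES:
        raise ParameterError(f"replicates must be at least {MIN_REPLICATES}")


def _collect(stat: Callable[[], float], replicates: int) -> np.ndarray:
    """Evaluate a randomized statistic, redrawing degenerate replicates.

    Data-quality warnings (e.g. clustering) are suppressed on replicates:
    they belong to the estimate on the observed data, not to every resample.
    """
    values = np.empty(replicates)
    got = 0
    attempts = 0
    limit = MAX_DRAW_INFLATION * replicates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClusteringWarning)
        while got < replicates:
            if attempts >= limit:
                raise ResamplingError(
                    f"estimator degenerate on {attempts - got} of {attempts} draws; giving up"
                )
            attempts += 1
            try:
                values[got] = stat()
            except (DegenerateDataError, InsufficientDataError):
                continue
            got += 1
    return values


def bootstrap_sem(
    dataset: ChromosomeDataset,
    estimator: str | Callable[..., float] = "lint",
    replicates: int = 200,
    seed: int = 0,
    **estimator_kwargs,
) -> ResampleResult:
    """Nonparametric bootstrap standard error over samples.

    Whole samples are resampled with replacement, keeping each sample's CO
    pattern intact. Replicates on which the estimator is degenerate (e.g. a
    bootstrap dataset with no CO pairs) are redrawn, up to a bounded number
    of extra draws.
    """
    _check_replicates(replicates)
    func, name = _resolve(estimator)
    n = dataset.n_samples
    if n < 2:
        raise ResamplingError("bootstrap needs at least two samples")
    point = func(dataset, **estimator_kwargs)
    rng = np.random.default_rng(seed)
    values = _collect(
        lambda: func(dataset.subset(rng.integers(0, n, n)), **estimator_kwargs),
        replicates,
    )
    return ResampleResult(
        point_estimate=float(point),
        sem=float(values.std(ddof=1)),
        replicates=replicates,
        seed=seed,
        estimator=name,
    )


def test_two_sample(
    a: ChromosomeDataset,
    b: ChromosomeDataset,
    estimator: str | Callable[..., float] = "lint",
    replicates: int = 999,
    seed: int = 0,
    **estimator_kwargs,
) -> TestResult:
    """Permutation test of equality of an estimator between two datasets.

    Samples are pooled and randomly reassigned to two groups of the original
    sizes; the statistic is |estimate(a) − estimate(b)|. The add-one p-value
    is two-sided by construction of the absolute statistic.
    """
    _check_replicates(replicates)
    func, name = _resolve(estimator)
    observed = abs(func(a, **estimator_kwargs) - func(b, **estimator_kwargs))
    pooled = a.samples + b.samples
    n_a, n_total = a.n_samples, len(pooled)
    rng = np.random.default_rng(seed)

    def perm_stat() -> float:
        order = rng.permutation(n_total)
        ds_a = ChromosomeDataset(
            a.chromosome_id, a.length_L, a.space, [pooled[i] for i in order[:n_a]]
        )
        ds_b = ChromosomeDataset(
            b.chromosome_id, b.length_L, b.space, [pooled[i] for i in order[n_a:]]
        )
        return abs(func(ds_a, **estimator_kwargs) - func(ds_b, **estimator_kwargs))

    stats = _collect(perm_stat, replicates)
    p = (1 + int((stats >= observed).sum())) / (replicates + 1)
    return TestResult(
        statistic=float(observed),
        p_value=float(p),
        replicates=replicates,
        seed=seed,
        kind="two_sample",
        estimator=name,
    )


def test_vs_null(
    dataset: ChromosomeDataset,
    estimator: str | Callable[..., float] = "lint",
    replicates: int = 999,
    seed: int = 0,
    **estimator_kwargs,
) -> TestResult:
    """Parametric bootstrap test against the no-interference null.

    The null fixes the observed mean CO count and positional density: counts
    are Poisson(⟨N⟩) and positions are drawn i.i.d. (with replacement) from
    the pooled observed positions. One-sided: interference makes the
    estimator large, so p is the add-one fraction of null replicates at or
    above the observed estimate.
    """
    _check_replicates(replicates)
    func, name = _resolve(estimator)
    observed = func(dataset, **estimator_kwargs)
    pool = dataset.pooled_positions()
    if pool.size == 0:
        raise DegenerateDataError("cannot fit the null: no observed CO positions")
    mean_count = float(dataset.counts().mean())
    n = dataset.n_samples
    rng = np.random.default_rng(seed)

    def draw_null() -> ChromosomeDataset:
        counts = rng.poisson(mean_count, n)
        flat = rng.choice(pool, size=int(counts.sum()), replace=True)
        parts = np.split(flat, np.cumsum(counts)[:-1])
        samples = [
            CrossoverSample(f"null{i}", np.sort(part)) for i, part in enumerate(parts)
        ]
        return ChromosomeDataset(
            dataset.chromosome_id, dataset.length_L, dataset.space, samples
        )

    stats = _collect(lambda: func(draw_null(), **estimator_kwargs), replicates)
    p = (1 + int((stats >= observed).sum())) / (replicates + 1)
    return TestResult(
        statistic=float(observed),
        p_value=float(p),
        replicates=replicates,
        seed=seed,
        kind="vs_null",
        estimator=name,
    )
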