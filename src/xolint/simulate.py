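"""Generative models of crossover placement and a sub-sampling operator.

Five point-process models on the interval [0, L], each returning a
:class:`~xolint.datatypes.ChromosomeDataset`:

* ``poisson_null`` — CO count per sample ~ Poisson(⟨N⟩), positions i.i.d.
  from a positional density. The no-interference reference: L_int = 0.
* ``obligate`` — exactly one CO per sample (complete interference with an
  obligate crossover). Uniform positions give L_int = 2/3·L.
* ``regular_placement`` — exactly N COs at spacing L/N, the first placed
  uniformly in [0, L/N]; marginally uniform CO density with maximally even
  spacing. Closed form: L_int = L·(1/N − 1/(3N²)).
* ``fixed_position`` — one CO at L/2 in every sample; the degenerate case
  L_int = L.
* ``renewal_gamma`` — stationary renewal process with gamma(ν₀) inter-CO
  distances; ν₀ tunes interference continuously (ν₀ = 1 is exactly the
  Poisson process). Not a scenario with a printed closed form — it is the
  standard tunable generator for exercising CoC, ν and L_int jointly.

Positional densities: ``"uniform"``, ``("beta", a, b)`` scaled to [0, L], or
``"bimodal"`` (an equal mixture of Beta(2, 8) and Beta(8, 2) — mass piled
near both chromosome ends, as in strongly distal CO landscapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .datatypes import ChromosomeDataset, CrossoverSample, Space
from .errors import ParameterError

__all__ = ["SimulationConfig", "simulate", "subsample", "MODELS"]

MODELS = ("poisson_null", "obligate", "regular_placement", "fixed_position", "renewal_gamma")

DensitySpec = Union[str, tuple]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated chromosome dataset.

    ``mean_count`` is the target mean CO count per sample ⟨N⟩ (an integer N
    for ``regular_placement``); ``shape`` is the renewal shape ν₀ and is used
    only by ``renewal_gamma``. ``position_density`` applies to the models
    that place COs independently (``poisson_null`` and ``obligate``).
    """

    model: str
    n_samples: int
    length_L: float = 1.0
    mean_count: float = 2.0
    shape: float = 1.0
    position_density: DensitySpec = "uniform"
    seed: int = 0
    chromosome_id: str = "sim"
    space: Space = Space.SC_UM

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be at least 1")
        if not self.length_L > 0:
            raise ParameterError("length_L must be positive")
        if self.model == "renewal_gamma" and not self.shape > 0:
            raise ParameterError("renewal shape must be positive")
        if self.model in ("poisson_null", "renewal_gamma") and not self.mean_count > 0:
            raise ParameterError("mean_count must be positive")
        if self.model == "regular_placement":
            if self.mean_count < 1 or self.mean_count != int(self.mean_count):
                raise ParameterError("regular_placement needs an integer CO count ≥ 1")


def _sample_density(
    density: DensitySpec, size: int, length_l: float, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(density, str):
        if density == "uniform":
            return rng.uniform(0.0, length_l, size)
        if density == "bimodal":
            a_side = rng.random(size) < 0.5
            x = np.where(
                a_side, rng.beta(2.0, 8.0, size), rng.beta(8.0, 2.0, size)
            )
            return x * length_l
        raise ParameterError(f"unknown position density {density!r}")
    if len(density) == 3 and density[0] == "beta":
        _, a, b = density
        return rng.beta(a, b, size) * length_l
    raise ParameterError(f"unknown position density spec {density!r}")


def _split_sorted(flat: np.ndarray, counts: np.ndarray, prefix: str) -> list[CrossoverSample]:
    """Build one sample per count from a flat position array."""
    parts = np.split(flat, np.cumsum(counts)[:-1])
    return [
        CrossoverSample(f"{prefix}{i}", np.sort(part))
        for i, part in enumerate(parts)
    ]


def _renewal_positions(
    n: int, length_l: float, mean_count: float, shape: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Stationary gamma renewal process restricted to [0, L], per sample.

    Inter-CO distances are gamma(ν₀, scale L/(ν₀⟨N⟩)), so the mean spacing
    is L/⟨N⟩ and the expected count on the window is exactly ⟨N⟩. The first
    CO is drawn from the equilibrium (forward-recurrence) distribution via
    the length-bias construction: U · gamma(ν₀ + 1) with U uniform, which
    makes the process stationary — and reduces exactly to a Poisson process
    at ν₀ = 1.
    """
    scale = length_l / (shape * mean_count)
    first = rng.random(n) * rng.gamma(shape + 1.0, scale, n)
    arrivals = [first]
    alive = first <= length_l
    current = first.copy()
    while alive.any():
        step = np.full(n, np.inf)
        k = int(alive.sum())
        step[alive] = rng.gamma(shape, scale, k)
        current = current + step
        arrivals.append(current.copy())
        alive = current <= length_l
    stacked = np.vstack(arrivals)  # (k_max, n)
    out = []
    for j in range(n):
        col = stacked[:, j]
        out.append(np.sort(col[col <= length_l]))
    return out


def simulate(config: SimulationConfig) -> ChromosomeDataset:
    """Generate a chromosome dataset under the configured placement model."""
    rng = np.random.default_rng(config.seed)
    n, L = config.n_samples, config.length_L

    if config.model == "poisson_null":
        counts = rng.poisson(config.mean_count, n)
        flat = _sample_density(config.position_density, int(counts.sum()), L, rng)
        samples = _split_sorted(flat, counts, "s")
    elif config.model == "obligate":
        flat = _sample_density(config.position_density, n, L, rng)
        samples = [CrossoverSample(f"s{i}", flat[i : i + 1]) for i in range(n)]
    elif config.model == "regular_placement":
        n_co = int(config.mean_count)
        spacing = L / n_co
        x0 = rng.uniform(0.0, spacing, n)
        grid = x0[:, None] + spacing * np.arange(n_co)[None, :]
        samples = [CrossoverSample(f"s{i}", grid[i]) for i in range(n)]
    elif config.model == "fixed_position":
        pos = np.array([L / 2.0])
        samples = [CrossoverSample(f"s{i}", pos.copy()) for i in range(n)]
    else:  # renewal_gamma
        per_sample = _renewal_positions(n, L, config.mean_count, config.shape, rng)
        samples = [CrossoverSample(f"s{i}", p) for i, p in enumerate(per_sample)]

    return ChromosomeDataset(
        chromosome_id=config.chromosome_id,
        length_L=L,
        space=config.space,
        samples=samples,
    )


def subsample(dataset: ChromosomeDataset, p: float, seed: int = 0) -> ChromosomeDataset:
    """Binomial thinning: retain each CO independently with probability p.

    Models random detection loss — e.g. a designated CO appearing in only
    half of the gametes in genetic data. Empty samples stay in the dataset.
    The interference length is invariant to thinning in expectation.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError("retention probability p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = []
    for s in dataset.samples:
        keep = rng.random(s.positions.size) < p
        classes = s.classes[keep] if s.classes is not None else None
        samples.append(CrossoverSample(s.sample_id, s.positions[keep], classes))
    return ChromosomeDataset(
        chromosome_id=dataset.chromosome_id,
        length_L=dataset.length_L,
        space=dataset.space,
        samples=samples,
    )
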