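"""Core domain types: crossover samples, per-chromosome datasets, length tables.

Positions are continuous coordinates in ``[0, L]`` along a single chromosome,
either in megabases (DNA space, genetic data) or micrometers along the
synaptonemal complex (SC space, cytological data). A *sample* is one meiotic
product or bivalent; a sample with zero crossovers is valid and matters for
the estimators (it contributes to the mean crossover count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .errors import MissingLengthError, ValidationError

CLASS_I = "I"
CLASS_II = "II"
CLASS_UNKNOWN = "unknown"
_VALID_CLASSES = frozenset({CLASS_I, CLASS_II, CLASS_UNKNOWN})


class Space(str, Enum):
    """Coordinate space of crossover positions."""

    DNA_MB = "dna"
    SC_UM = "sc"


@dataclass
class CrossoverSample:
    """Ordered crossover positions of one meiotic product on one chromosome.

    Parameters
    ----------
    sample_id
        Opaque identifier (cell, gamete, offspring, ...).
    positions
        Crossover coordinates; stored sorted ascending. May be empty.
    classes
        Optional per-crossover pathway label (``"I"``, ``"II"`` or
        ``"unknown"``), aligned with ``positions``.
    """

    sample_id: str
    positions: np.ndarray
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: positions must be one-dimensional"
            )
        if self.classes is not None:
            cls = np.asarray(self.classes, dtype=object)
            if cls.shape != pos.shape:
                raise ValidationError(
                    f"sample {self.sample_id!r}: classes length {cls.size} "
                    f"!= positions length {pos.size}"
                )
            bad = set(cls) - _VALID_CLASSES
            if bad:
                raise ValidationError(
                    f"sample {self.sample_id!r}: invalid class labels {sorted(map(str, bad))}"
                )
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            cls = cls[order]
            self.classes = cls
        else:
            pos = np.sort(pos)
        self.positions = pos

    @property
    def n(self) -> int:
        """Number of crossovers in this sample."""
        return int(self.positions.size)


@dataclass
class ChromosomeDataset:
    """All samples for one chromosome; the unit of analysis for every estimator.

    ``length_L`` is the physical chromosome (or SC) length in the coordinate
    space of ``space``; it is a parameter of the measures, never inferred from
    the data.
    """

    chromosome_id: str
    length_L: float
    space: Space
    samples: list[CrossoverSample]

    def __post_init__(self) -> None:
        if not self.length_L > 0:
            raise ValidationError(
                f"chromosome {self.chromosome_id!r}: length_L must be positive"
            )
        if not self.samples:
            raise ValidationError(
                f"chromosome {self.chromosome_id!r}: at least one sample required"
            )
        pooled = self.pooled_positions()
        if pooled.size and (pooled.min() < 0.0 or pooled.max() > self.length_L):
            raise ValidationError(
                f"chromosome {self.chromosome_id!r}: positions outside "
                f"[0, {self.length_L}]"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def counts(self) -> np.ndarray:
        """Crossover count per sample (includes zero-CO samples)."""
        return np.fromiter(
            (s.positions.size for s in self.samples), dtype=np.int64, count=len(self.samples)
        )

    def pooled_positions(self) -> np.ndarray:
        """All crossover positions pooled across samples (a multiset)."""
        arrays = [s.positions for s in self.samples if s.positions.size]
        if not arrays:
            return np.empty(0, dtype=np.float64)
        return np.concatenate(arrays)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled positions plus per-sample counts, preserving sample order.

        Positions stay sorted within each sample, so within-sample pair sums
        can be computed by rank arithmetic without re-sorting.
        """
        return self.pooled_positions(), self.counts()

    def subset(self, indices: Iterable[int]) -> "ChromosomeDataset":
        """Dataset restricted to (or resampled over) the given sample indices."""
        return ChromosomeDataset(
            chromosome_id=self.chromosome_id,
            length_L=self.length_L,
            space=self.space,
            samples=[self.samples[i] for i in indices],
        )


@dataclass
class LengthTable:
    """Chromosome lengths in DNA space (Mb) and/or SC space (μm).

    Conversion between spaces requires both lengths for a chromosome; the
    conversion assumes uniform compaction along the chromosome.
    """

    lengths: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (dna, sc) in self.lengths.items():
            for value, name in ((dna, "DNA"), (sc, "SC")):
                if value is not None and not value > 0:
                    raise ValidationError(
                        f"chromosome {chrom!r}: {name} length must be positive"
                    )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[float | None, float | None]]
    ) -> "LengthTable":
        return cls(dict(mapping))

    def __contains__(self, chromosome_id: str) -> bool:
        return chromosome_id in self.lengths

    def length(self, chromosome_id: str, space: Space) -> float:
        """Length of a chromosome in the requested space."""
        try:
            dna, sc = self.lengths[chromosome_id]
        except KeyError:
            raise MissingLengthError(
                f"chromosome {chromosome_id!r} not in length table"
            ) from None
        value = dna if space is Space.DNA_MB else sc
        if value is None:
            raise MissingLengthError(
                f"chromosome {chromosome_id!r} has no length in {space.value} space"
            )
        return float(value)
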