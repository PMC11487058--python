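"""Readers, writers and coordinate-space conversion for crossover tables.

File formats (UTF-8, tab-separated, ``.`` decimal separator):

* Crossover table — header ``sample_id  chromosome  position  co_class``.
  One row per detected crossover. A row with an *empty* position field is a
  manifest row: it declares that the sample was assayed on that chromosome
  and carries zero crossovers there. Zero-CO samples enter the mean
  crossover count, so dropping them would bias every downstream estimate;
  they must therefore be declared explicitly.
* Length table — header ``chromosome  length_dna_mb  length_sc_um``; either
  length column may be left empty for a chromosome, but converting between
  spaces requires both.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ChromosomeDataset,
    CrossoverSample,
    LengthTable,
    Space,
    CLASS_UNKNOWN,
)
from .errors import FormatError, MissingLengthError, ValidationError

_CO_COLUMNS = ("sample_id", "chromosome", "position")


def read_length_table(path: str | Path) -> LengthTable:
    """Read a chromosome-length table."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "chromosome" not in df.columns:
        raise FormatError(f"{path}: missing 'chromosome' column")
    lengths: dict[str, tuple[float | None, float | None]] = {}
    for _, row in df.iterrows():
        dna = row.get("length_dna_mb")
        sc = row.get("length_sc_um")
        dna = None if dna is None or pd.isna(dna) else float(dna)
        sc = None if sc is None or pd.isna(sc) else float(sc)
        if dna is None and sc is None:
            raise FormatError(
                f"{path}: chromosome {row['chromosome']!r} has no length in either space"
            )
        lengths[str(row["chromosome"])] = (dna, sc)
    return LengthTable(lengths)


def write_length_table(table: LengthTable, path: str | Path) -> None:
    rows = [
        {"chromosome": chrom, "length_dna_mb": dna, "length_sc_um": sc}
        for chrom, (dna, sc) in table.lengths.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_crossover_table(
    path: str | Path, lengths: LengthTable, space: Space
) -> list[ChromosomeDataset]:
    """Read a crossover table into one dataset per chromosome.

    The sample universe of a chromosome is the set of sample ids appearing in
    its rows; samples whose only row is a manifest row (empty position) come
    out as zero-CO samples. Positions are validated against the chromosome
    length from ``lengths`` in the declared ``space``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "chromosome": str, "co_class": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in _CO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_class = "co_class" in df.columns

    datasets: list[ChromosomeDataset] = []
    for chrom in df["chromosome"].drop_duplicates():
        if chrom not in lengths:
            raise MissingLengthError(f"{path}: chromosome {chrom!r} not in length table")
        length_l = lengths.length(chrom, space)
        sub = df[df["chromosome"] == chrom]
        samples: list[CrossoverSample] = []
        for sample_id in sub["sample_id"].drop_duplicates():
            rows = sub[sub["sample_id"] == sample_id]
            observed = rows[rows["position"].notna()]
            pos = observed["position"].to_numpy(dtype=np.float64)
            if pos.size and (pos.min() < 0.0 or pos.max() > length_l):
                bad = observed.index[
                    (observed["position"] < 0.0) | (observed["position"] > length_l)
                ][0]
                raise ValidationError(
                    f"{path} row {bad + 2}: position outside [0, {length_l}] "
                    f"for chromosome {chrom!r}"
                )
            cls = None
            if has_class and pos.size:
                raw = observed["co_class"].fillna(CLASS_UNKNOWN).to_numpy(dtype=object)
                if not np.all(raw == CLASS_UNKNOWN):
                    cls = raw
            samples.append(CrossoverSample(str(sample_id), pos, cls))
        datasets.append(
            ChromosomeDataset(
                chromosome_id=str(chrom), length_L=length_l, space=space, samples=samples
            )
        )
    return datasets


def write_crossover_table(
    datasets: list[ChromosomeDataset], path: str | Path
) -> None:
    """Write datasets as a crossover table (manifest rows for empty samples).

    Positions are serialized with ``repr`` so a round trip reproduces the
    float64 values exactly.
    """
    if not datasets:
        raise ValueError("datasets must be non-empty")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "chromosome", "position", "co_class"])
        for ds in datasets:
            for sample in ds.samples:
                if sample.positions.size == 0:
                    writer.writerow([sample.sample_id, ds.chromosome_id, "", ""])
                    continue
                classes = (
                    sample.classes
                    if sample.classes is not None
                    else [CLASS_UNKNOWN] * sample.positions.size
                )
                for pos, cls in zip(sample.positions, classes):
                    writer.writerow([sample.sample_id, ds.chromosome_id, repr(float(pos)), cls])


def convert_space(
    dataset: ChromosomeDataset, lengths: LengthTable, target: Space
) -> ChromosomeDataset:
    """Rescale a dataset between DNA (Mb) and SC (μm) coordinates.

    Positions are multiplied by the ratio of target to source length; this
    assumes uniform chromatin compaction along the chromosome. Converting to
    the dataset's own space returns an equivalent copy.
    """
    if target is dataset.space:
        factor = 1.0
        target_length = dataset.length_L
    else:
        source_length = lengths.length(dataset.chromosome_id, dataset.space)
        target_length = lengths.length(dataset.chromosome_id, target)
        factor = target_length / source_length
    samples = [
        # clip guards against positions at exactly L drifting past the new
        # length by one ulp under the multiplication
        CrossoverSample(
            s.sample_id, np.clip(s.positions * factor, 0.0, target_length), s.classes
        )
        for s in dataset.samples
    ]
    return ChromosomeDataset(
        chromosome_id=dataset.chromosome_id,
        length_L=target_length,
        space=target,
        samples=samples,
    )
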