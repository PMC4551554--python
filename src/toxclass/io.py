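"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: TSV for matrices, metadata and annotation,
GMT for gene sets and JSON for models and configs. Readers validate against
the domain-type invariants and fail fast with coordinates on malformed
input; writers emit files that round-trip bit-exactly through the readers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ContrastMatrix,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    ProbeAnnotation,
    SampleMetadata,
)

# Full float precision so write -> read is the identity.
_FLOAT_FMT = "%.17g"


def _read_matrix_frame(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        sample_ids = header[1:]
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}:{line_no}: expected {len(header)} fields, got {len(rec)}"
                )
            probe_ids.append(rec[0])
            vals = []
            for col, cell in enumerate(rec[1:]):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{line_no}: non-numeric value {cell!r} in column "
                        f"{sample_ids[col]!r}"
                    ) from None
            rows.append(vals)
    return pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(probe_ids), len(sample_ids)),
        index=probe_ids,
        columns=sample_ids,
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a probe x sample log2 expression TSV (header = sample ids)."""
    return ExpressionMatrix(_read_matrix_frame(path))


def read_contrast_matrix(path) -> ContrastMatrix:
    """Read a probe x treated-sample contrast TSV."""
    return ContrastMatrix(_read_matrix_frame(path))


def write_matrix(matrix, path) -> None:
    """Write an expression or contrast matrix as TSV at full float precision."""
    df = matrix.data
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", *df.columns])
        for probe, row in zip(df.index, df.to_numpy()):
            writer.writerow([probe, *(_FLOAT_FMT % v for v in row)])


write_expression_matrix = write_matrix
write_contrast_matrix = write_matrix


def read_sample_metadata(path) -> SampleMetadata:
    """Read the sample design TSV (matched controls semicolon-separated)."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "sample_id": str,
            "compound": str,
            "class_label": str,
            "batch_id": str,
            "matched_control_ids": str,
        },
        keep_default_na=False,
    )
    if "matched_control_ids" not in table.columns:
        raise FormatError(f"{path}: missing matched_control_ids column")
    table["matched_control_ids"] = [
        [c for c in str(cell).split(";") if c] for cell in table["matched_control_ids"]
    ]
    table["replicate_index"] = table["replicate_index"].astype(int)
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    table = meta.table.copy()
    table["matched_control_ids"] = [
        ";".join(c) for c in table["matched_control_ids"]
    ]
    table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> ProbeAnnotation:
    """Read the probe_id -> gene_symbol TSV; blank symbol = unannotated."""
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, usecols=["probe_id", "gene_symbol"]
    )
    mapping = {}
    for probe, gene in zip(table["probe_id"], table["gene_symbol"]):
        if probe in mapping:
            raise FormatError(f"{path}: duplicate probe id {probe!r}")
        mapping[probe] = gene if gene else None
    return ProbeAnnotation(mapping)


def write_annotation(annot: ProbeAnnotation, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", "gene_symbol"])
        for probe, gene in annot.mapping.items():
            writer.writerow([probe, gene if gene is not None else ""])


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, tab-separated symbols)."""
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{line_no}: GMT line needs name and description")
            name, description, *genes = fields
            sets.append(GeneSet(name=name, description=description, genes=tuple(g for g in genes if g)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
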