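"""Shared domain types for the expression-based toxicant-class pipeline.

All stages exchange data through a small set of validated containers built
on pandas. Matrices are stored probes-as-rows / samples-as-columns in log2
units; row and column order is always preserved from the source (never
sorted silently) and all joins are by identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "CONTROL"
CLASS_A = "CLASS_A"
CLASS_B = "CLASS_B"


class ValidationError(ValueError):
    """An input violates a structural invariant of a domain type."""


class FormatError(ValidationError):
    """A file does not conform to the expected on-disk dialect."""


class PairingError(ValidationError):
    """A treated sample cannot be matched to any control."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


class _Matrix:
    """Base for dense probe x sample grids with finite float values."""

    _value_name = "value"

    def __init__(self, data: pd.DataFrame):
        _check_unique(list(data.index), "probe")
        _check_unique(list(data.columns), "sample")
        values = data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite {self._value_name} at probe "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)

    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probe_ids: Sequence):
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"unknown probe ids: {missing[:5]}")
        return type(self)(self.data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Sequence):
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return type(self)(self.data[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.shape[0]} probes x {self.shape[1]} samples)"


class ExpressionMatrix(_Matrix):
    """Probe-set x sample log2 intensity matrix, the carrier between stages."""

    _value_name = "log2 intensity"


class ContrastMatrix(_Matrix):
    """Treated-minus-matched-control log2 differences.

    Columns are exactly the treated (non-control) samples of the source
    metadata; values are unitless log2 ratios.
    """

    _value_name = "log2 contrast"


class SampleMetadata:
    """Per-sample design table: compound, class, batch, matched controls.

    ``matched_control_ids`` holds 1-2 control sample ids for every treated
    sample and is empty for controls themselves. Referential integrity is
    checked on construction.
    """

    COLUMNS = (
        "sample_id",
        "compound",
        "class_label",
        "batch_id",
        "replicate_index",
        "matched_control_ids",
    )

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        table = table.reset_index(drop=True)
        _check_unique(list(table["sample_id"]), "sample")
        ids = set(table["sample_id"])
        compound_of = dict(zip(table["sample_id"], table["compound"]))
        for _, row in table.iterrows():
            ctrls = row["matched_control_ids"]
            if not isinstance(ctrls, (list, tuple)):
                raise ValidationError(
                    f"matched_control_ids of {row['sample_id']!r} must be a list"
                )
            if row["compound"] == CONTROL:
                if ctrls:
                    raise ValidationError(
                        f"control sample {row['sample_id']!r} lists matched controls"
                    )
                if row["class_label"] != CONTROL:
                    raise ValidationError(
                        f"control sample {row['sample_id']!r} has class "
                        f"{row['class_label']!r}"
                    )
                continue
            if not ctrls:
                raise PairingError(
                    f"treated sample {row['sample_id']!r} has no matched control"
                )
            for c in ctrls:
                if c not in ids:
                    raise ValidationError(
                        f"matched control {c!r} of {row['sample_id']!r} "
                        "is not a known sample"
                    )
                if compound_of[c] != CONTROL:
                    raise ValidationError(
                        f"matched control {c!r} of {row['sample_id']!r} "
                        "is not a control sample"
                    )
            if int(row["replicate_index"]) < 1:
                raise ValidationError(
                    f"replicate_index of {row['sample_id']!r} must be >= 1"
                )
        self.table = table

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def treated_ids(self) -> list:
        t = self.table
        return list(t.loc[t["compound"] != CONTROL, "sample_id"])

    @property
    def control_ids(self) -> list:
        t = self.table
        return list(t.loc[t["compound"] == CONTROL, "sample_id"])

    @property
    def compounds(self) -> list:
        """Unique treated compounds in first-appearance order."""
        out = []
        for c in self.table["compound"]:
            if c != CONTROL and c not in out:
                out.append(c)
        return out

    def class_of(self, compound: str) -> str:
        t = self.table
        labels = set(t.loc[t["compound"] == compound, "class_label"])
        if len(labels) != 1:
            raise ValidationError(
                f"compound {compound!r} maps to class labels {sorted(labels)}"
            )
        return labels.pop()

    def samples_of(self, compound: str) -> list:
        t = self.table
        return list(t.loc[t["compound"] == compound, "sample_id"])

    def controls_of(self, sample_id: str) -> list:
        t = self.table
        row = t.loc[t["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        return list(row.iloc[0]["matched_control_ids"])

    def batch_of(self, sample_id: str):
        t = self.table
        row = t.loc[t["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        return row.iloc[0]["batch_id"]

    @property
    def batch_ids(self) -> pd.Series:
        return self.table.set_index("sample_id")["batch_id"]

    def subset_compounds(self, compounds: Iterable[str]) -> "SampleMetadata":
        keep = set(compounds)
        t = self.table
        mask = (t["compound"].isin(keep)) | (t["compound"] == CONTROL)
        return SampleMetadata(t.loc[mask].reset_index(drop=True))

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return (
            f"SampleMetadata({len(self.treated_ids)} treated + "
            f"{len(self.control_ids)} control samples, "
            f"{len(self.compounds)} compounds)"
        )


class ProbeAnnotation:
    """Many-to-one probe-set -> gene-symbol map.

    Probes mapped to ``None`` (blank in the TSV) are explicitly unannotated
    and never contribute to gene-level calls.
    """

    def __init__(self, mapping: Mapping[str, str | None]):
        self.mapping = dict(mapping)

    def symbol(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def is_annotated(self, probe_id: str) -> bool:
        return self.mapping.get(probe_id) is not None

    @property
    def annotated_probes(self) -> list:
        return [p for p, g in self.mapping.items() if g is not None]

    def probes_of(self, gene: str) -> list:
        return [p for p, g in self.mapping.items() if g == gene]

    @property
    def genes(self) -> list:
        """Unique gene symbols in first-appearance order."""
        out = []
        for g in self.mapping.values():
            if g is not None and g not in out:
                out.append(g)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeAnnotation) and self.mapping == other.mapping

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols, optionally tagged with a direction."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    direction: str | None = None  # "up" / "down" / None

    def __post_init__(self):
        _check_unique(self.genes, f"gene (set {self.name!r})")
        if self.direction not in (None, "up", "down"):
            raise ValidationError(f"invalid direction {self.direction!r}")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)
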