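"""Data model and TSV I/O for fold-change matrices, instance metadata and
drug-target annotations.

The three on-disk formats are plain tab-separated UTF-8 text:

* expression matrix — first column header ``gene_id``, remaining columns one
  per instance; body is strictly positive linear fold-change ratios
  (treatment/control), never log ratios;
* instance table — columns ``instance_id``, ``batch_id``, ``compound_id`` and
  optionally ``cell_line``, ``dose``;
* drug-target map — columns ``compound_id``, ``target_id``.

Validation is total: every invariant is checked at read time and raises
:class:`DataValidationError`; nothing is silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "ExpressionMatrix",
    "InstanceTable",
    "DrugTargetMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_instance_table",
    "write_instance_table",
    "read_drug_target_map",
    "write_drug_target_map",
]


class DataValidationError(ValueError):
    """Raised when an input file or in-memory table violates an invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x instances matrix of linear fold-change ratios (> 0).

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per instance id.
        All values must be finite and strictly positive; logs are taken
        internally by downstream stages, never stored here.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene_ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate instance_ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("expression matrix body must be numeric")
        bad = ~(np.isfinite(values) & (values > 0))
        if bad.any():
            g, i = np.argwhere(bad)[0]
            raise DataValidationError(
                "expression values must be finite positive ratios; "
                f"offending cell gene={df.index[g]!r} instance={df.columns[i]!r} "
                f"value={values[g, i]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def instance_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_instances(self) -> int:
        return self.data.shape[1]

    def log2(self) -> pd.DataFrame:
        """The matrix on log2 scale (all internal arithmetic lives there)."""
        return np.log2(self.data)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x instances TSV of positive fold-change ratios.

    The first row holds instance ids, the first column gene ids; the first
    column header must be ``gene_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise DataValidationError(
            f"{path}: first column header must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise DataValidationError(
                f"{path}: non-numeric value in instance {col!r} at gene {gene!r}"
            )
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Instance metadata
# ---------------------------------------------------------------------------

_REQUIRED_META = ("instance_id", "batch_id", "compound_id")
_OPTIONAL_META = ("cell_line", "dose")


@dataclass
class InstanceTable:
    """Per-instance metadata: batch and compound, the key to finding bridges."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _REQUIRED_META if c not in df.columns]
        if missing:
            raise DataValidationError(f"instance table missing columns: {missing}")
        if df["instance_id"].duplicated().any():
            dups = df.loc[df["instance_id"].duplicated(), "instance_id"].tolist()
            raise DataValidationError(f"duplicate instance_ids: {dups}")
        for col in ("batch_id", "compound_id"):
            empty = df[col].isna() | (df[col].astype(str).str.len() == 0)
            if empty.any():
                rows = df.loc[empty, "instance_id"].tolist()
                raise DataValidationError(
                    f"empty {col} for instance(s) {rows}"
                )
        self.data = df.reset_index(drop=True)

    @property
    def instance_ids(self) -> list[str]:
        return list(self.data["instance_id"])

    @property
    def batch_ids(self) -> list[str]:
        return sorted(self.data["batch_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())

    def batch_of(self) -> dict[str, str]:
        return dict(zip(self.data["instance_id"], self.data["batch_id"]))

    def compound_of(self) -> dict[str, str]:
        return dict(zip(self.data["instance_id"], self.data["compound_id"]))

    def instances_in_batch(self, batch_id: str) -> list[str]:
        sel = self.data["batch_id"] == batch_id
        return list(self.data.loc[sel, "instance_id"])

    def instances_of_compound(self, compound_id: str) -> list[str]:
        sel = self.data["compound_id"] == compound_id
        return list(self.data.loc[sel, "instance_id"])

    def batch_sizes(self) -> dict[str, int]:
        return self.data["batch_id"].value_counts().to_dict()

    def equals(self, other: "InstanceTable") -> bool:
        return self.data.equals(other.data)


def read_instance_table(path: str | Path) -> InstanceTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required column(s) {missing}")
    keep = [c for c in (*_REQUIRED_META, *_OPTIONAL_META) if c in df.columns]
    return InstanceTable(df[keep])


def write_instance_table(meta: InstanceTable, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Drug-target annotation
# ---------------------------------------------------------------------------


@dataclass
class DrugTargetMap:
    """Deduplicated (compound_id, target_id) annotation, queryable both ways.

    Compound identity is the id string verbatim — no synonym resolution.
    """

    pairs: pd.DataFrame
    _by_target: dict[str, set[str]] = field(init=False, repr=False)
    _by_compound: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.pairs
        missing = [c for c in ("compound_id", "target_id") if c not in df.columns]
        if missing:
            raise DataValidationError(f"drug-target map missing columns: {missing}")
        bad = df["compound_id"].eq("") | df["target_id"].eq("")
        if bad.any():
            raise DataValidationError("empty compound_id or target_id in annotation")
        df = (
            df[["compound_id", "target_id"]]
            .drop_duplicates()
            .sort_values(["compound_id", "target_id"])
            .reset_index(drop=True)
        )
        self.pairs = df
        self._by_target = {}
        self._by_compound = {}
        for c, t in df.itertuples(index=False):
            self._by_target.setdefault(t, set()).add(c)
            self._by_compound.setdefault(c, set()).add(t)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self._by_target)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self._by_compound)

    def ligands(self, target_id: str) -> set[str]:
        """Compounds annotated to ``target_id`` (empty set if absent)."""
        return set(self._by_target.get(target_id, set()))

    def targets(self, compound_id: str) -> set[str]:
        return set(self._by_compound.get(compound_id, set()))

    def shared_ligands(self, target_a: str, target_b: str) -> set[str]:
        return self.ligands(target_a) & self.ligands(target_b)

    def __len__(self) -> int:
        return len(self.pairs)

    def equals(self, other: "DrugTargetMap") -> bool:
        return self.pairs.equals(other.pairs)


def read_drug_target_map(path: str | Path) -> DrugTargetMap:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["compound_id", "target_id"]:
            raise DataValidationError(
                f"{path}: header must start with compound_id\ttarget_id, got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header) or not fields[0] or not fields[1]:
                raise DataValidationError(f"{path}: malformed row at line {lineno}: {line!r}")
            rows.append(fields[:2])
    df = pd.DataFrame(rows, columns=["compound_id", "target_id"], dtype=str)
    return DrugTargetMap(df)


def write_drug_target_map(dtm: DrugTargetMap, path: str | Path) -> None:
    dtm.pairs.to_csv(path, sep="\t", index=False)


def check_consistency(expr: ExpressionMatrix, meta: InstanceTable) -> None:
    """Every matrix instance must be described in the metadata table."""
    known = set(meta.instance_ids)
    orphans = [i for i in expr.instance_ids if i not in known]
    if orphans:
        raise DataValidationError(
            f"instances present in matrix but absent from metadata: {orphans[:5]}"
        )
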