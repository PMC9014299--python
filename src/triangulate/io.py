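"""Tab-separated readers and writers for the pipeline's tables.

Two p-value layouts are accepted, both with a header row and missing
values encoded as empty fields or "NA":

* wide — columns ``trait`` and ``tissue`` followed by one p-value column
  per method;
* long — columns ``trait``, ``tissue``, ``method``, ``pvalue``.

Binary matrices, ROC tables and atlas tables are written as TSV with
6-decimal numeric formatting; fit results as flat ``key<TAB>value`` text
at full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSummary
from .model import BinaryOutcomeMatrix, FitResult
from .sweep import PValueMatrix

__all__ = [
    "read_pvalue_table",
    "write_pvalue_table",
    "read_binary_matrix",
    "write_binary_matrix",
    "write_fit_result",
    "write_roc_table",
    "write_atlas",
]

_NA = ["", "NA"]


def _pair_tuples(df: pd.DataFrame):
    return [tuple(x) for x in df[["trait", "tissue"]].itertuples(index=False)]


def read_pvalue_table(path, layout: str = "wide") -> PValueMatrix:
    """Read a TSV p-value table in wide or long layout."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    if layout == "wide":
        required = {"trait", "tissue"}
        if not required.issubset(df.columns):
            raise ValueError(f"wide layout requires columns {sorted(required)}")
        if df.duplicated(["trait", "tissue"]).any():
            raise ValueError("duplicate (trait, tissue) rows in wide table")
        methods = [c for c in df.columns if c not in required]
        if not methods:
            raise ValueError("wide table has no p-value columns")
        values = df[methods].to_numpy(dtype=float)
        pairs = _pair_tuples(df)
    elif layout == "long":
        required = {"trait", "tissue", "method", "pvalue"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        if df.duplicated(["trait", "tissue", "method"]).any():
            raise ValueError("duplicate (trait, tissue, method) entries in long table")
        wide = df.pivot(index=["trait", "tissue"], columns="method", values="pvalue")
        methods = list(wide.columns)
        values = wide.to_numpy(dtype=float)
        pairs = list(wide.index)
    else:
        raise ValueError("layout must be 'wide' or 'long'")

    finite = values[~np.isnan(values)]
    bad = (finite < 0) | (finite > 1)
    if bad.any():
        offender = finite[bad][0]
        raise ValueError(f"p-value {offender} outside [0, 1] in {path}")
    return PValueMatrix(values=values, pair_labels=pairs, method_labels=methods)


def write_pvalue_table(pmatrix: PValueMatrix, path) -> None:
    """Write a p-value matrix in the wide TSV layout."""
    df = pd.DataFrame(pmatrix.values, columns=list(pmatrix.method_labels))
    trait, tissue = zip(*(_split_pair(p) for p in pmatrix.pair_labels))
    df.insert(0, "tissue", tissue)
    df.insert(0, "trait", trait)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _split_pair(label):
    if isinstance(label, tuple) and len(label) == 2:
        return label
    return (str(label), str(label))


def read_binary_matrix(path) -> BinaryOutcomeMatrix:
    df = pd.read_csv(path, sep="\t")
    methods = [c for c in df.columns if c not in ("trait", "tissue")]
    return BinaryOutcomeMatrix(
        values=df[methods].to_numpy(),
        pair_labels=_pair_tuples(df) if "tissue" in df.columns else (),
        method_labels=methods,
    )


def write_binary_matrix(matrix: BinaryOutcomeMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.method_labels))
    trait, tissue = zip(*(_split_pair(p) for p in matrix.pair_labels))
    df.insert(0, "tissue", tissue)
    df.insert(0, "trait", trait)
    df.to_csv(path, sep="\t", index=False)


def write_fit_result(fit: FitResult, path, boot: BootstrapSummary | None = None) -> None:
    """Flat key<TAB>value text file with full-precision estimates."""
    items = fit.to_flat_dict()
    if boot is not None:
        items.update(boot.to_flat_dict())
    with open(path, "w") as fh:
        for key, value in items.items():
            if isinstance(value, float):
                fh.write(f"{key}\t{value!r}\n")
            else:
                fh.write(f"{key}\t{value}\n")


def write_roc_table(roc: pd.DataFrame, path) -> None:
    roc.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_atlas(scored: pd.DataFrame, path) -> None:
    """Atlas table: one row per pair with calls, S, FDR and the <0.05 flag."""
    out = scored.copy()
    if "pair" in out.columns:
        trait, tissue = zip(*(_split_pair(p) for p in out["pair"]))
        out.insert(0, "tissue", tissue)
        out.insert(0, "trait", trait)
        out = out.drop(columns="pair")
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
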