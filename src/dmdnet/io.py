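"""Readers and writers for the plain-text dialects used by the pipeline.

Formats: GMT gene-set libraries, expression matrices with companion design
files, and the small TSV tables (gene--disease associations, drug--gene
interactions, drug--target edges).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_drug_target_table",
]


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into ``(name, description, genes)`` records."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        records.append((name, desc, genes))
    return records


def write_gmt(path: str | Path,
              sets: Iterable[tuple[str, Sequence[str]] | tuple[str, str, Sequence[str]]]) -> None:
    """Write gene sets as GMT; entries are (name, genes) or (name, desc, genes)."""
    lines = []
    for entry in sets:
        if len(entry) == 2:
            name, genes = entry  # type: ignore[misc]
            desc = "na"
        else:
            name, desc, genes = entry  # type: ignore[misc]
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(expr_path: str | Path, design_path: str | Path
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Read an expression TSV (first column ``gene``) and its design file.

    The design file has two columns ``sample<TAB>group`` with group in
    {control, case}; a header row is accepted.  Returns the genes-by-samples
    matrix and the per-sample group series, aligned on sample names.
    """
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    design = pd.read_csv(design_path, sep="\t", header=None, names=["sample", "group"])
    if design.iloc[0].tolist() == ["sample", "group"]:
        design = design.iloc[1:]
    design = design.astype(str)
    bad = set(design["group"]) - {"control", "case"}
    if bad:
        raise ValueError(f"{design_path}: groups must be control/case, found {sorted(bad)}")
    groups = design.set_index("sample")["group"]
    missing = set(groups.index) - set(matrix.columns)
    if missing:
        raise ValueError(f"{design_path}: samples absent from matrix: {sorted(missing)[:5]}")
    return matrix.loc[:, groups.index.tolist()], groups


def write_expression(expr_path: str | Path, design_path: str | Path,
                     matrix: pd.DataFrame, groups: pd.Series) -> None:
    matrix.to_csv(expr_path, sep="\t", index_label="gene")
    groups.rename("group").rename_axis("sample").to_csv(design_path, sep="\t", header=False)


def read_drug_target_table(path: str | Path) -> pd.DataFrame:
    """Read a drug--target TSV with columns ``drug, gene, source``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug", "gene", "source"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    return df[["drug", "gene", "source"]]
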