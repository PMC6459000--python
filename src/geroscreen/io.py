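"""Readers and writers for the screen's exchange formats.

Expression matrices travel as GCT 1.2 (two header lines, ``#1.2`` then
``<rows>\\t<cols>``, then a Name/Description header).  Sample
attributes use the GTEx v6 tab-delimited dialect (SMTSD tissue, GENDER,
AGE_BIN, SMRIN quality score, SMAFRZE usable flag).  Perturbations,
truth labels, survival tables and `animal_position.csv` position logs
are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from geroscreen.matrix import ExpressionMatrix

# GTEx v6 attribute dialect <-> internal metadata columns
_ATTR_COLS = {
    "SMTSD": "tissue",
    "GENDER": "gender",
    "AGE_BIN": "age_bin",
    "SMRIN": "rin",
    "SMAFRZE": "usable",
}
_USABLE_FLAG = "USE ME"
_UNUSABLE_FLAG = "EXCLUDE"


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x samples matrix as GCT 1.2; the Description
    column repeats the gene id."""
    path = Path(path)
    n_rows, n_cols = matrix.values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.samples) + "\n")
        for gene, row in zip(matrix.genes, matrix.values.to_numpy()):
            fh.write(gene + "\t" + gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gct(path: str | Path, stage: str = "linear") -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: header promises {n_rows}x{n_cols} but body is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    df.index.name = None
    return ExpressionMatrix(df, stage=stage)


def write_sample_attributes(metadata: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "SAMPID": metadata.index,
            "SMTSD": metadata["tissue"].to_numpy(),
            "GENDER": metadata["gender"].to_numpy(),
            "AGE_BIN": metadata["age_bin"].to_numpy(),
            "SMRIN": metadata["rin"].to_numpy(),
            "SMAFRZE": [
                _USABLE_FLAG if u else _UNUSABLE_FLAG
                for u in metadata["usable"].astype(bool)
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sample_attributes(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    missing = ({"SAMPID"} | set(_ATTR_COLS)) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: attribute table missing columns {sorted(missing)}")
    meta = raw.set_index("SAMPID").rename(columns=_ATTR_COLS)[list(_ATTR_COLS.values())]
    meta.index.name = "sample_id"
    meta["usable"] = meta["usable"].astype(str).str.strip().eq(_USABLE_FLAG)
    meta["rin"] = meta["rin"].astype(float)
    return meta


def write_perturbations(
    table: pd.DataFrame, labels: pd.Series | None, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "perturbations.csv", index=False)
    if labels is not None:
        labels.rename("label").to_csv(out / "perturbation_labels.csv")


def read_perturbations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "drug" not in table.columns:
        raise ValueError(f"{path}: perturbation table lacks a 'drug' column")
    return table


def read_labels(path: str | Path) -> pd.Series:
    return pd.read_csv(path, index_col=0)["label"]


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"worm", "arm", "day", "censored"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: survival table missing columns {sorted(missing)}")
    if "plate" not in table.columns:
        table["plate"] = table["arm"]
    return table


def write_positions(positions: pd.DataFrame, path: str | Path) -> None:
    """Write the position log; by convention the file is named
    `animal_position.csv`."""
    positions.to_csv(path, index=False)


def read_positions(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"plate", "timepoint", "x", "y"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: position log missing columns {sorted(missing)}")
    return table


def read_known_set(path: str | Path) -> set[str]:
    """One drug name per line (or a single-column CSV with header
    'drug')."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower() == "drug":
        lines = lines[1:]
    return set(lines)
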