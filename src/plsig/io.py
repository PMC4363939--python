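"""Readers and writers for the package's plain-text table formats.

Formats
-------
Expression TSV (one file per tissue/group/week):
    probe_id  gene_symbol  rep1  rep2  rep3  geom_mean  p_value
    (log2 ratios vs the normal-diet control; the geometric mean of the
    intensity ratios is the arithmetic mean in log2 space)
Phenotype CSV: group, week, body_weight, blood_glucose, cytokine columns.
Master-list TSV: gene_symbol, expression, p_value, reg_class.
Design TSV: one row per (group, input week); "NA" marks missing entries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import PROBE_COLUMNS, DesignMatrix, MasterList

FLOAT_FMT = "%.8g"  # at least 6 significant digits, round-trip stable

PRO_CYTOKINES = [
    "GM_CSF", "IFNg", "IL1a", "IL1b", "IL6", "MCP1", "TNFa", "IL12p70",
]
ANTI_CYTOKINES = ["IL4", "IL10", "IL13"]
MEASURES = ["body_weight", "blood_glucose"] + PRO_CYTOKINES + ANTI_CYTOKINES
PHENOTYPE_COLUMNS = ["group", "week"] + MEASURES


def expression_filename(tissue: str, group: str, week: int) -> str:
    return f"expr_{tissue}_{group}_wk{week}.tsv"


def write_expression_tsv(table: pd.DataFrame, path) -> None:
    table = table[PROBE_COLUMNS]
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    except OSError as exc:
        raise OSError(f"cannot read expression table {path}") from exc
    missing = [c for c in PROBE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return table[PROBE_COLUMNS]


def write_phenotype_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_phenotype_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"group": str})
    except OSError as exc:
        raise OSError(f"cannot read phenotype table {path}") from exc
    if "group" not in table.columns or "week" not in table.columns:
        raise ValueError(f"{path}: phenotype table needs group and week columns")
    return table


def write_master_list(master: MasterList, path) -> None:
    master.entries.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_master_list(path, week: int) -> MasterList:
    entries = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    return MasterList(week=int(week), entries=entries)


def write_design_tsv(design: DesignMatrix, path) -> None:
    frame = pd.concat([design.X, design.Y], axis=1)
    frame.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT)


def read_design_tsv(path, n_responses: int, protocol: str = "union") -> DesignMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=[0, 1], na_values=["NA"])
    X = frame.iloc[:, : frame.shape[1] - n_responses]
    Y = frame.iloc[:, frame.shape[1] - n_responses:]
    return DesignMatrix(X=X, Y=Y, protocol=protocol)
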