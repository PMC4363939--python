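"""Probe-level noise filtration and design-matrix assembly.

Expression arrives as probe-level log2 ratios of a treatment group against
the normal-diet (ND) control, three replicate values per probe plus their
geometric mean and a p-value.  A gene is called significantly regulated when
|log2 ratio| exceeds a threshold (default 1, i.e. two-fold).  The cleaning
cascade is:

1. keep probes whose three replicates agree in regulation class
   (by default only unanimously up- or down-regulated probes survive);
2. collapse genes measured by several probes to the probe with the
   smallest p-value;

yielding the per-week *master list* of noise-free, non-redundant genes.
Master lists from two early weeks are then assembled into a PLS design
matrix under either the intersection protocol (genes present in every
group/week list) or the union protocol (genes present in any list, absent
entries marked missing).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegulationClass",
    "MasterList",
    "DesignMatrix",
    "classify_regulation",
    "filter_consistent",
    "dedup_probes",
    "build_master_list",
    "assemble_design",
    "PROBE_COLUMNS",
]

PROBE_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "rep1",
    "rep2",
    "rep3",
    "geom_mean",
    "p_value",
]

REPLICATE_COLUMNS = ["rep1", "rep2", "rep3"]


class RegulationClass(str, enum.Enum):
    """Direction of differential expression relative to control."""

    UP = "up"
    DOWN = "down"
    INSIGNIFICANT = "insignificant"


def classify_regulation(x: float, threshold: float = 1.0) -> RegulationClass:
    """Classify a log2 ratio as up / down / insignificant.

    Strict inequalities: exactly ±threshold is insignificant.
    """
    if not np.isfinite(x):
        raise ValueError(f"log2 ratio must be finite, got {x!r}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if x > threshold:
        return RegulationClass.UP
    if x < -threshold:
        return RegulationClass.DOWN
    return RegulationClass.INSIGNIFICANT


def _class_codes(values: np.ndarray, threshold: float) -> np.ndarray:
    """Vectorized regulation codes: +1 up, -1 down, 0 insignificant."""
    if not np.isfinite(values).all():
        raise ValueError("log2 ratios must be finite")
    return np.where(values > threshold, 1, np.where(values < -threshold, -1, 0))


def filter_consistent(
    table: pd.DataFrame,
    threshold: float = 1.0,
    keep_insignificant: bool = False,
) -> pd.DataFrame:
    """Keep probes whose replicates agree in regulation class.

    A probe survives iff all three replicates fall in the same class;
    unanimously insignificant probes are dropped unless
    ``keep_insignificant`` is set.  Idempotent.
    """
    if table.empty:
        return table.copy()
    reps = table[REPLICATE_COLUMNS].to_numpy(dtype=float)
    codes = _class_codes(reps, threshold)
    unanimous = (codes == codes[:, [0]]).all(axis=1)
    keep = unanimous & (keep_insignificant | (codes[:, 0] != 0))
    return table.loc[keep].copy()


def dedup_probes(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate probes per gene to the minimum-p-value probe.

    Exact p ties break to the lexicographically smallest probe_id.  Input
    is expected to be consistency-filtered already.
    """
    if records.empty:
        return records.copy()
    ordered = records.sort_values(
        ["gene_symbol", "p_value", "probe_id"], kind="mergesort"
    )
    return ordered.drop_duplicates("gene_symbol", keep="first").reset_index(
        drop=True
    )


@dataclass
class MasterList:
    """Per-week noise-filtered, deduplicated gene-level expression."""

    week: int
    entries: pd.DataFrame  # gene_symbol, expression, p_value, reg_class

    @property
    def genes(self) -> set:
        return set(self.entries["gene_symbol"])

    def expression_map(self) -> pd.Series:
        return self.entries.set_index("gene_symbol")["expression"]

    def to_frame(self) -> pd.DataFrame:
        return self.entries.copy()


def build_master_list(
    table: pd.DataFrame,
    week: int,
    threshold: float = 1.0,
    keep_insignificant: bool = False,
) -> MasterList:
    """filter_consistent → dedup_probes → gene-level master list.

    The gene's expression is the probe's geometric-mean log2 ratio (the
    value the p-value refers to).
    """
    consistent = filter_consistent(
        table, threshold=threshold, keep_insignificant=keep_insignificant
    )
    unique = dedup_probes(consistent)
    if unique.empty:
        entries = pd.DataFrame(
            columns=["gene_symbol", "expression", "p_value", "reg_class"]
        )
    else:
        codes = _class_codes(
            unique["geom_mean"].to_numpy(dtype=float), threshold
        )
        entries = pd.DataFrame(
            {
                "gene_symbol": unique["gene_symbol"].to_numpy(),
                "expression": unique["geom_mean"].to_numpy(dtype=float),
                "p_value": unique["p_value"].to_numpy(dtype=float),
                "reg_class": [
                    {1: "up", -1: "down", 0: "insignificant"}[c] for c in codes
                ],
            }
        )
    return MasterList(week=int(week), entries=entries)


@dataclass
class DesignMatrix:
    """PLS-ready predictor block with attached responses.

    ``X`` rows are (group, input week) observations over a common gene
    column set; missing markers (NaN) appear only under the union
    protocol.  ``Y`` carries the response value(s) at the critical output
    week(s), repeated across a group's rows.
    """

    X: pd.DataFrame  # MultiIndex (group, week) rows × gene columns
    Y: pd.DataFrame  # same row index × response columns
    protocol: str

    @property
    def genes(self) -> list:
        return list(self.X.columns)


def _response_frame(
    phenotypes: pd.DataFrame,
    groups: Sequence[str],
    response_spec: Sequence[tuple],
) -> Mapping[str, dict]:
    """Per-group response values: spec entries are (measure, output_week)."""
    idx = phenotypes.set_index(["group", "week"])
    out = {}
    for g in groups:
        row = {}
        for measure, week in response_spec:
            try:
                row[f"{measure}@wk{week}"] = float(idx.loc[(g, week), measure])
            except KeyError as exc:
                raise KeyError(
                    f"phenotype {measure!r} at week {week} missing for "
                    f"group {g!r}"
                ) from exc
        out[g] = row
    return out


def assemble_design(
    master_lists: Mapping[tuple, MasterList],
    phenotypes: pd.DataFrame,
    protocol: str = "intersection",
    input_weeks: Sequence[int] = (3, 6),
    response_spec: Sequence[tuple] = (("body_weight", 15),),
    groups: Sequence[str] | None = None,
    control_group: str = "ND",
) -> DesignMatrix:
    """Assemble the two-week PLS design matrix from master lists.

    Parameters
    ----------
    master_lists : mapping (group, week) -> MasterList
        Required for every non-control group at both input weeks.  The
        control group needs no lists: its log2 ratios are identically 0
        (expression is measured relative to it).
    protocol : {"intersection", "union"}
        Gene columns common to all non-control (group, week) lists, or
        present in any of them (absent entries become NaN).
    response_spec : sequence of (measure, output_week)
        Response columns; each group's rows repeat its output-week
        value(s).
    """
    if protocol not in ("intersection", "union"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if len(input_weeks) != 2:
        raise ValueError("exactly two input weeks are required")
    if groups is None:
        groups = sorted({g for g, _ in master_lists})
        if control_group in set(phenotypes["group"]):
            groups = [control_group] + [g for g in groups if g != control_group]
    test_groups = [g for g in groups if g != control_group]

    gene_sets = []
    for g in test_groups:
        for w in input_weeks:
            if (g, w) not in master_lists:
                raise KeyError(f"missing master list for group {g!r} week {w}")
            gene_sets.append(master_lists[(g, w)].genes)
    if protocol == "intersection":
        genes = set.intersection(*gene_sets) if gene_sets else set()
        if not genes:
            raise ValueError(
                "no common genes across the master lists under the "
                "intersection protocol"
            )
    else:
        genes = set.union(*gene_sets) if gene_sets else set()
    columns = sorted(genes)

    rows, index = [], []
    for g in groups:
        for w in input_weeks:
            if g == control_group:
                values = pd.Series(0.0, index=columns)
            else:
                expr = master_lists[(g, w)].expression_map()
                values = expr.reindex(columns)
                if protocol == "intersection" and values.isna().any():
                    # cannot happen by construction of the intersection
                    raise AssertionError("intersection design has missing")
            rows.append(values)
            index.append((g, w))
    X = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["group", "week"]))

    responses = _response_frame(phenotypes, groups, response_spec)
    Y = pd.DataFrame(
        [responses[g] for g, _ in index],
        index=X.index,
    )
    return DesignMatrix(X=X, Y=Y, protocol=protocol)
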