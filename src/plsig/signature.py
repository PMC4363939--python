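"""Per-tissue, per-parameter signature training and blind prediction.

Each physiological parameter gets its own model: gene expression from the
two early input weeks (3 and 6) predicts the parameter at its critical
output week — week 15 for body weight, week 12 for blood glucose, and the
combined weeks 9 and 12 for the cytokine panels (each cytokine at each
output week is a parallel response column).  Training first tries the
intersection gene protocol; if the model fails the predictivity gate
(cross-validated Q2 > 0.5) it falls back to the union protocol, whose
missing entries the NIPALS engine absorbs.  A trained signature is then
applied blind: a held-out group's week-3 and week-6 expression each give
one prediction, with genes lost to noise filtration entered as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ANTI_CYTOKINES, PRO_CYTOKINES
from .pls import Diagnostics, PLSNipals, select_and_refit
from .preprocess import DesignMatrix, MasterList, assemble_design

__all__ = ["ModelSpec", "TrainedSignature", "train", "predict_blind",
           "PARAMETERS", "Q2_GATE"]

Q2_GATE = 0.5

# parameter -> response columns as (measure, output week); the output
# weeks are the phenotypes' critical weeks
PARAMETERS = {
    "body_weight": [("body_weight", 15)],
    "blood_glucose": [("blood_glucose", 12)],
    "pro_cytokines": [(c, w) for w in (9, 12) for c in PRO_CYTOKINES],
    "anti_cytokines": [(c, w) for w in (9, 12) for c in ANTI_CYTOKINES],
}

DEFAULT_TRAINING_GROUPS = ["ND", "HFHSD", "KAL-20", "KAL-75"]


@dataclass
class ModelSpec:
    """What to train: tissue, parameter, weeks and gene-list protocol."""

    tissue: str = "skeletal"
    parameter: str = "body_weight"
    input_weeks: tuple = (3, 6)
    protocol: str = "auto"  # auto | intersection | union
    training_groups: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_TRAINING_GROUPS)
    )
    include_control: bool = True
    control_group: str = "ND"
    vip_cutoff: float = 1.0
    cv_folds: int = 7
    cv_seed: int = 0

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of "
                f"{sorted(PARAMETERS)}"
            )
        if self.protocol not in ("auto", "intersection", "union"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @property
    def response_spec(self):
        return PARAMETERS[self.parameter]

    @property
    def output_weeks(self):
        return sorted({w for _, w in self.response_spec})

    def groups(self):
        gs = list(self.training_groups)
        if not self.include_control:
            gs = [g for g in gs if g != self.control_group]
        return gs


@dataclass
class TrainedSignature:
    """A fitted signature: selected genes, refit model and its verdict."""

    spec: ModelSpec
    genes: list
    model: PLSNipals | None
    diagnostics: Diagnostics | None
    worked: bool
    protocol_used: str | None
    full_diagnostics: Diagnostics | None = None
    attempts: dict = field(default_factory=dict)


def _attempt(spec: ModelSpec, master_lists, phenotypes, protocol: str):
    design = assemble_design(
        master_lists,
        phenotypes,
        protocol=protocol,
        input_weeks=spec.input_weeks,
        response_spec=spec.response_spec,
        groups=spec.groups(),
        control_group=spec.control_group,
    )
    genes, refit, diags = select_and_refit(
        design.X,
        design.Y,
        cutoff=spec.vip_cutoff,
        folds=min(spec.cv_folds, design.X.shape[0]),
        seed=spec.cv_seed,
    )
    return genes, refit, diags, design


def train(spec: ModelSpec, master_lists: Mapping[tuple, MasterList],
          phenotypes: pd.DataFrame) -> TrainedSignature:
    """Train one signature model, falling back to the union protocol.

    The protocol order is intersection first (auto), then union when the
    intersection model misses the Q2 > 0.5 gate or cannot be built at
    all.  When both protocols fail, the returned signature has
    ``worked=False`` and carries the better attempt's diagnostics.
    """
    protocols = (
        [spec.protocol]
        if spec.protocol in ("intersection", "union")
        else ["intersection", "union"]
    )
    attempts = {}
    for protocol in protocols:
        try:
            genes, refit, diags, design = _attempt(
                spec, master_lists, phenotypes, protocol
            )
        except (ValueError, KeyError) as exc:
            attempts[protocol] = {"error": str(exc), "q2": -np.inf}
            continue
        q2 = diags["selected"].q2
        attempts[protocol] = {
            "genes": genes,
            "model": refit,
            "diagnostics": diags,
            "q2": q2,
        }
        if q2 > Q2_GATE:
            return TrainedSignature(
                spec=spec,
                genes=genes,
                model=refit,
                diagnostics=diags["selected"],
                worked=True,
                protocol_used=protocol,
                full_diagnostics=diags["full"],
                attempts={p: a.get("q2") for p, a in attempts.items()},
            )
    # no protocol passed the gate: report the best attempt
    best = max(attempts, key=lambda p: attempts[p]["q2"])
    info = attempts[best]
    return TrainedSignature(
        spec=spec,
        genes=info.get("genes", []),
        model=info.get("model"),
        diagnostics=(info["diagnostics"]["selected"]
                     if "diagnostics" in info else None),
        worked=False,
        protocol_used=best if "model" in info else None,
        full_diagnostics=(info["diagnostics"]["full"]
                          if "diagnostics" in info else None),
        attempts={p: a.get("q2") for p, a in attempts.items()},
    )


def predict_blind(trained: TrainedSignature,
                  blind_lists: Mapping[int, MasterList]) -> pd.DataFrame:
    """Predict the output-week phenotype(s) from a blind group's lists.

    ``blind_lists`` maps each input week to the blind group's master list
    for that week.  One prediction row is produced per input week; genes
    filtered out of a blind list enter as missing and contribute nothing
    to the scores (a list missing every signature gene predicts the
    training response mean).
    """
    if not trained.worked or trained.model is None:
        raise ValueError(
            "signature did not pass the predictivity gate; cannot predict"
        )
    rows, index = [], []
    for week in trained.spec.input_weeks:
        if week not in blind_lists:
            raise KeyError(f"no blind master list for input week {week}")
        expr = blind_lists[week].expression_map()
        rows.append(expr.reindex(trained.genes))
        index.append(week)
    X = pd.DataFrame(rows, index=pd.Index(index, name="input_week"))
    X.columns = [str(c) for c in X.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yhat = trained.model.predict(X)
    columns = [f"{m}@wk{w}" for m, w in trained.spec.response_spec]
    return pd.DataFrame(yhat, index=X.index, columns=columns)
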