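"""Study-shaped synthetic microarray and phenotype data with known truth.

The generator emulates a diet-induced obesity time course in mice: five
groups (normal diet ND, high-fat/high-sucrose HFHSD, and three treatment
doses), six timepoints at three-week intervals, three replicate arrays per
probe, and far more genes than observations.  Expression is emitted as
already-normalized log2 ratios against ND, so ND's own ratios are centered
at zero.

A planted set of signature genes carries the disease signal: their
expression scales with a per-group severity (1 for HFHSD, decreasing with
treatment dose, 0 for ND), and each phenotype's deviation from the ND
baseline is an exact linear function of the signature genes' week-3/6
expression.  Phenotype trajectories rise logistically and plateau at the
phenotype's critical week (week 15 for body weight, 12 for blood glucose,
9 for cytokines), after which the HFHSD-vs-ND difference is constant.

Data pathologies of real probe tables are reproduced on demand: a fraction
of genes appear under two probe ids with distinct p-values (exercising
minimum-p deduplication), and a fraction of probes get one replicate
sign-flipped so their replicates disagree in regulation class (exercising
the consistency filter).  Corruption is confined to non-signature probes so
the planted signal remains recoverable by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ANTI_CYTOKINES,
    MEASURES,
    PRO_CYTOKINES,
    expression_filename,
    read_expression_tsv,
    read_phenotype_csv,
    write_expression_tsv,
    write_phenotype_csv,
)
from .preprocess import PROBE_COLUMNS

__all__ = ["StudyDesign", "GroundTruth", "generate_study", "write_fixture"]

DEFAULT_GROUPS = ["ND", "HFHSD", "KAL-5", "KAL-20", "KAL-75"]
DEFAULT_WEEKS = [3, 6, 9, 12, 15, 18]

# Disease severity per group: HFHSD untreated = 1, treatment doses reduce
# it, control = 0.  Unlisted (custom) groups draw a seeded severity.
DEFAULT_SEVERITY = {"ND": 0.0, "HFHSD": 1.0, "KAL-5": 0.8, "KAL-20": 0.55,
                    "KAL-75": 0.3}

CRITICAL_WEEK = {"body_weight": 15, "blood_glucose": 12}
CRITICAL_WEEK.update({c: 9 for c in PRO_CYTOKINES + ANTI_CYTOKINES})

# ND plateau values: body weight 27.5 g and glucose 141 mg/dl at their
# critical weeks (the reference experiment's control values); cytokine
# plateaus at magnitudes typical of serum panels (pg/ml).
ND_PLATEAU = {
    "body_weight": 27.5, "blood_glucose": 141.0,
    "GM_CSF": 55.0, "IFNg": 71.0, "IL1a": 103.0, "IL1b": 54.0, "IL6": 62.0,
    "MCP1": 92.0, "TNFa": 92.0, "IL12p70": 89.0,
    "IL4": 41.0, "IL10": 63.0, "IL13": 66.0,
}
ND_START = {"body_weight": 18.0, "blood_glucose": 130.0}

# Full-severity (HFHSD) deviation from ND at the critical week; positive
# for weight, glucose and pro-inflammatory cytokines, negative for the
# anti-inflammatory panel.
TARGET_DELTA = {"body_weight": 10.5, "blood_glucose": 29.0}
TARGET_DELTA.update({c: 0.5 * ND_PLATEAU[c] for c in PRO_CYTOKINES})
TARGET_DELTA.update({c: -0.35 * ND_PLATEAU[c] for c in ANTI_CYTOKINES})


def _ramp(week: float, critical_week: float) -> float:
    """Logistic rise that reaches (exactly) its plateau at the critical week."""
    if week >= critical_week:
        return 1.0
    z = (week - critical_week / 2.0) * 8.0 / critical_week
    return float((1.0 / (1.0 + np.exp(-z))) / (1.0 / (1.0 + np.exp(-4.0))))


def _baseline(measure: str, week: float) -> float:
    plateau = ND_PLATEAU[measure]
    start = ND_START.get(measure, 0.8 * plateau)
    return start + (plateau - start) * _ramp(week, CRITICAL_WEEK[measure])


@dataclass
class StudyDesign:
    """Parameters of the simulated study.

    The first group in ``groups`` is the control; expression is reported
    as log2 ratio against it.  ``noise_sd`` is the replicate measurement
    noise (log2 units); ``gene_wiggle_sd`` is per-(gene, group, week)
    biological variation of the planted signal, part of the true
    expression and therefore not attenuated when ``noise_sd`` → 0.
    """

    groups: list = field(default_factory=lambda: list(DEFAULT_GROUPS))
    weeks: list = field(default_factory=lambda: list(DEFAULT_WEEKS))
    n_replicates: int = 3
    n_genes: int = 300
    n_signature: int = 20
    duplicate_probe_fraction: float = 0.05
    inconsistent_replicate_fraction: float = 0.05
    noise_sd: float = 0.1
    gene_wiggle_sd: float = 0.15
    effect_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("groups: need a control and at least one test group")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("groups: labels must be unique")
        if any(w2 <= w1 for w1, w2 in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks: must be strictly increasing")
        if self.n_replicates != 3:
            raise ValueError("n_replicates: exactly 3 replicate arrays are modelled")
        if self.n_genes < 0:
            raise ValueError("n_genes: must be nonnegative")
        if not 0 <= self.n_signature <= self.n_genes:
            raise ValueError("n_signature: must be in [0, n_genes]")
        for name in ("duplicate_probe_fraction", "inconsistent_replicate_fraction"):
            frac = getattr(self, name)
            if not 0 <= frac < 1:
                raise ValueError(f"{name}: must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be nonnegative")
        if self.gene_wiggle_sd < 0:
            raise ValueError("gene_wiggle_sd: must be nonnegative")
        if self.effect_scale < 0:
            raise ValueError("effect_scale: must be nonnegative")

    @property
    def control_group(self) -> str:
        return self.groups[0]


@dataclass
class GroundTruth:
    """What was planted: the answer key for downstream recovery tests."""

    signature_genes: set
    coefficients: pd.DataFrame  # signature genes × measures; others are 0
    baseline: pd.DataFrame      # control trajectory, week × measure
    group_effects: pd.DataFrame  # deterministic group × measure deviation
    severity: Mapping[str, float]
    signature_expression: pd.DataFrame  # groups × signature genes (wk3/6 mean)


def _severities(design: StudyDesign, rng: np.random.Generator):
    sev = {}
    for i, g in enumerate(design.groups):
        if i == 0:
            sev[g] = 0.0
        elif g in DEFAULT_SEVERITY:
            sev[g] = DEFAULT_SEVERITY[g]
        else:
            sev[g] = float(rng.uniform(0.3, 1.1))
    return sev


def generate_study(design: StudyDesign):
    """Generate probe tables, phenotypes and the ground truth.

    Returns
    -------
    probe_tables : dict (group, week) -> DataFrame
        Probe-level replicated log2 ratios in the expression-TSV layout.
    phenotypes : DataFrame
        One row per (group, week) with every phenotype measure.
    truth : GroundTruth
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    sev = _severities(design, rng)

    genes = np.array([f"G{i + 1:05d}" for i in range(design.n_genes)])
    sig_idx = rng.choice(design.n_genes, size=design.n_signature, replace=False) \
        if design.n_signature else np.array([], dtype=int)
    sig_idx = np.sort(sig_idx)
    sig_genes = genes[sig_idx]
    directions = rng.choice([-1.0, 1.0], size=design.n_signature)
    magnitudes = rng.uniform(3.5, 5.0, size=design.n_signature)

    # coefficients: dose-positive loadings normalized so a full-severity
    # group's deterministic deviation equals TARGET_DELTA per measure
    raw = rng.uniform(0.5, 1.5, size=(design.n_signature, len(MEASURES)))
    coef = pd.DataFrame(0.0, index=sig_genes, columns=MEASURES)
    if design.n_signature:
        denom = raw.T @ magnitudes  # per measure
        for k, m in enumerate(MEASURES):
            coef[m] = (directions * raw[:, k]
                       * design.effect_scale * TARGET_DELTA[m] / denom[k])

    # true signature expression per (group, week in {first two weeks})
    input_weeks = design.weeks[:2] if len(design.weeks) >= 2 else design.weeks
    true_expr = {}  # (group, week) -> ndarray over all genes
    sig_mean = pd.DataFrame(0.0, index=design.groups, columns=sig_genes)
    for g in design.groups:
        per_week = []
        for w in design.weeks:
            x = np.zeros(design.n_genes)
            if g != design.control_group and design.n_genes:
                x = rng.normal(0.0, 0.45, size=design.n_genes)
                if design.n_signature:
                    x[sig_idx] = directions * magnitudes * sev[g] + rng.normal(
                        0.0, design.gene_wiggle_sd, size=design.n_signature
                    )
            true_expr[(g, w)] = x
            if w in input_weeks:
                per_week.append(x[sig_idx])
        if per_week and design.n_signature:
            sig_mean.loc[g] = np.mean(per_week, axis=0)

    # phenotypes: baseline trajectory + planted linear deviation on a ramp
    baseline = pd.DataFrame(
        {m: [_baseline(m, w) for w in design.weeks] for m in MEASURES},
        index=pd.Index(design.weeks, name="week"),
    )
    delta = sig_mean.to_numpy() @ coef.to_numpy() if design.n_signature else \
        np.zeros((len(design.groups), len(MEASURES)))
    delta = pd.DataFrame(delta, index=design.groups, columns=MEASURES)
    pheno_rows = []
    for g in design.groups:
        for w in design.weeks:
            row = {"group": g, "week": w}
            for m in MEASURES:
                noise = rng.normal(0.0, design.noise_sd * abs(TARGET_DELTA[m]) / 5.0)
                row[m] = (
                    baseline.loc[w, m]
                    + delta.loc[g, m] * _ramp(w, CRITICAL_WEEK[m])
                    + noise
                )
            pheno_rows.append(row)
    phenotypes = pd.DataFrame(pheno_rows, columns=["group", "week"] + MEASURES)

    # probe layout: primary probes, duplicates, corrupted (inconsistent)
    n_dup = int(np.floor(design.duplicate_probe_fraction * design.n_genes))
    dup_idx = np.sort(rng.choice(design.n_genes, size=n_dup, replace=False)) \
        if n_dup else np.array([], dtype=int)
    non_sig = np.setdiff1d(np.arange(design.n_genes), sig_idx)
    n_inc = min(
        int(np.floor(design.inconsistent_replicate_fraction * design.n_genes)),
        non_sig.size,
    )
    inc_idx = np.sort(rng.choice(non_sig, size=n_inc, replace=False)) \
        if n_inc else np.array([], dtype=int)
    inc_flip = rng.integers(0, 3, size=n_inc)  # which replicate to flip
    inc_set = {int(i): int(f) for i, f in zip(inc_idx, inc_flip)}

    probe_tables = {}
    for g in design.groups:
        for w in design.weeks:
            x = true_expr[(g, w)].copy()
            # corrupted probes carry a clearly regulated base value so the
            # sign flip produces genuinely mixed replicate classes
            if g != design.control_group:
                for i in inc_set:
                    x[i] = rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 3.0)
            rows = []
            for i in range(design.n_genes):
                reps = x[i] + rng.normal(0.0, design.noise_sd, size=3)
                if g != design.control_group and i in inc_set:
                    reps[inc_set[i]] = -reps[inc_set[i]]
                rows.append(
                    (f"P{i + 1:05d}", genes[i], reps[0], reps[1], reps[2],
                     reps.mean(), float(rng.uniform(0.0, 0.05)))
                )
            for i in dup_idx:
                reps = x[i] + rng.normal(0.0, design.noise_sd, size=3)
                rows.append(
                    (f"P{i + 1:05d}D", genes[i], reps[0], reps[1], reps[2],
                     reps.mean(), float(rng.uniform(0.0, 0.05)))
                )
            probe_tables[(g, w)] = pd.DataFrame(rows, columns=PROBE_COLUMNS)

    truth = GroundTruth(
        signature_genes=set(sig_genes),
        coefficients=coef,
        baseline=baseline,
        group_effects=delta,
        severity=sev,
        signature_expression=sig_mean,
    )
    return probe_tables, phenotypes, truth


def write_fixture(probe_tables, phenotypes, directory, tissue="skeletal"):
    """Write generated tables to ``directory`` in the package formats.

    Returns the list of written paths.  Files round-trip bit-identically
    through :func:`read_fixture` (floats are written with 8 significant
    digits and re-written unchanged).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    try:
        for (g, w), table in sorted(probe_tables.items()):
            path = directory / expression_filename(tissue, g, w)
            write_expression_tsv(table, path)
            paths.append(path)
        pheno_path = directory / "phenotypes.csv"
        write_phenotype_csv(phenotypes, pheno_path)
        paths.append(pheno_path)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths


def read_fixture(directory, tissue="skeletal"):
    """Read back a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    probe_tables = {}
    prefix = f"expr_{tissue}_"
    for path in sorted(directory.glob(f"{prefix}*_wk*.tsv")):
        stem = path.stem[len(prefix):]
        group, wk = stem.rsplit("_wk", 1)
        probe_tables[(group, int(wk))] = read_expression_tsv(path)
    phenotypes = read_phenotype_csv(directory / "phenotypes.csv")
    return probe_tables, phenotypes
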