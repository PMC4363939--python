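"""Cross-experiment conversion and effectiveness classification.

A trained signature model predicts phenotypes on the scale of its own
*reference* experiment.  A new experiment's measurements live on a shifted
scale (different animal batch, different absolute values), so before
comparison they are mapped linearly onto the reference scale, anchoring the
two experiments' ND (control) and HFHSD (untreated disease) values — the
same idea as a Celsius-to-Fahrenheit conversion.

On the reference scale, a phenotype value is classified against two
cutpoints placed 25% and 50% of the way from the ND value to the HFHSD
value: at or below the 25% point the formulation "worked" (+), between the
25% and 50% points it partially worked (+/−), above the 50% point the
animal is in the disease range (−).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePair",
    "LinearConversion",
    "Cutpoints",
    "fit_conversion",
    "convert",
    "reference_ranges",
    "classify",
    "evaluate_formulations",
]

EFFECTIVE = "+"
BORDERLINE = "+/-"
INEFFECTIVE = "-"


@dataclass(frozen=True)
class ReferencePair:
    """ND (control) and HFHSD (untreated disease) values of one phenotype."""

    nd_value: float
    hfhsd_value: float

    def __post_init__(self):
        if not (np.isfinite(self.nd_value) and np.isfinite(self.hfhsd_value)):
            raise ValueError("ND/HFHSD anchor values must be finite")
        if self.hfhsd_value == self.nd_value:
            raise ValueError("ND and HFHSD anchor values must differ")


@dataclass(frozen=True)
class LinearConversion:
    """Affine map value ↦ m·value + c onto the reference scale."""

    m: float
    c: float

    def __post_init__(self):
        if not np.isfinite(self.m) or self.m == 0:
            raise ValueError("slope must be finite and nonzero")
        if not np.isfinite(self.c):
            raise ValueError("intercept must be finite")


@dataclass(frozen=True)
class Cutpoints:
    """Reference-range boundaries: 25% and 50% of the ND→HFHSD gap."""

    lower: float
    upper: float
    nd: float
    hfhsd: float


def fit_conversion(reference: ReferencePair, new_experiment: ReferencePair
                   ) -> LinearConversion:
    """Line through the two anchor pairs, mapping the NEW scale onto the
    REFERENCE scale: m = (ref_HFHSD − ref_ND)/(new_HFHSD − new_ND) and
    c = ref_ND − m·new_ND."""
    m = (reference.hfhsd_value - reference.nd_value) / (
        new_experiment.hfhsd_value - new_experiment.nd_value
    )
    c = reference.nd_value - m * new_experiment.nd_value
    return LinearConversion(m=m, c=c)


def convert(value, conversion: LinearConversion):
    """Map a new-experiment value onto the reference scale."""
    value = np.asarray(value, dtype=float)
    if not np.isfinite(value).all():
        raise ValueError("value must be finite")
    out = conversion.m * value + conversion.c
    return float(out) if out.ndim == 0 else out


def reference_ranges(reference: ReferencePair) -> Cutpoints:
    """Cutpoints at 25% and 50% of the ND→HFHSD gap.

    E.g. body weight anchors (27.5, 38) g give 30.125 and 32.75 g: normal
    up to 30.125, possible disease up to 32.75, disease above.
    """
    gap = reference.hfhsd_value - reference.nd_value
    return Cutpoints(
        lower=reference.nd_value + 0.25 * gap,
        upper=reference.nd_value + 0.50 * gap,
        nd=reference.nd_value,
        hfhsd=reference.hfhsd_value,
    )


def classify(value: float, cutpoints: Cutpoints) -> str:
    """Effectiveness label for one value: '+', '+/-' or '-'.

    Boundary values go to the milder class (the disease class is strictly
    "more than" the upper cutpoint).
    """
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if value <= cutpoints.lower:
        return EFFECTIVE
    if value <= cutpoints.upper:
        return BORDERLINE
    return INEFFECTIVE


def evaluate_formulations(
    predictions,
    observations,
    reference: ReferencePair,
    new_pair: ReferencePair | None = None,
    conversion: LinearConversion | None = None,
) -> pd.DataFrame:
    """Score formulations: predicted vs converted-observed labels.

    Parameters
    ----------
    predictions, observations : mapping formulation -> value
        Predictions are already on the reference scale; observations are on
        the new experiment's scale and get converted.
    new_pair : ReferencePair, optional
        The new experiment's ND/HFHSD anchors; used to fit the conversion
        unless an explicit ``conversion`` is supplied (needed when the
        published (m, c) differ from what the anchors imply).

    Returns
    -------
    DataFrame with columns formulation, predicted, predicted_label,
    observed, converted, observed_label, agree.  Converted values are full
    precision; round for display.
    """
    if conversion is None:
        if new_pair is None:
            raise ValueError(
                "conversion impossible: provide new_pair anchors or an "
                "explicit LinearConversion"
            )
        conversion = fit_conversion(reference, new_pair)
    cuts = reference_ranges(reference)
    rows = []
    for name, pred in predictions.items():
        if name not in observations:
            raise KeyError(f"no observation for formulation {name!r}")
        obs = float(observations[name])
        conv = convert(obs, conversion)
        p_label = classify(float(pred), cuts)
        o_label = classify(conv, cuts)
        rows.append(
            {
                "formulation": name,
                "predicted": float(pred),
                "predicted_label": p_label,
                "observed": obs,
                "converted": conv,
                "observed_label": o_label,
                "agree": p_label == o_label,
            }
        )
    return pd.DataFrame(rows)
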