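"""Logistic IDH-genotype probability model over the (SDC, DDVD, ADC) triplet.

The package ships a fixed reference coefficient set,

    p(IDH-mutant) = 1 / (1 + exp(-(8.941*SDC - 0.124*DDVD
                                   + 0.034*ADC - 1.229))),

with SDC in au/s, DDVD in au/pixel and ADC in 1e-4 mm^2/s.  The unit
contract is enforced through the triplet's ADC unit tag: feeding ADC in
mm^2/s into coefficients expecting 1e-4 mm^2/s would shift the linear
predictor by a factor 10^4, so mismatches are converted exactly once or
refused — never silently rescaled twice.

The same three-predictor model form can be refit to any cohort by maximum
likelihood (IRLS, no regularization); refitting never alters the reference
instance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import MetricTriplet, ADC_E4, ADC_MM2S
from .roc import auc_from_mann_whitney

__all__ = [
    "LogisticCoefficients",
    "REFERENCE_MODEL",
    "SeparationError",
    "predict_probability",
    "predict_probability_cohort",
    "fit_logistic",
    "classify_cohort",
    "LogisticFit",
]

METRIC_COLS = ("sdc_au_per_s", "ddvd_au_per_pixel", "adc_e4_mm2_per_s")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclasses.dataclass(frozen=True)
class LogisticCoefficients:
    """Weights of the three-metric logistic genotype model.

    ``adc_unit`` states which ADC scale the ``beta_adc`` weight applies to;
    it is part of the model's identity.
    """

    beta_sdc: float            # per au/s
    beta_ddvd: float           # per au/pixel
    beta_adc: float            # per ADC unit below
    intercept: float
    adc_unit: str = ADC_E4
    name: str | None = None

    def __post_init__(self) -> None:
        for f in ("beta_sdc", "beta_ddvd", "beta_adc", "intercept"):
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")
        if self.adc_unit not in (ADC_E4, ADC_MM2S):
            raise ValueError(f"unknown adc unit tag {self.adc_unit!r}")

    def linear_predictor(self, triplet: MetricTriplet) -> float:
        adc = triplet.adc_in(self.adc_unit)
        return (self.beta_sdc * triplet.sdc
                + self.beta_ddvd * triplet.ddvd
                + self.beta_adc * adc
                + self.intercept)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta_sdc": self.beta_sdc,
            "beta_ddvd": self.beta_ddvd,
            "beta_adc": self.beta_adc,
            "intercept": self.intercept,
            "units": {"sdc": "au/s", "ddvd": "au/pixel",
                      "adc": self.adc_unit},
            "name": self.name,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticCoefficients":
        d = json.loads(Path(path).read_text())
        return cls(
            beta_sdc=d["beta_sdc"], beta_ddvd=d["beta_ddvd"],
            beta_adc=d["beta_adc"], intercept=d["intercept"],
            adc_unit=d.get("units", {}).get("adc", ADC_E4),
            name=d.get("name"),
        )


#: the published reference coefficient set; immutable, never refit in place
REFERENCE_MODEL = LogisticCoefficients(
    beta_sdc=8.941,
    beta_ddvd=-0.124,
    beta_adc=0.034,
    intercept=-1.229,
    adc_unit=ADC_E4,
    name="glioma-idh-2025-reference",
)


def predict_probability(
    triplet: MetricTriplet,
    coeffs: LogisticCoefficients = REFERENCE_MODEL,
) -> float:
    """Probability of IDH-mutant genotype for one metric triplet.

    Strictly inside (0, 1) for finite inputs; strictly increasing in SDC and
    ADC and decreasing in DDVD under the reference sign pattern.
    """
    eta = coeffs.linear_predictor(triplet)
    if eta >= 0:
        return float(1.0 / (1.0 + math.exp(-eta)))
    e = math.exp(eta)     # stable for very negative eta
    return float(e / (1.0 + e))


def _design(df: pd.DataFrame) -> np.ndarray:
    missing = [c for c in METRIC_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing metric columns: {missing}")
    x = df.loc[:, list(METRIC_COLS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite metric values")
    return x


def predict_probability_cohort(
    df: pd.DataFrame,
    coeffs: LogisticCoefficients = REFERENCE_MODEL,
) -> np.ndarray:
    """Vectorised probabilities for a cohort table in canonical columns."""
    x = _design(df)
    if coeffs.adc_unit == ADC_MM2S:
        x = x.copy()
        x[:, 2] *= 1e-4   # table stores ADC in 1e-4 mm^2/s
    eta = (coeffs.beta_sdc * x[:, 0] + coeffs.beta_ddvd * x[:, 1]
           + coeffs.beta_adc * x[:, 2] + coeffs.intercept)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclasses.dataclass
class LogisticFit:
    """Fit report: coefficients, SEs, convergence, in-sample AUC."""

    coeffs: LogisticCoefficients
    se: dict[str, float]
    converged: bool
    n: int
    n_positive: int
    auc_in_sample: float
    log_likelihood: float


def fit_logistic(
    df: pd.DataFrame,
    label: str = "idh_gene",
    exclude_partial: bool = False,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood fit of the three-metric logistic model.

    ``label`` is "idh_gene" (0/1) or "idh_ihc" (0 / 0.5 / 1); with
    ``exclude_partial`` the 0.5 (partial-positive) level is dropped — not
    merged into either class.  Fitting is IRLS to the ML solution with no
    penalty.  Complete separation is detected (fitted probabilities
    numerically saturated at every subject) and raised, not returned as
    divergent coefficients.
    """
    data = df
    if label not in data.columns:
        raise ValueError(f"no label column {label!r}")
    y_raw = data[label].to_numpy(dtype=float)
    if exclude_partial:
        keep = y_raw != 0.5
        data = data.loc[keep]
        y_raw = y_raw[keep]
    if np.any((y_raw != 0) & (y_raw != 1)):
        raise ValueError(
            f"label {label!r} has non-binary levels after exclusions; "
            f"use exclude_partial for the three-level IHC label")
    y = y_raw.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present after exclusions")
    x = sm.add_constant(_design(data), prepend=False)
    model = sm.GLM(y, x, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    p = np.asarray(res.fittedvalues)
    eps = 1e-8
    if np.all((p < eps) | (p > 1 - eps)):
        raise SeparationError(
            "complete separation: all fitted probabilities saturated; "
            "the maximum-likelihood estimate does not exist")
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)
    coeffs = LogisticCoefficients(
        beta_sdc=float(params[0]), beta_ddvd=float(params[1]),
        beta_adc=float(params[2]), intercept=float(params[3]),
        adc_unit=ADC_E4, name="fitted",
    )
    auc = auc_from_mann_whitney(p, y)
    return LogisticFit(
        coeffs=coeffs,
        se={"beta_sdc": float(ses[0]), "beta_ddvd": float(ses[1]),
            "beta_adc": float(ses[2]), "intercept": float(ses[3])},
        converged=bool(res.converged),
        n=int(y.size),
        n_positive=int(y.sum()),
        auc_in_sample=float(auc),
        log_likelihood=float(res.llf),
    )


def classify_cohort(
    df: pd.DataFrame,
    coeffs: LogisticCoefficients = REFERENCE_MODEL,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-subject genotype probability and predicted class.

    A probability exactly at the threshold classifies positive (documented
    tie rule).  An empty cohort yields an empty table.
    """
    if len(df) == 0:
        return pd.DataFrame(
            columns=["subject_id", "probability", "predicted_class"])
    prob = predict_probability_cohort(df, coeffs)
    out = pd.DataFrame({
        "subject_id": df.get(
            "subject_id", pd.Series(range(len(df)), index=df.index)),
        "probability": prob,
        "predicted_class": (prob >= threshold).astype(int),
    })
    return out.reset_index(drop=True)
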