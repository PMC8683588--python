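"""Synthetic patient cohorts with known growth-rate models.

Generates per-patient covariate tables shaped like a Marfan / non-syndromic
thoracic-aortic-aneurysm follow-up cohort: demographics, hemodynamics,
comorbidity and medication flags, per-segment baseline diameters and lengths,
per-segment pulse wave velocity, ascending flow displacement and curvature
radius.  Growth rates are generated from a stated linear model (named true
coefficients plus Gaussian residual noise) and written back as follow-up
measurements, so the full growth-rate + screening + regression chain can be
validated against known truth.

Default covariate distributions follow the published cohort means/SDs; the
default true effects are the reported associations: ascending curvature
radius on diameter growth (-0.018 mm/y per mm) and flow displacement on
length growth (+9.5 mm/y per unit FD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ..errors import CohortError

__all__ = ["CohortSpec", "make_cohort", "DEFAULT_COVARIATES", "DEFAULT_COEFFICIENTS", "COLUMN_DICTIONARY"]

SEGMENTS = ("S1", "S2", "S3", "S4")

# population means/SDs for the simulated covariates (total-cohort values)
DEFAULT_COVARIATES: dict[str, dict[str, Any]] = {
    "age_years": {"kind": "normal", "mean": 47.7, "sd": 16.6, "lo": 18.0},
    "sex_male": {"kind": "bernoulli", "p": 0.653},
    "group_marfan": {"kind": "bernoulli", "p": 18.0 / 49.0},
    "bsa_m2": {"kind": "normal", "mean": 2.1, "sd": 0.2, "lo": 1.2},
    "map_mmHg": {"kind": "normal", "mean": 95.1, "sd": 11.3, "lo": 50.0},
    "heart_rate_bpm": {"kind": "normal", "mean": 67.1, "sd": 9.8, "lo": 35.0},
    "smoking": {"kind": "bernoulli", "p": 0.163},
    "hypertension": {"kind": "bernoulli", "p": 0.429},
    "diabetes": {"kind": "bernoulli", "p": 0.02},
    "betablocker": {"kind": "bernoulli", "p": 0.571},
    "ace_arb": {"kind": "bernoulli", "p": 0.408},
    "interval_years": {"kind": "normal", "mean": 8.6, "sd": 1.8, "lo": 4.0},
    "baseline_diameter_S1_mm": {"kind": "normal", "mean": 40.6, "sd": 4.3, "lo": 20.0},
    "baseline_diameter_S2_mm": {"kind": "normal", "mean": 31.3, "sd": 4.8, "lo": 15.0},
    "baseline_diameter_S3_mm": {"kind": "normal", "mean": 26.6, "sd": 3.3, "lo": 12.0},
    "baseline_diameter_S4_mm": {"kind": "normal", "mean": 20.5, "sd": 2.9, "lo": 10.0},
    "baseline_length_S1_mm": {"kind": "normal", "mean": 89.9, "sd": 13.4, "lo": 40.0},
    "baseline_length_S2_mm": {"kind": "normal", "mean": 35.9, "sd": 6.6, "lo": 15.0},
    "baseline_length_S3_mm": {"kind": "normal", "mean": 265.0, "sd": 25.6, "lo": 150.0},
    "baseline_length_S4_mm": {"kind": "normal", "mean": 102.4, "sd": 11.4, "lo": 50.0},
    "pwv_S1_m_per_s": {"kind": "normal", "mean": 7.1, "sd": 4.7, "lo": 1.0},
    "pwv_S2_m_per_s": {"kind": "normal", "mean": 6.9, "sd": 5.1, "lo": 1.0},
    "pwv_S3_m_per_s": {"kind": "normal", "mean": 7.6, "sd": 3.9, "lo": 1.0},
    "pwv_S4_m_per_s": {"kind": "normal", "mean": 8.1, "sd": 4.1, "lo": 1.0},
    "flow_displacement": {"kind": "normal", "mean": 0.05, "sd": 0.04, "lo": 0.0},
    "curvature_radius_mm": {"kind": "normal", "mean": 45.9, "sd": 6.9, "lo": 20.0},
}

# true growth-rate models: outcome -> {predictor: beta, "intercept": value}
# intercepts chosen so the outcome means match the observed growth rates
# (S1 diameter 0.40 mm/y, S1 length 0.98 mm/y); residual SDs chosen so the
# marginal outcome SDs match the observed 0.31 / 0.83 mm/y.
DEFAULT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "diameter_growth_S1_mm_per_year": {
        "intercept": 0.40 + 0.018 * 45.9,
        "curvature_radius_mm": -0.018,
    },
    "length_growth_S1_mm_per_year": {
        "intercept": 0.98 - 9.5 * 0.05,
        "flow_displacement": 9.5,
    },
    "diameter_growth_S2_mm_per_year": {"intercept": 0.45},
    "length_growth_S2_mm_per_year": {"intercept": 0.51},
    "diameter_growth_S3_mm_per_year": {"intercept": 0.37},
    "length_growth_S3_mm_per_year": {"intercept": 1.57},
    "diameter_growth_S4_mm_per_year": {"intercept": 0.18},
    "length_growth_S4_mm_per_year": {"intercept": 0.86},
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "diameter_growth_S1_mm_per_year": 0.28,
    "length_growth_S1_mm_per_year": 0.74,
    "diameter_growth_S2_mm_per_year": 0.22,
    "length_growth_S2_mm_per_year": 0.60,
    "diameter_growth_S3_mm_per_year": 0.19,
    "length_growth_S3_mm_per_year": 1.10,
    "diameter_growth_S4_mm_per_year": 0.37,
    "length_growth_S4_mm_per_year": 0.98,
}

COLUMN_DICTIONARY: dict[str, str] = {
    "patient_id": "synthetic patient identifier",
    "group": "Marfan or NTAA (non-syndromic thoracic aortic aneurysm)",
    "age_years": "age at baseline (years)",
    "sex_male": "sex, 1 = male, 0 = female",
    "bsa_m2": "body surface area (m^2)",
    "map_mmHg": "mean arterial pressure (mmHg)",
    "heart_rate_bpm": "heart rate (beats/min)",
    "smoking": "history of smoking (0/1)",
    "hypertension": "history of hypertension (0/1)",
    "diabetes": "history of diabetes (0/1)",
    "betablocker": "betablocker use (0/1)",
    "ace_arb": "ACE-inhibitor / AT2-antagonist use (0/1)",
    "interval_years": "time between baseline and follow-up scan (years)",
    "baseline_diameter_{S}_mm": "baseline maximal mean diameter of segment S (mm)",
    "baseline_length_{S}_mm": "baseline centerline length of segment S (mm)",
    "followup_diameter_{S}_mm": "follow-up maximal mean diameter of segment S (mm)",
    "followup_length_{S}_mm": "follow-up centerline length of segment S (mm)",
    "pwv_{S}_m_per_s": "baseline regional pulse wave velocity of segment S (m/s)",
    "flow_displacement": "baseline normalized ascending flow displacement (unitless)",
    "curvature_radius_mm": "baseline ascending aorta curvature radius (mm)",
}


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 49
    coefficient_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    )
    covariate_distributions: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )
    noise_sd: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        sds = (
            self.noise_sd.values() if isinstance(self.noise_sd, dict) else [self.noise_sd]
        )
        if any(s < 0 for s in sds):
            raise ValueError("noise_sd must be non-negative")
        for outcome, coeffs in self.coefficient_map.items():
            for name in coeffs:
                if name != "intercept" and name not in self.covariate_distributions:
                    raise CohortError(
                        f"coefficient map for {outcome!r} names covariate {name!r} "
                        "absent from covariate_distributions"
                    )

    def outcome_noise_sd(self, outcome: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(outcome, 0.0))
        return float(self.noise_sd)


def _draw(rng: np.random.Generator, dist: dict[str, Any], n: int) -> np.ndarray:
    kind = dist["kind"]
    if kind == "normal":
        x = rng.normal(dist["mean"], dist["sd"], size=n)
        if "lo" in dist:
            x = np.maximum(x, dist["lo"])
        if "hi" in dist:
            x = np.minimum(x, dist["hi"])
        return x
    if kind == "bernoulli":
        return (rng.random(n) < dist["p"]).astype(float)
    raise CohortError(f"unknown covariate distribution kind {kind!r}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic cohort table; the seed fully determines the output.

    Growth-rate outcomes are the stated linear combinations of covariates plus
    Gaussian noise; follow-up diameters/lengths are back-computed as
    baseline + rate * interval so that the growth-rate computation downstream
    recovers the generated rates exactly.  Missingness (if requested) is
    applied after generation, to measurement columns only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cols: dict[str, np.ndarray] = {}
    for name in spec.covariate_distributions:  # insertion order: deterministic draws
        cols[name] = _draw(rng, spec.covariate_distributions[name], n)

    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(n)])
    if "group_marfan" in df:
        df.insert(1, "group", np.where(df.pop("group_marfan") > 0.5, "Marfan", "NTAA"))

    # outcomes from the stated linear models
    for outcome, coeffs in spec.coefficient_map.items():
        y = np.full(n, float(coeffs.get("intercept", 0.0)))
        for name, beta in coeffs.items():
            if name == "intercept":
                continue
            y = y + beta * df[name].to_numpy()
        sd = spec.outcome_noise_sd(outcome)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n)
        df[outcome] = y

    # back-compute follow-up measurements from the generated rates
    for seg in SEGMENTS:
        for meas in ("diameter", "length"):
            rate_col = f"{meas}_growth_{seg}_mm_per_year"
            base_col = f"baseline_{meas}_{seg}_mm"
            fu_col = f"followup_{meas}_{seg}_mm"
            if rate_col in df and base_col in df:
                df[fu_col] = df[base_col] + df[rate_col] * df["interval_years"]

    if spec.missing_rate > 0:
        protected = {"patient_id", "group", "age_years", "sex_male", "interval_years"}
        for col in df.columns:
            if col in protected:
                continue
            miss = rng.random(n) < spec.missing_rate
            df.loc[miss, col] = np.nan
    return df
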