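"""Lesion-level synthetic cohorts.

Generates lesion tables with the statistical structure the diagnostics layer
assumes: a fixed number of lesions nested in patients, enhancing flags, a
progressive / non-progressive outcome split, and log-normally distributed
TBR_max / BV_max / nBV_max per outcome group with a shared latent factor
inducing the between-metric correlation seen in real scatter plots.

Default group medians follow published lesion summary statistics for
recurrent high-grade glioma (76 lesions in 60 patients, 67 enhancing, 44
progressive; non-progressive vs progressive medians 1.7/2.8 for TBR_max,
3.4/14.7 mL/100 g for BV_max, 4.9/20.5 for nBV_max).  Log-scale spreads are
calibrated once to the published ranges, with a larger standardized group
separation for the PET metric than the BV metrics (sigma 0.30 vs 1.1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .outcomes import NON_EVALUABLE, NON_PROGRESSIVE, PROGRESSIVE


@dataclasses.dataclass(frozen=True)
class GroupDistribution:
    """Log-normal location (median, natural units) and log-scale sigma."""

    median_nonprog: float
    median_prog: float
    sigma: float

    def mu(self, progressive: bool) -> float:
        return float(np.log(self.median_prog if progressive else self.median_nonprog))


DEFAULT_METRICS = {
    "tbr_max": GroupDistribution(1.7, 2.8, 0.30),
    "bv_max": GroupDistribution(3.4, 14.7, 1.1),
    "nbv_max": GroupDistribution(4.9, 20.5, 1.1),
}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and per-group metric distributions."""

    n_patients: int = 60
    n_lesions: int = 76
    n_enhancing: int = 67
    n_progressive: int = 44
    metrics: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_METRICS))
    latent_correlation: float = 0.5
    n_nonevaluable_patients: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < self.n_patients:
            raise ValueError("need at least one lesion per patient")
        if self.n_enhancing > self.n_lesions or self.n_progressive > self.n_lesions:
            raise ValueError("subgroup counts cannot exceed the lesion count")
        if min(self.n_patients, self.n_lesions) < 1:
            raise ValueError("cohort must be non-empty")
        if not 0.0 <= self.latent_correlation <= 1.0:
            raise ValueError("latent correlation must be in [0, 1]")
        if self.n_nonevaluable_patients >= self.n_patients:
            raise ValueError("at least one evaluable patient is required")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Seeded, reproducible lesion table.

    Every patient receives at least one lesion; outcome labels and enhancing
    flags are assigned by permutation so the configured counts hold exactly;
    metric values are drawn per outcome group from the configured log-normal
    distributions, correlated through a shared standard-normal latent factor
    with weight sqrt(latent_correlation).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lesions
    patient_of = np.concatenate(
        [np.arange(spec.n_patients), rng.integers(0, spec.n_patients, n - spec.n_patients)]
    )
    rng.shuffle(patient_of)

    progressive = np.zeros(n, dtype=bool)
    progressive[rng.permutation(n)[: spec.n_progressive]] = True
    enhancing = np.zeros(n, dtype=bool)
    enhancing[rng.permutation(n)[: spec.n_enhancing]] = True

    rho = spec.latent_correlation
    latent = rng.standard_normal(n)
    data = {}
    for name, dist in spec.metrics.items():
        z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        mu = np.where(progressive, dist.mu(True), dist.mu(False))
        data[name] = np.exp(mu + dist.sigma * z)

    # per-patient chart-level non-evaluability (models the occasional patient
    # whose patient-wise outcome cannot be determined)
    override = np.full(n, np.nan, dtype=object)
    if spec.n_nonevaluable_patients:
        blocked = rng.permutation(spec.n_patients)[: spec.n_nonevaluable_patients]
        override[np.isin(patient_of, blocked)] = NON_EVALUABLE

    days_from_rt = np.exp(
        np.log(np.where(progressive, 226.0, 277.0)) + 0.8 * rng.standard_normal(n)
    )
    idh_wt = rng.random(n) < np.where(progressive, 38 / 44, 26 / 32)
    mgmt = rng.random(n) < np.where(progressive, 18 / 44, 24 / 32)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{p:03d}" for p in patient_of],
            "lesion_id": [f"L{i:03d}" for i in range(n)],
            "enhancing": enhancing,
            "outcome": np.where(progressive, PROGRESSIVE, NON_PROGRESSIVE),
            "patient_outcome": override,
            "days_from_rt": np.round(days_from_rt, 0),
            "idh_wildtype": idh_wt,
            "mgmt_methylated": mgmt,
            **{k: np.round(v, 3) for k, v in data.items()},
        }
    )
    return df
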