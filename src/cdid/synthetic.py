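"""Synthetic-data generators with the statistical structure the model assumes.

Three generators are provided:

* :func:`generate_bias_study_data` — the omitted-baseline-predictor design:
  J clinics, I patients per clinic-year, four iid standard-normal clinic-level
  covariates, no system effects.  Used to measure the bias in the change-model
  coefficients when the baseline mean is modeled intercept-only (MS1) versus
  with the shared predictor set (MS2).
* :func:`generate_coverage_study_data` — the hierarchical cascade with system
  effects and a dynamic confounder (X1 correlated with the clinic-score change),
  used to contrast the ad-hoc correlation test with the hierarchical model's
  credible-interval coverage.  The real clinic sizes and scores behind the
  original experiment are not public, so a documented stand-in design supplies
  them (see :class:`StandInDesign`).
* :func:`generate_full_hierarchy` — a patients.csv / scores.csv fixture pair
  emulating the registry data layout end to end, including filter-violating
  rows and unmatched patients across years.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DesignMatrix
from .sampler import ClinicData


@dataclass
class SimulatedDataset:
    """Clinic-level data, the fitting design, and the generating truth."""

    data: ClinicData
    design: DesignMatrix
    truth: dict


def _aggregate_patients(mu: np.ndarray, sizes: np.ndarray, sigma: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-clinic (sum, sum of squares) of N(mu_j, sigma^2) patient draws."""
    J = mu.size
    idx = np.repeat(np.arange(J), sizes)
    y = mu[idx] + sigma * rng.standard_normal(idx.size)
    return (np.bincount(idx, weights=y, minlength=J),
            np.bincount(idx, weights=y * y, minlength=J))


def generate_bias_study_data(seed: int, J: int = 100, I: int = 10,
                             Theta: Sequence[float] = (0.0, 0.0, 0.5, 1.0, 0.0),
                             ThetaTilde: Sequence[float] = (0.0, 1.0, 0.5, 0.0, 0.0),
                             noise_free: bool = False) -> SimulatedDataset:
    """Two-year clinic data with four iid N(0,1) covariates and no systems.

    ``Theta``/``ThetaTilde`` are [beta0, alpha, beta1, beta2, beta3] on
    [1, X1, X2, X3, X4]; mu2009 = X Theta~ + e, mudiff = X Theta + e with unit
    clinic-level and patient-level noise (all noise suppressed when
    ``noise_free``).
    """
    Theta = np.asarray(Theta, dtype=float)
    ThetaTilde = np.asarray(ThetaTilde, dtype=float)
    rng = np.random.default_rng(seed)
    Xc = rng.standard_normal((J, 4))
    X = np.column_stack([np.ones(J), Xc])
    s = 0.0 if noise_free else 1.0
    mu09 = X @ ThetaTilde + s * rng.standard_normal(J)
    mudiff = X @ Theta + s * rng.standard_normal(J)
    sizes = np.full(J, I)
    sum09, sumsq09 = _aggregate_patients(mu09, sizes, s, rng)
    sum12, sumsq12 = _aggregate_patients(mu09 + mudiff, sizes, s, rng)
    data = ClinicData(system=np.zeros(J, dtype=int), n09=sizes, n12=sizes,
                      sum09=sum09, sum12=sum12, sumsq09=sumsq09, sumsq12=sumsq12)
    design = DesignMatrix(X=X, columns=["intercept", "x1", "x2", "x3", "x4"],
                          clinic_ids=[f"c{j}" for j in range(J)],
                          system_index=np.zeros(J, dtype=int))
    truth = {"Theta": Theta.copy(), "ThetaTilde": ThetaTilde.copy(),
             "mu09": mu09, "mudiff": mudiff, "coef_labels":
             ["beta0", "alpha", "beta1", "beta2", "beta3"]}
    return SimulatedDataset(data=data, design=design, truth=truth)


@dataclass
class StandInDesign:
    """Clinic layout for the hierarchical coverage study.

    The original experiment reused the real clinic sample sizes and scores,
    which are not deposited; this stand-in draws them instead: ``n_clinics``
    split evenly over ``n_systems``, per-year sizes round(lognormal(log 60,
    0.5)) clipped to at least 2, and cdiff ~ N(0, 7^2).  The cdiff scale was
    set so the induced marginal correlation between clinic mean change and
    cdiff is ~0.35, the magnitude of the confounded ad-hoc signal this study
    is built to exhibit; the printed ad-hoc rejection rate therefore reproduces
    qualitatively, not numerically.  Explicit arrays override any drawn part.
    """

    n_clinics: int = 100
    n_systems: int = 10
    size_log_mean: float = float(np.log(60.0))
    size_log_sd: float = 0.5
    cdiff_mean: float = 0.0
    cdiff_sd: float = 7.0
    confounder_slope: float = 0.1
    sizes09: np.ndarray | None = None
    sizes12: np.ndarray | None = None
    cdiff: np.ndarray | None = None
    system: np.ndarray | None = None

    def realize(self, rng: np.random.Generator):
        J = self.n_clinics
        if J <= 0:
            raise ValueError("design with zero clinics")
        system = self.system if self.system is not None else \
            np.arange(J) % self.n_systems
        def draw_sizes():
            return np.maximum(
                np.round(rng.lognormal(self.size_log_mean, self.size_log_sd, J)), 2
            ).astype(int)
        n09 = self.sizes09 if self.sizes09 is not None else draw_sizes()
        n12 = self.sizes12 if self.sizes12 is not None else draw_sizes()
        cdiff = self.cdiff if self.cdiff is not None else \
            self.cdiff_mean + self.cdiff_sd * rng.standard_normal(J)
        return np.asarray(system, dtype=int), np.asarray(n09), np.asarray(n12), \
            np.asarray(cdiff, dtype=float)


def generate_coverage_study_data(seed: int,
                                 design: StandInDesign | None = None,
                                 Theta: Sequence[float] = (0.0, 1.0, 0.5),
                                 ThetaTilde: Sequence[float] = (0.0, 0.0, 0.5),
                                 ) -> SimulatedDataset:
    """Hierarchical cascade with system effects and a dynamic confounder.

    Generating model on [cdiff, X1, X2] with X1 = slope*cdiff + N(0,1) and
    X2 ~ N(0,1):

        upsilon_s, psi_s ~ N(0,1)
        mu2009 ~ N(X Theta~ + upsilon_s, 1),  mudiff ~ N(X Theta + psi_s, 1)
        Y(2009) ~ N(mu2009, 1),  Y(2012) ~ N(mu2009 + mudiff, 1)

    with true alpha (the cdiff coefficient of the change model) = 0: any
    marginal association between clinic mean change and cdiff is pure
    confounding through X1.  The returned fitting design prepends an intercept.
    """
    design = design or StandInDesign()
    rng = np.random.default_rng(seed)
    system, n09, n12, cdiff = design.realize(rng)
    J = cdiff.size
    S = int(system.max()) + 1
    x1 = design.confounder_slope * cdiff + rng.standard_normal(J)
    x2 = rng.standard_normal(J)
    Xgen = np.column_stack([cdiff, x1, x2])
    Theta = np.asarray(Theta, dtype=float)
    ThetaTilde = np.asarray(ThetaTilde, dtype=float)
    upsilon = rng.standard_normal(S)
    psi = rng.standard_normal(S)
    mu09 = Xgen @ ThetaTilde + upsilon[system] + rng.standard_normal(J)
    mudiff = Xgen @ Theta + psi[system] + rng.standard_normal(J)
    sum09, sumsq09 = _aggregate_patients(mu09, n09, 1.0, rng)
    sum12, sumsq12 = _aggregate_patients(mu09 + mudiff, n12, 1.0, rng)
    data = ClinicData(system=system, n09=n09, n12=n12, sum09=sum09, sum12=sum12,
                      sumsq09=sumsq09, sumsq12=sumsq12)
    fit_design = DesignMatrix(X=np.column_stack([np.ones(J), Xgen]),
                              columns=["intercept", "cdiff", "x1", "x2"],
                              clinic_ids=[f"c{j}" for j in range(J)],
                              system_index=system)
    truth = {"Theta": Theta.copy(), "ThetaTilde": ThetaTilde.copy(),
             "alpha": float(Theta[0]), "cdiff": cdiff, "psi": psi,
             "upsilon": upsilon, "mudiff": mudiff, "mu09": mu09}
    return SimulatedDataset(data=data, design=fit_design, truth=truth)


@dataclass
class SynthConfig:
    """Configuration of the full registry-like hierarchy generator.

    Defaults give 10 systems x 5 clinics with ~60 patient-years per clinic-year
    on an A1c-like scale; all regression/hierarchy variances default to 1.
    ``violation_fraction`` injects rows violating the patient-year exclusion
    rules (split evenly across the five rules); years are generated
    independently, so patients are unmatched across years by construction.
    """

    n_systems: int = 10
    clinics_per_system: int = 5
    patients_per_clinic_year: int = 60
    Theta_true: dict = field(default_factory=lambda: {
        "intercept": 0.0, "cdiff": -0.05, "comm_diff": 0.5, "age_diff": -0.1,
        "fem_diff": 0.0, "ivd_diff": 0.0, "c2008": 0.02})
    ThetaTilde_true: dict = field(default_factory=lambda: {
        "intercept": 7.5, "cdiff": 0.0, "comm_diff": 0.3, "age_diff": 0.0,
        "fem_diff": 0.0, "ivd_diff": 0.0, "c2008": 0.05})
    sigma2: float = 1.0
    tau2: float = 1.0
    lambda2: float = 1.0
    zeta2: float = 1.0
    omega2: float = 1.0
    cdiff_mean: float = 1.0
    cdiff_sd: float = 0.5
    violation_fraction: float = 0.0
    theta_comm: tuple[float, float] = (6.0, 6.0)    # Beta hyperparams per clinic-year
    gamma_fem: tuple[float, float] = (10.0, 8.0)
    kappa_ivd: tuple[float, float] = (3.0, 12.0)
    age_mean: float = 58.0
    age_between_sd: float = 4.0
    sigma_age: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_systems, self.clinics_per_system,
               self.patients_per_clinic_year) < 1:
            raise ValueError("all counts must be >= 1")
        for v in (self.sigma2, self.tau2, self.lambda2, self.zeta2, self.omega2):
            if v <= 0:
                raise ValueError("all variances must be > 0")


def generate_full_hierarchy(config: SynthConfig | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit a (patients, scores) table pair in the documented CSV layout.

    Patient covariates are sampled from clinic-year latent parameters
    (binomial insurance/sex/IVD flags, Gaussian ages) and outcomes from the
    hierarchical change model; neighborhood scores are clinic-level values with
    small patient-level jitter.  Returns (patients_df, scores_df, truth).
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    S, C = cfg.n_systems, cfg.clinics_per_system
    J = S * C
    system = np.repeat(np.arange(S), C)
    clinic_ids = [f"clinic{j:03d}" for j in range(J)]
    system_ids = [f"system{s:02d}" for s in system]

    c2008 = rng.normal(0.0, 1.0, J)
    cdiff = rng.normal(cfg.cdiff_mean, cfg.cdiff_sd, J)
    c2011 = c2008 + cdiff

    def beta_pair(ab):
        base = rng.beta(*ab, size=J)
        shift = np.clip(base + rng.normal(0, 0.05, J), 0.02, 0.98)
        return np.column_stack([base, shift])

    theta = beta_pair(cfg.theta_comm)          # (J,2) commercial
    gamma = beta_pair(cfg.gamma_fem)           # female
    kappa = beta_pair(cfg.kappa_ivd)           # IVD
    eta09 = rng.normal(cfg.age_mean, cfg.age_between_sd, J)
    eta = np.column_stack([eta09, eta09 + rng.normal(0, 1.0, J)])
    wlth = rng.normal(0.0, 1.0, J)
    inc = rng.normal(0.0, 1.0, J)
    nhw = rng.uniform(0.5, 0.98, J)

    cols = list(cfg.Theta_true)
    Xtrue = np.column_stack([
        np.ones(J), cdiff,
        theta[:, 1] - theta[:, 0], eta[:, 1] - eta[:, 0],
        gamma[:, 1] - gamma[:, 0], kappa[:, 1] - kappa[:, 0],
        c2008,
    ])
    Theta = np.array([cfg.Theta_true[c] for c in cols])
    ThetaTilde = np.array([cfg.ThetaTilde_true[c] for c in cols])
    psi = rng.normal(0, np.sqrt(cfg.zeta2), S)
    upsilon = rng.normal(0, np.sqrt(cfg.omega2), S)
    mu09 = Xtrue @ ThetaTilde + upsilon[system] + rng.normal(0, np.sqrt(cfg.lambda2), J)
    mudiff = Xtrue @ Theta + psi[system] + rng.normal(0, np.sqrt(cfg.tau2), J)

    rows = []
    for j in range(J):
        for year, mu, lat_col in ((2009, mu09[j], 0), (2012, mu09[j] + mudiff[j], 1)):
            n = max(int(rng.poisson(cfg.patients_per_clinic_year)), 2)
            # clean rows stay inside the registry-valid ranges; rule-violating
            # rows are injected separately below
            a1c = np.clip(rng.normal(mu, np.sqrt(cfg.sigma2), n), 3.05, 24.95)
            ldl = np.clip(rng.normal(100.0 + 10.0 * (mu - 7.5), 25.0, n), 0.5, 999.5)
            dbp = np.clip(rng.normal(78.0, 9.0, n), 50.0, None)
            sbp = dbp + np.abs(rng.normal(48.0, 12.0, n))
            comm = rng.uniform(size=n) < theta[j, lat_col]
            fem = rng.uniform(size=n) < gamma[j, lat_col]
            ivd = rng.uniform(size=n) < kappa[j, lat_col]
            age = rng.normal(eta[j, lat_col], cfg.sigma_age, n)
            for i in range(n):
                rows.append({
                    "system_id": system_ids[j], "clinic_id": clinic_ids[j],
                    "year": year, "a1c": round(a1c[i], 2), "ldl": round(ldl[i], 1),
                    "sbp": round(sbp[i], 1), "dbp": round(dbp[i], 1),
                    "commercial": bool(comm[i]), "age": round(age[i], 1),
                    "female": bool(fem[i]), "ivd": bool(ivd[i]),
                    "diabetes_type": 2,
                    "wlth": round(wlth[j] + rng.normal(0, 0.1), 3),
                    "inc": round(inc[j] + rng.normal(0, 0.1), 3),
                    "nhw": round(float(np.clip(nhw[j] + rng.normal(0, 0.03), 0, 1)), 3),
                    "a1c_date_valid": True, "ldl_date_valid": True,
                })
    patients = pd.DataFrame(rows)

    if cfg.violation_fraction > 0:
        n_bad = int(round(cfg.violation_fraction * len(patients)))
        bad_idx = rng.choice(len(patients), size=n_bad, replace=False)
        rules = rng.integers(0, 5, size=n_bad)
        for i, rule in zip(bad_idx, rules):
            if rule == 0:
                patients.loc[i, "a1c_date_valid"] = False
            elif rule == 1:
                patients.loc[i, "a1c"] = 2.0 if rng.uniform() < 0.5 else 26.0
            elif rule == 2:
                patients.loc[i, "ldl"] = 1500.0
            elif rule == 3:
                patients.loc[i, "sbp"] = 45.0
            else:
                patients.loc[i, "diabetes_type"] = 1

    scores = pd.DataFrame({"clinic_id": clinic_ids,
                           "c2008": np.round(c2008, 4),
                           "c2011": np.round(c2011, 4)})
    truth = {"columns": cols, "Theta": Theta, "ThetaTilde": ThetaTilde,
             "psi": psi, "upsilon": upsilon, "mu09": mu09, "mudiff": mudiff,
             "theta": theta, "gamma": gamma, "kappa": kappa, "eta": eta,
             "cdiff": cdiff, "c2008": c2008,
             "clinic_ids": clinic_ids, "system_ids": system_ids}
    return patients, scores, truth
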