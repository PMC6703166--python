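"""The package's analyses as runnable experiments.

* :func:`adhoc_correlation` — the naive marginal Pearson analysis of clinic
  mean outcome change against clinic-score change.
* :func:`run_bias_study` — Monte-Carlo bias of the change-model coefficients
  when the baseline mean is modeled intercept-only (MS1) versus with the shared
  predictor set (MS2).
* :func:`run_coverage_study` — ad-hoc rejection rate versus hierarchical-model
  credible-interval coverage for the null cdiff effect under confounded,
  hierarchical data.
* :func:`shrinkage_table` — per-clinic sample change vs posterior mean vs
  model-predicted change, with the precision scale factor used for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DesignMatrix
from .sampler import (ClinicData, PosteriorDraws, intercept_only_design,
                      rebuild_latent_columns, run_gibbs, GibbsState)
from .synthetic import (StandInDesign, generate_bias_study_data,
                        generate_coverage_study_data)


@dataclass(frozen=True)
class AdHocResult:
    """Marginal Pearson correlation and its two-sided t test."""

    rho_hat: float
    p_value: float
    n_clinics: int


def adhoc_correlation(clinic_mean_diffs, cdiff_values) -> AdHocResult:
    """Pearson correlation of clinic mean outcome change against cdiff.

    The p-value is the two-sided test of rho = 0 from the usual transform
    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom.
    """
    y = np.asarray(clinic_mean_diffs, dtype=float)
    c = np.asarray(cdiff_values, dtype=float)
    if y.size != c.size or y.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if y.std() == 0 or c.std() == 0:
        raise ValueError("zero variance in an input vector")
    r, p = stats.pearsonr(y, c)
    return AdHocResult(rho_hat=float(r), p_value=float(p), n_clinics=y.size)


_BIAS_COEFS = ("alpha", "beta1", "beta2", "beta3")


@dataclass
class BiasTable:
    """Monte-Carlo biases of the change-model coefficients under MS1/MS2.

    ``bias[ms][coef]`` and ``se[ms][coef]`` for ms in {"MS1", "MS2"} and coef
    in alpha..beta3; SEs are the Monte-Carlo standard errors over replicates
    (NaN and flagged when reps < 2).
    """

    bias: dict
    se: dict
    reps: int
    draws_per_rep: int
    truth: dict
    estimates: dict  # per-ms (reps, 4) arrays of posterior-mean estimates
    n_skipped: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for ms in ("MS1", "MS2"):
            for coef in _BIAS_COEFS:
                rows.append({"mean_structure": ms, "coefficient": coef,
                             "truth": self.truth[coef],
                             "bias": self.bias[ms][coef], "se": self.se[ms][coef]})
        return pd.DataFrame(rows)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % np.uint32(2**31)


def run_bias_study(reps: int = 500, gibbs_draws: int = 2000, burn: int = 200,
                   seed: int = 0, J: int = 100, I: int = 10,
                   Theta=(0.0, 0.0, 0.5, 1.0, 0.0),
                   ThetaTilde=(0.0, 1.0, 0.5, 0.0, 0.0),
                   max_skip_fraction: float = 0.1) -> BiasTable:
    """Monte-Carlo bias of the change-model coefficient estimates.

    Each replicate draws a fresh dataset and fits the change model twice: MS1
    models the baseline clinic means as intercept-only, MS2 shares the change
    model's predictors.  Both fits pin the patient- and clinic-level variances
    at their generating value 1 (they are part of the study design; under MS1
    this is what lets the unmodeled baseline signal leak into the change
    coefficients instead of being absorbed by an inflated baseline variance).
    The point estimate is the posterior mean; bias is mean(estimate − truth)
    over replicates with its MC standard error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    Theta = np.asarray(Theta, dtype=float)
    seeds = _child_seeds(seed, 3 * reps)
    est = {"MS1": np.full((reps, 4), np.nan), "MS2": np.full((reps, 4), np.nan)}
    skipped = 0
    for r in range(reps):
        try:
            sim = generate_bias_study_data(int(seeds[3 * r]), J=J, I=I,
                                           Theta=Theta, ThetaTilde=ThetaTilde)
            fixed = {"fix_sigma2": 1.0, "fix_tau2": 1.0, "fix_lambda2": 1.0}
            ms1 = run_gibbs(sim.data, sim.design,
                            baseline_design=intercept_only_design(sim.design),
                            system_effects=False, n_iter=gibbs_draws,
                            burn_in=burn, seed=int(seeds[3 * r + 1]), **fixed)
            ms2 = run_gibbs(sim.data, sim.design, system_effects=False,
                            n_iter=gibbs_draws, burn_in=burn,
                            seed=int(seeds[3 * r + 2]), **fixed)
            est["MS1"][r] = ms1.theta.mean(axis=0)[1:5]
            est["MS2"][r] = ms2.theta.mean(axis=0)[1:5]
        except (np.linalg.LinAlgError, RuntimeError, FloatingPointError):
            skipped += 1
    if skipped > max_skip_fraction * reps:
        raise RuntimeError(f"{skipped}/{reps} replicates failed")

    truth = dict(zip(_BIAS_COEFS, Theta[1:5]))
    bias, se = {}, {}
    for ms in ("MS1", "MS2"):
        errs = est[ms] - Theta[1:5]
        ok = np.isfinite(errs).all(axis=1)
        e = errs[ok]
        bias[ms] = dict(zip(_BIAS_COEFS, e.mean(axis=0)))
        if e.shape[0] >= 2:
            se[ms] = dict(zip(_BIAS_COEFS, e.std(axis=0, ddof=1) / np.sqrt(e.shape[0])))
        else:
            se[ms] = dict.fromkeys(_BIAS_COEFS, float("nan"))
    return BiasTable(bias=bias, se=se, reps=reps, draws_per_rep=gibbs_draws,
                     truth=truth, estimates=est, n_skipped=skipped)


@dataclass
class CoverageResult:
    """Ad-hoc test behaviour vs hierarchical-model CI coverage for alpha = 0."""

    adhoc_rejection_rate: float
    adhoc_mean_rho: float
    ci_noncoverage_rate: float
    reps: int
    n_skipped: int = 0


def run_coverage_study(reps: int = 200, design_spec: StandInDesign | None = None,
                       seed: int = 0, gibbs_draws: int = 2000, burn: int = 200,
                       level: float = 0.95, test_level: float = 0.05,
                       max_skip_fraction: float = 0.1) -> CoverageResult:
    """Contrast the naive correlation test with the hierarchical model.

    Per replicate: generate hierarchical two-year data with true alpha = 0 and
    a confounder correlated with cdiff; run the ad-hoc Pearson test of clinic
    mean change against cdiff; fit the hierarchical model and record whether
    the equal-tail CI for alpha excludes 0.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    design_spec = design_spec or StandInDesign()
    seeds = _child_seeds(seed, 2 * reps)
    reject = np.full(reps, np.nan)
    rho = np.full(reps, np.nan)
    noncover = np.full(reps, np.nan)
    skipped = 0
    for r in range(reps):
        try:
            sim = generate_coverage_study_data(int(seeds[2 * r]), design=design_spec)
            ad = adhoc_correlation(sim.data.sample_diff, sim.truth["cdiff"])
            reject[r] = ad.p_value < test_level
            rho[r] = ad.rho_hat
            draws = run_gibbs(sim.data, sim.design, system_effects=True,
                              n_iter=gibbs_draws, burn_in=burn,
                              seed=int(seeds[2 * r + 1]))
            lo, hi = draws.ci("cdiff", level)
            noncover[r] = not (lo <= sim.truth["alpha"] <= hi)
        except (np.linalg.LinAlgError, RuntimeError, FloatingPointError, ValueError):
            skipped += 1
    if skipped > max_skip_fraction * reps:
        raise RuntimeError(f"{skipped}/{reps} replicates failed")
    ok = np.isfinite(noncover)
    return CoverageResult(
        adhoc_rejection_rate=float(np.nanmean(reject)),
        adhoc_mean_rho=float(np.nanmean(rho)),
        ci_noncoverage_rate=float(noncover[ok].mean()),
        reps=reps, n_skipped=skipped)


@dataclass(frozen=True)
class ShrinkageRow:
    """One clinic's sample change, posterior mean, and model prediction.

    ``scale_factor`` = 1/(1/n09 + 1/n12) is the precision weight used to size
    points in the shrinkage plots (larger clinics plot larger).
    """

    clinic_id: str
    system_id: str
    sample_diff: float
    posterior_mean_mudiff: float
    predicted: float
    scale_factor: float


def shrinkage_table(draws: PosteriorDraws, data: ClinicData,
                    design: DesignMatrix) -> list[ShrinkageRow]:
    """Per-clinic shrinkage of the sample mean change toward X Theta-hat.

    ``predicted`` evaluates the design at the posterior means of Theta (with
    latent-driven columns rebuilt at the posterior means of the covariate
    latents, when the measurement model was active).
    """
    theta_hat = draws.theta.mean(axis=0)
    X = design.X.copy()
    lm = draws.latent_means
    if design.latent_columns and "theta" in lm:
        tmp = DesignMatrix(X=X, columns=list(design.columns),
                           clinic_ids=design.clinic_ids,
                           system_index=design.system_index,
                           latent_columns=dict(design.latent_columns))
        mean_state = GibbsState(
            mu09=lm["mu09"], mudiff=lm["mudiff"], sigma2=lm["sigma2"],
            Theta=theta_hat, ThetaTilde=draws.theta_tilde.mean(axis=0),
            psi=draws.psi.mean(axis=0), upsilon=draws.upsilon.mean(axis=0),
            tau2=1.0, lambda2=1.0, zeta2=1.0, omega2=1.0,
            theta=lm.get("theta"), gamma=lm.get("gamma"), kappa=lm.get("kappa"),
            eta=lm.get("eta"))
        rebuild_latent_columns(tmp, mean_state)
        X = tmp.X
    predicted = X @ theta_hat
    post_mean = draws.latent_means["mudiff"]
    sample = data.sample_diff
    n09 = data.n09.astype(float)
    n12 = data.n12.astype(float)
    scale = 1.0 / (1.0 / n09 + 1.0 / n12)
    ids = data.clinic_ids or [f"c{j}" for j in range(data.n_clinics)]
    sys_ids = data.system_ids or [f"s{k}" for k in data.system]
    return [ShrinkageRow(clinic_id=ids[j], system_id=sys_ids[j],
                         sample_diff=float(sample[j]),
                         posterior_mean_mudiff=float(post_mean[j]),
                         predicted=float(predicted[j]),
                         scale_factor=float(scale[j]))
            for j in range(data.n_clinics)]
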