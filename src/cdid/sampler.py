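"""Gibbs sampler for the Bayesian hierarchical continuous-DiD model.

The model, per clinic j in system s:

    Y_sji(2009) ~ N(mu_sj(2009), sigma_sj^2)
    Y_sji(2012) ~ N(mu_sj(2009) + mu_sj^diff, sigma_sj^2)
    mu_sj^diff  = X_sj Theta  + eps_sj,        eps_sj  ~ N(psi_s, tau^2)
    mu_sj(2009) = X_sj Theta~ + eps~_sj,       eps~_sj ~ N(upsilon_s, lambda^2)
    psi_s ~ N(0, zeta^2),  upsilon_s ~ N(0, omega^2)

with an optional errors-in-covariates measurement layer in which the observed
clinic-year insurance/sex/IVD counts are binomial draws from latent proportions
(theta, gamma, kappa) and the observed mean age is Gaussian around a latent eta
with variance sigma_age^2 / n.

All full conditionals are conjugate.  Theta and Theta~ are drawn marginally
over the system effects using the block covariance Sigma (diagonal tau^2+zeta^2,
within-system off-diagonal zeta^2), after which psi and upsilon are redrawn —
a partially collapsed ordering that remains a valid Gibbs scheme.  A
conditional-on-psi variant is available (``collapsed=False``).

Everything operates on clinic-level sufficient statistics (:class:`ClinicData`),
which is what makes replicate-heavy simulation studies affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .data_model import DesignMatrix, ClinicYearSummary, ClinicScore, build_design_matrix
from .priors import IGHyper, PriorConfig, empirical_bayes_from_sample_variances

VARIANCE_FLOOR = 1e-12
VARIANCE_CEILING = 1e12

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------- #
# data container                                                              #
# --------------------------------------------------------------------------- #

@dataclass
class ClinicData:
    """Clinic-level sufficient statistics for one outcome.

    Outcome sums/sums-of-squares are kept separately per year so that the
    (mu2009, mudiff) and sigma^2 conditionals can be evaluated without patient
    rows.  The measurement-model blocks (``x_comm`` … ``age_s2``) are (J, 2)
    arrays with year order (2009, 2012) and may be ``None`` when the covariate
    layer is not in play (e.g. the simulation studies).
    """

    system: np.ndarray          # (J,) int codes 0..S-1
    n09: np.ndarray             # (J,) int
    n12: np.ndarray
    sum09: np.ndarray           # (J,) float
    sum12: np.ndarray
    sumsq09: np.ndarray
    sumsq12: np.ndarray
    clinic_ids: list[str] | None = None
    system_ids: list[str] | None = None
    x_comm: np.ndarray | None = None   # (J, 2) counts
    x_fem: np.ndarray | None = None
    x_ivd: np.ndarray | None = None
    age_mean: np.ndarray | None = None  # (J, 2)
    age_s2: np.ndarray | None = None    # (J, 2) sample variances (EB prior input)

    def __post_init__(self):
        self.system = np.asarray(self.system, dtype=int)
        for name in ("n09", "n12"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("sum09", "sum12", "sumsq09", "sumsq12"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_clinics(self) -> int:
        return self.system.size

    @property
    def n_systems(self) -> int:
        return int(self.system.max()) + 1 if self.system.size else 0

    @property
    def clinics_per_system(self) -> np.ndarray:
        return np.bincount(self.system, minlength=self.n_systems)

    @property
    def n_counts(self) -> np.ndarray:
        """(J, 2) patient counts by year."""
        return np.stack([self.n09, self.n12], axis=1)

    @property
    def ybar09(self) -> np.ndarray:
        return np.divide(self.sum09, self.n09, out=np.zeros_like(self.sum09),
                         where=self.n09 > 0)

    @property
    def ybar12(self) -> np.ndarray:
        return np.divide(self.sum12, self.n12, out=np.zeros_like(self.sum12),
                         where=self.n12 > 0)

    @property
    def sample_diff(self) -> np.ndarray:
        """Per-clinic sample change in mean outcome, ybar(2012) − ybar(2009)."""
        return self.ybar12 - self.ybar09

    def pooled_sample_variance(self) -> np.ndarray:
        """Within-clinic sample variance pooled over the two years (df n09+n12−2)."""
        ss09 = self.sumsq09 - np.divide(self.sum09 ** 2, self.n09,
                                        out=np.zeros_like(self.sum09), where=self.n09 > 0)
        ss12 = self.sumsq12 - np.divide(self.sum12 ** 2, self.n12,
                                        out=np.zeros_like(self.sum12), where=self.n12 > 0)
        df = self.n09 + self.n12 - 2
        return np.divide(ss09 + ss12, df, out=np.full(self.n_clinics, np.nan), where=df > 0)

    @classmethod
    def from_patient_arrays(cls, system, y09_by_clinic, y12_by_clinic, **kw) -> "ClinicData":
        """Build from per-clinic lists/arrays of patient outcome values."""
        n09 = np.array([len(v) for v in y09_by_clinic])
        n12 = np.array([len(v) for v in y12_by_clinic])
        return cls(
            system=system, n09=n09, n12=n12,
            sum09=np.array([np.sum(v) for v in y09_by_clinic], dtype=float),
            sum12=np.array([np.sum(v) for v in y12_by_clinic], dtype=float),
            sumsq09=np.array([np.sum(np.square(v)) for v in y09_by_clinic], dtype=float),
            sumsq12=np.array([np.sum(np.square(v)) for v in y12_by_clinic], dtype=float),
            **kw,
        )

    @classmethod
    def from_summaries(cls, summaries: Sequence[ClinicYearSummary], outcome: str) -> "ClinicData":
        """Build from both-year clinic summaries for one outcome (a1c/ldl/sbp)."""
        by_clinic: dict[tuple[str, str], dict[int, ClinicYearSummary]] = {}
        for s in summaries:
            by_clinic.setdefault((s.system_id, s.clinic_id), {})[s.year] = s
        keys = sorted(by_clinic)
        pairs = []
        for key in keys:
            yrs = by_clinic[key]
            if set(yrs) != {2009, 2012}:
                raise ValueError(f"clinic {key[1]} lacks a both-year summary pair")
            pairs.append((yrs[2009], yrs[2012]))
        sys_ids = [k[0] for k in keys]
        sys_order = sorted(dict.fromkeys(sys_ids))
        code = {sid: i for i, sid in enumerate(sys_order)}

        def stats(s: ClinicYearSummary):
            m, v, n = s.ybar[outcome], s.s2[outcome], s.n
            total = n * m
            ssq = (n - 1) * v + n * m * m if n >= 2 else n * m * m
            return total, ssq

        sums = np.array([[stats(a), stats(b)] for a, b in pairs])  # (J,2,2)
        return cls(
            system=np.array([code[s] for s in sys_ids]),
            n09=np.array([a.n for a, _ in pairs]),
            n12=np.array([b.n for _, b in pairs]),
            sum09=sums[:, 0, 0], sumsq09=sums[:, 0, 1],
            sum12=sums[:, 1, 0], sumsq12=sums[:, 1, 1],
            clinic_ids=[k[1] for k in keys], system_ids=sys_ids,
            x_comm=np.array([[a.x_comm, b.x_comm] for a, b in pairs]),
            x_fem=np.array([[a.x_fem, b.x_fem] for a, b in pairs]),
            x_ivd=np.array([[a.x_ivd, b.x_ivd] for a, b in pairs]),
            age_mean=np.array([[a.age_mean, b.age_mean] for a, b in pairs]),
            age_s2=np.array([[a.age_s2, b.age_s2] for a, b in pairs]),
        )


# --------------------------------------------------------------------------- #
# sampler state                                                               #
# --------------------------------------------------------------------------- #

@dataclass
class GibbsState:
    mu09: np.ndarray
    mudiff: np.ndarray
    sigma2: np.ndarray
    Theta: np.ndarray
    ThetaTilde: np.ndarray
    psi: np.ndarray
    upsilon: np.ndarray
    tau2: float
    lambda2: float
    zeta2: float
    omega2: float
    # measurement latents (may be unused)
    theta: np.ndarray | None = None     # (J,2) commercial-insurance proportion
    gamma: np.ndarray | None = None     # (J,2) female proportion
    kappa: np.ndarray | None = None     # (J,2) IVD proportion
    eta: np.ndarray | None = None       # (J,2) mean age
    sigma2_age: np.ndarray | None = None  # (J,)


def init_state(data: ClinicData, design: DesignMatrix,
               prior_config: PriorConfig | None = None, seed: int = 0,
               baseline_design: DesignMatrix | None = None) -> GibbsState:
    """Deterministic starting state.

    Clinic means start at the sample means/differences, sigma^2 at the pooled
    sample variances (unit fallback where undefined), coefficients at zero,
    hierarchical variances at one, and measurement latents at the observed
    proportions/means with proportions clipped into [1/(n+2), 1−1/(n+2)].
    """
    if design.n_clinics == 0:
        raise ValueError("empty design")
    del seed  # initialisation is deterministic; kept for interface stability
    J = data.n_clinics
    s2 = data.pooled_sample_variance()
    s2 = np.where(np.isfinite(s2) & (s2 > 0), s2, 1.0)
    pb = baseline_design.X.shape[1] if baseline_design is not None else design.X.shape[1]
    st = GibbsState(
        mu09=data.ybar09.copy(), mudiff=data.sample_diff.copy(), sigma2=s2,
        Theta=np.zeros(design.X.shape[1]), ThetaTilde=np.zeros(pb),
        psi=np.zeros(data.n_systems), upsilon=np.zeros(data.n_systems),
        tau2=1.0, lambda2=1.0, zeta2=1.0, omega2=1.0,
    )
    if data.x_comm is not None:
        n = data.n_counts.astype(float)
        lo = 1.0 / (n + 2.0)

        def clipped(x):
            p = np.divide(x, n, out=np.full_like(n, 0.5), where=n > 0)
            return np.clip(p, lo, 1.0 - lo)

        st.theta = clipped(data.x_comm)
        st.gamma = clipped(data.x_fem)
        st.kappa = clipped(data.x_ivd)
    if data.age_mean is not None:
        st.eta = np.where(np.isfinite(data.age_mean), data.age_mean, 0.0)
        s2a_pool = np.nanmean(np.where(np.isfinite(data.age_s2), data.age_s2, np.nan), axis=1) \
            if data.age_s2 is not None else np.ones(J)
        st.sigma2_age = np.where(np.isfinite(s2a_pool) & (s2a_pool > 0), s2a_pool, 1.0)
    return st


# --------------------------------------------------------------------------- #
# full-conditional updates                                                    #
# --------------------------------------------------------------------------- #

def clinic_mean_posterior(state: GibbsState, data: ClinicData,
                          mean_base: np.ndarray, mean_diff: np.ndarray):
    """Closed-form full-conditional moments of (mu2009, mudiff) per clinic.

    Returns (m1, m2, c11, c12, c22): means and the 2x2 covariance entries of
    the bivariate-normal conditional combining the two years' outcome sums at
    precision n/sigma^2 with the regression 'priors' N(mean_base, lambda^2)
    and N(mean_diff, tau^2).
    """
    s2 = state.sigma2
    a11 = (data.n09 + data.n12) / s2 + 1.0 / state.lambda2
    a22 = data.n12 / s2 + 1.0 / state.tau2
    a12 = data.n12 / s2
    b1 = (data.sum09 + data.sum12) / s2 + mean_base / state.lambda2
    b2 = data.sum12 / s2 + mean_diff / state.tau2
    det = a11 * a22 - a12 * a12
    m1 = (a22 * b1 - a12 * b2) / det
    m2 = (a11 * b2 - a12 * b1) / det
    return m1, m2, a22 / det, -a12 / det, a11 / det


def update_clinic_means(state: GibbsState, data: ClinicData,
                        mean_base: np.ndarray, mean_diff: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Joint bivariate-normal draw of (mu2009, mudiff) per clinic.

    Vectorised 2x2 precision algebra over all clinics; see
    :func:`clinic_mean_posterior` for the conditional.
    """
    m1, m2, c11, c12, c22 = clinic_mean_posterior(state, data, mean_base, mean_diff)
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 * l21, 0.0))
    z1 = rng.standard_normal(m1.size)
    z2 = rng.standard_normal(m1.size)
    return m1 + l11 * z1, m2 + l21 * z1 + l22 * z2


def update_outcome_variances(state: GibbsState, data: ClinicData,
                             ig: IGHyper, rng: np.random.Generator) -> np.ndarray:
    """Per-clinic sigma^2 from IG(a + n/2, b + SS/2), residuals pooled over years."""
    m09 = state.mu09
    m12 = state.mu09 + state.mudiff
    ss = (data.sumsq09 - 2 * m09 * data.sum09 + data.n09 * m09 ** 2
          + data.sumsq12 - 2 * m12 * data.sum12 + data.n12 * m12 ** 2)
    shape = ig.shape + 0.5 * (data.n09 + data.n12)
    scale = ig.scale + 0.5 * np.maximum(ss, 0.0)
    return scale / rng.gamma(shape)


def coefficient_posterior(y: np.ndarray, X: np.ndarray, resid_var: float,
                          sys_var: float, system: np.ndarray,
                          prior_precision: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the coefficient vector given y.

    y ~ N(X Theta, Sigma) with Sigma the within-system exchangeable block matrix
    (diagonal resid_var + sys_var, within-block off-diagonal sys_var); the
    Woodbury identity gives Sigma^{-1} without forming the dense matrix.  With
    prior_precision = 0 this is the non-informative-prior update
    B = (X' Sigma^{-1} X)^{-1}, mean = B X' Sigma^{-1} y.
    """
    S = int(system.max()) + 1
    ns = np.bincount(system, minlength=S).astype(float)
    if sys_var > 0:
        g = sys_var / (resid_var + ns * sys_var)           # (S,)
        Sx = np.zeros((S, X.shape[1]))
        np.add.at(Sx, system, X)
        ysum = np.bincount(system, weights=y, minlength=S)
        A = (X.T @ X - Sx.T @ (g[:, None] * Sx)) / resid_var
        b = (X.T @ y - Sx.T @ (g * ysum)) / resid_var
    else:
        A = (X.T @ X) / resid_var
        b = (X.T @ y) / resid_var
    if prior_precision > 0:
        A = A + prior_precision * np.eye(A.shape[0])
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X' Sigma^-1 X is singular; design columns are collinear") from exc
    return cov @ b, cov


def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(cov.shape[0]))
    return mean + L @ rng.standard_normal(mean.size)


def update_regression_coefficients(state: GibbsState, design: DesignMatrix,
                                   rng: np.random.Generator, *,
                                   collapsed: bool = True,
                                   prior_precision: float = 0.0) -> np.ndarray:
    """Draw Theta | mudiff.

    ``collapsed=True`` marginalises the system effects psi through the block
    Sigma; ``collapsed=False`` conditions on the current psi (subtracting it
    from mudiff) with Sigma = tau^2 I.
    """
    if collapsed:
        mean, cov = coefficient_posterior(state.mudiff, design.X, state.tau2,
                                          state.zeta2, design.system_index,
                                          prior_precision)
    else:
        y = state.mudiff - state.psi[design.system_index]
        mean, cov = coefficient_posterior(y, design.X, state.tau2, 0.0,
                                          design.system_index, prior_precision)
    return _draw_mvn(mean, cov, rng)


def update_baseline_coefficients(state: GibbsState, design: DesignMatrix,
                                 rng: np.random.Generator, *,
                                 collapsed: bool = True,
                                 prior_precision: float = 0.0) -> np.ndarray:
    """Draw Theta~ | mu2009 (same scheme with lambda^2 / omega^2)."""
    if collapsed:
        mean, cov = coefficient_posterior(state.mu09, design.X, state.lambda2,
                                          state.omega2, design.system_index,
                                          prior_precision)
    else:
        y = state.mu09 - state.upsilon[design.system_index]
        mean, cov = coefficient_posterior(y, design.X, state.lambda2, 0.0,
                                          design.system_index, prior_precision)
    return _draw_mvn(mean, cov, rng)


def update_system_effects(resid: np.ndarray, system: np.ndarray, n_systems: int,
                          resid_var: float, effect_var: float,
                          rng: np.random.Generator, *,
                          flat_prior: bool = False) -> np.ndarray:
    """Conjugate normal draw of one family of system effects.

    ``resid`` are the clinic-level regression residuals (e.g. mudiff − X Theta);
    each system's effect combines its clinics at precision n_s/resid_var with
    prior precision 1/effect_var (0 under the flat-prior variant).
    """
    ns = np.bincount(system, minlength=n_systems).astype(float)
    rsum = np.bincount(system, weights=resid, minlength=n_systems)
    prior_prec = 0.0 if flat_prior else 1.0 / effect_var
    prec = ns / resid_var + prior_prec
    mean = (rsum / resid_var) / prec
    return mean + rng.standard_normal(n_systems) / np.sqrt(prec)


def draw_variance(ss: float, k: int, rng: np.random.Generator,
                  prior_ab: tuple[float, float] = (0.0, 0.0),
                  current: float = 1.0, label: str = "variance") -> float:
    """Conjugate variance draw under pi(v) ~ IG(a0, b0) (a0=b0=0: log-uniform).

    Full conditional is IG(a0 + k/2, b0 + SS/2).  k=0 with an improper prior
    leaves the value unchanged (warned); an all-zero residual sum is floored.
    """
    a0, b0 = prior_ab
    shape = a0 + 0.5 * k
    scale = b0 + 0.5 * ss
    if shape <= 0:
        warnings.warn(f"{label}: no residuals and improper prior; holding current value")
        return current
    if scale < VARIANCE_FLOOR:
        warnings.warn(f"{label}: degenerate (all residuals zero); flooring scale")
        scale = VARIANCE_FLOOR
    return float(scale / rng.gamma(shape))


def update_hier_variances(state: GibbsState, design: DesignMatrix,
                          baseline_design: DesignMatrix,
                          rng: np.random.Generator, *,
                          prior_ab: tuple[float, float] = (0.0, 0.0),
                          system_effects: bool = True,
                          flat_system_prior: bool = False) -> tuple[float, float, float, float]:
    """Draw (tau^2, lambda^2, zeta^2, omega^2) from their IG full conditionals."""
    sysid = design.system_index
    r_diff = state.mudiff - design.X @ state.Theta - state.psi[sysid]
    r_base = state.mu09 - baseline_design.X @ state.ThetaTilde - state.upsilon[sysid]
    J = r_diff.size
    tau2 = draw_variance(float(r_diff @ r_diff), J, rng, prior_ab, state.tau2, "tau2")
    lambda2 = draw_variance(float(r_base @ r_base), J, rng, prior_ab, state.lambda2, "lambda2")
    zeta2, omega2 = state.zeta2, state.omega2
    if system_effects and not flat_system_prior:
        S = state.psi.size
        zeta2 = draw_variance(float(state.psi @ state.psi), S, rng, prior_ab,
                              state.zeta2, "zeta2")
        omega2 = draw_variance(float(state.upsilon @ state.upsilon), S, rng, prior_ab,
                               state.omega2, "omega2")
    return tau2, lambda2, zeta2, omega2


# ---- errors-in-covariates layer ------------------------------------------- #

_LATENT_FAMILIES = {"comm_diff": "theta", "fem_diff": "gamma", "ivd_diff": "kappa",
                    "age_diff": "eta"}


def update_covariate_params(state: GibbsState, data: ClinicData,
                            rng: np.random.Generator, *,
                            beta_prior: tuple[float, float] = (1.0, 1.0),
                            ig_age: IGHyper | None = None,
                            exclude: frozenset[str] = frozenset()) -> None:
    """Cut-feedback draw of the clinic-year covariate latents (in place).

    Each latent is updated from its own measurement data only: proportions from
    Beta(x + a, n − x + b) conjugacy, eta from N(observed mean, sigma_age^2/n)
    under its flat prior, and sigma_age^2 from its empirical-Bayes IG conjugate
    update (one value per clinic, shared by the two years).  Families named in
    ``exclude`` (theta/gamma/kappa/eta) are skipped — the full-feedback scheme
    updates those by Metropolis instead.
    """
    a, b = beta_prior
    n = data.n_counts.astype(float)
    for counts, attr in ((data.x_comm, "theta"), (data.x_fem, "gamma"), (data.x_ivd, "kappa")):
        if counts is None or attr in exclude:
            continue
        draw = rng.beta(counts + a, n - counts + b)
        setattr(state, attr, np.clip(draw, 1e-12, 1.0 - 1e-12))
    if data.age_mean is not None:
        obs = np.where(np.isfinite(data.age_mean), data.age_mean, 0.0)
        if "eta" not in exclude:
            with np.errstate(divide="ignore"):
                sd = np.sqrt(state.sigma2_age[:, None] / np.maximum(n, 1.0))
            eta = obs + sd * rng.standard_normal(n.shape)
            state.eta = np.where(n > 0, eta, state.eta)
        if ig_age is not None:
            # likelihood factor per year: N(agebar | eta, sigma_age^2 / n)
            dev2 = n * (obs - state.eta) ** 2
            k_years = (n > 0).sum(axis=1)
            shape = ig_age.shape + 0.5 * k_years
            scale = ig_age.scale + 0.5 * np.where(n > 0, dev2, 0.0).sum(axis=1)
            state.sigma2_age = scale / rng.gamma(shape)


def update_covariate_params_full(state: GibbsState, data: ClinicData,
                                 design: DesignMatrix,
                                 baseline_design: DesignMatrix,
                                 rng: np.random.Generator, *,
                                 beta_prior: tuple[float, float] = (1.0, 1.0),
                                 baseline_shared: bool = True) -> None:
    """Full-feedback Metropolis-within-Gibbs update of the covariate latents.

    The target for each clinic's latent pair (year 2009, 2012) includes, besides
    its measurement factor and prior, the regression factors through the latent
    design column (diff = value2012 − value2009).  Proposals are random walks on
    the logit scale for proportions (with the change-of-variables Jacobian) and
    on the natural scale for eta; both years are proposed jointly and accepted
    per clinic.
    """
    sysid = design.system_index
    n = data.n_counts.astype(float)
    a, b = beta_prior

    def regression_loglik(label, col_idx, diff_vals):
        Xd = design.X.copy()
        Xd[:, col_idx] = diff_vals
        r = state.mudiff - Xd @ state.Theta - state.psi[sysid]
        ll = -0.5 * r * r / state.tau2
        bcol = baseline_design.latent_columns.get(label)
        if bcol is not None:
            Xb = baseline_design.X.copy()
            Xb[:, bcol] = diff_vals
            rb = state.mu09 - Xb @ state.ThetaTilde - state.upsilon[sysid]
            ll = ll - 0.5 * rb * rb / state.lambda2
        return ll

    for label, col in design.latent_columns.items():
        fam = _LATENT_FAMILIES[label]
        if fam == "eta":
            if data.age_mean is None:
                continue
            cur = state.eta
            obs = np.where(np.isfinite(data.age_mean), data.age_mean, 0.0)
            step = 2.0 * np.sqrt(state.sigma2_age[:, None] / np.maximum(n, 1.0))
            prop = cur + step * rng.standard_normal(cur.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                meas_cur = np.where(n > 0, -0.5 * n * (obs - cur) ** 2
                                    / state.sigma2_age[:, None], 0.0).sum(axis=1)
                meas_prop = np.where(n > 0, -0.5 * n * (obs - prop) ** 2
                                     / state.sigma2_age[:, None], 0.0).sum(axis=1)
            log_acc = (meas_prop + regression_loglik(label, col, prop[:, 1] - prop[:, 0])
                       - meas_cur - regression_loglik(label, col, cur[:, 1] - cur[:, 0]))
            accept = np.log(rng.uniform(size=log_acc.size)) < log_acc
            state.eta = np.where(accept[:, None], prop, cur)
            design.X[:, col] = state.eta[:, 1] - state.eta[:, 0]
        else:
            counts = {"theta": data.x_comm, "gamma": data.x_fem, "kappa": data.x_ivd}[fam]
            if counts is None:
                continue
            cur = getattr(state, fam)
            logit = np.log(cur) - np.log1p(-cur)
            step = 2.0 / np.sqrt(n + 4.0)
            prop = 1.0 / (1.0 + np.exp(-(logit + step * rng.standard_normal(cur.shape))))
            prop = np.clip(prop, 1e-12, 1.0 - 1e-12)

            def logpost(p):
                # Binomial + Beta prior + logit-scale Jacobian p(1-p)
                return ((counts + a) * np.log(p) + (n - counts + b) * np.log1p(-p)).sum(axis=1)

            log_acc = (logpost(prop) + regression_loglik(label, col, prop[:, 1] - prop[:, 0])
                       - logpost(cur) - regression_loglik(label, col, cur[:, 1] - cur[:, 0]))
            accept = np.log(rng.uniform(size=log_acc.size)) < log_acc
            new = np.where(accept[:, None], prop, cur)
            setattr(state, fam, new)
            design.X[:, col] = new[:, 1] - new[:, 0]
    if baseline_shared:
        for label, col in design.latent_columns.items():
            if label in baseline_design.latent_columns:
                baseline_design.X[:, baseline_design.latent_columns[label]] = design.X[:, col]


def rebuild_latent_columns(design: DesignMatrix, state: GibbsState) -> None:
    """Refresh latent-driven design columns from the current latent draw."""
    for label, col in design.latent_columns.items():
        fam = _LATENT_FAMILIES[label]
        vals = getattr(state, fam)
        design.X[:, col] = vals[:, 1] - vals[:, 0]


# --------------------------------------------------------------------------- #
# likelihood / deviance                                                       #
# --------------------------------------------------------------------------- #

def log_joint_likelihood(data: ClinicData, design: DesignMatrix,
                         baseline_design: DesignMatrix, state: GibbsState, *,
                         system_effects: bool = True,
                         hierarchical_system_prior: bool = True,
                         measurement: bool = False) -> float:
    """Log of the full hierarchical joint density at the given state.

    Includes the patient-outcome factors (via sufficient statistics), the two
    clinic-level regressions, the system-effect normals (under the hierarchical
    prior) and, when ``measurement`` is set, the binomial/Gaussian covariate
    measurement factors.  Latent clinic means are treated as parameters.
    """
    sysid = design.system_index
    m09, m12 = state.mu09, state.mu09 + state.mudiff
    ss = (data.sumsq09 - 2 * m09 * data.sum09 + data.n09 * m09 ** 2
          + data.sumsq12 - 2 * m12 * data.sum12 + data.n12 * m12 ** 2)
    ntot = data.n09 + data.n12
    ll = float(np.sum(-0.5 * ntot * (_LOG2PI + np.log(state.sigma2))
                      - 0.5 * ss / state.sigma2))

    r = state.mudiff - design.X @ state.Theta - state.psi[sysid]
    ll += float(np.sum(-0.5 * (_LOG2PI + np.log(state.tau2)) - 0.5 * r * r / state.tau2))
    rb = state.mu09 - baseline_design.X @ state.ThetaTilde - state.upsilon[sysid]
    ll += float(np.sum(-0.5 * (_LOG2PI + np.log(state.lambda2)) - 0.5 * rb * rb / state.lambda2))

    if system_effects and hierarchical_system_prior:
        ll += float(np.sum(-0.5 * (_LOG2PI + np.log(state.zeta2))
                           - 0.5 * state.psi ** 2 / state.zeta2))
        ll += float(np.sum(-0.5 * (_LOG2PI + np.log(state.omega2))
                           - 0.5 * state.upsilon ** 2 / state.omega2))

    if measurement:
        n = data.n_counts.astype(float)
        for counts, p in ((data.x_comm, state.theta), (data.x_fem, state.gamma),
                          (data.x_ivd, state.kappa)):
            if counts is None or p is None:
                continue
            x = counts.astype(float)
            ll += float(np.sum(gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
                               + x * np.log(p) + (n - x) * np.log1p(-p)))
        if data.age_mean is not None and state.eta is not None:
            obs = data.age_mean
            var = state.sigma2_age[:, None] / np.maximum(n, 1.0)
            valid = (n > 0) & np.isfinite(obs)
            terms = np.where(valid,
                             -0.5 * (_LOG2PI + np.log(var)) -
                             0.5 * np.where(valid, (obs - state.eta), 0.0) ** 2 / var,
                             0.0)
            ll += float(terms.sum())
    return ll


# --------------------------------------------------------------------------- #
# chain container                                                             #
# --------------------------------------------------------------------------- #

@dataclass
class PosteriorDraws:
    """Retained Gibbs draws plus run metadata.

    Coefficient chains are labelled by their design columns.  Clinic-level
    latents are summarised by running posterior means (full chains optionally
    kept via ``store_latents``); ``deviance`` is present when the run computed
    the per-draw deviance for DIC.
    """

    columns: list[str]
    baseline_columns: list[str]
    theta: np.ndarray                 # (R, p)
    theta_tilde: np.ndarray           # (R, pb)
    psi: np.ndarray                   # (R, S)
    upsilon: np.ndarray               # (R, S)
    variances: np.ndarray             # (R, 4) tau2, lambda2, zeta2, omega2
    latent_means: dict[str, np.ndarray]
    n_iter: int
    burn_in: int
    seed: int
    thin: int = 1
    deviance: np.ndarray | None = None
    mu09_draws: np.ndarray | None = None
    mudiff_draws: np.ndarray | None = None
    sigma2_draws: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.theta.shape[0]

    def chain(self, label: str) -> np.ndarray:
        """Scalar chain by label: a design column (Theta), 'tilde:<col>', or a
        variance name among tau2/lambda2/zeta2/omega2."""
        vnames = ("tau2", "lambda2", "zeta2", "omega2")
        if label in vnames:
            return self.variances[:, vnames.index(label)]
        if label.startswith("tilde:"):
            return self.theta_tilde[:, self.baseline_columns.index(label[6:])]
        return self.theta[:, self.columns.index(label)]

    def posterior_mean(self, label: str) -> float:
        return float(self.chain(label).mean())

    def ci(self, label: str, level: float = 0.95) -> tuple[float, float]:
        return equal_tail_ci(self.chain(label), level)

    def summary(self):
        import pandas as pd

        rows = []
        for c in self.columns:
            lo, hi = self.ci(c)
            rows.append({"coefficient": c, "model": "change",
                         "mean": self.posterior_mean(c), "ci_low": lo, "ci_high": hi})
        for c in self.baseline_columns:
            lo, hi = self.ci("tilde:" + c)
            rows.append({"coefficient": c, "model": "baseline",
                         "mean": self.posterior_mean("tilde:" + c),
                         "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def to_frame(self):
        """Flat per-draw data frame (one row per retained draw)."""
        import pandas as pd

        cols = {f"theta[{c}]": self.theta[:, i] for i, c in enumerate(self.columns)}
        cols.update({f"theta_tilde[{c}]": self.theta_tilde[:, i]
                     for i, c in enumerate(self.baseline_columns)})
        for i, v in enumerate(("tau2", "lambda2", "zeta2", "omega2")):
            cols[v] = self.variances[:, i]
        for s in range(self.psi.shape[1]):
            cols[f"psi[{s}]"] = self.psi[:, s]
            cols[f"upsilon[{s}]"] = self.upsilon[:, s]
        if self.deviance is not None:
            cols["deviance"] = self.deviance
        return pd.DataFrame(cols)


def equal_tail_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail credible interval via linear-interpolation (type-7) quantiles."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty chain")
    lo = (1.0 - level) / 2.0
    q = np.quantile(draws, [lo, 1.0 - lo])  # numpy default = linear interpolation
    return float(q[0]), float(q[1])


# --------------------------------------------------------------------------- #
# the sampler driver                                                          #
# --------------------------------------------------------------------------- #

def run_gibbs(data: ClinicData, design: DesignMatrix, *,
              prior_config: PriorConfig | None = None,
              n_iter: int = 100_000, burn_in: int = 10_000, thin: int = 1,
              seed: int = 0,
              baseline_design: DesignMatrix | None = None,
              system_effects: bool = True,
              collapsed: bool = True,
              measurement: Literal["off", "cut", "full"] = "off",
              ig: IGHyper | None = None,
              ig_age: IGHyper | None = None,
              compute_deviance: bool = False,
              store_latents: bool = False,
              fix_sigma2: float | None = None,
              fix_tau2: float | None = None,
              fix_lambda2: float | None = None,
              initial_state: GibbsState | None = None) -> PosteriorDraws:
    """Run the Gibbs sampler and return the retained draws.

    Update order per sweep: covariate latents (and latent design columns) →
    clinic means → outcome variances → Theta (marginal over psi) → psi →
    Theta~ (marginal over upsilon) → upsilon → hierarchical variances.  A single
    seeded generator drives every draw, so runs are exactly reproducible.

    ``baseline_design`` defaults to the change-model design (the shared-predictor
    requirement); pass an intercept-only design for the omitted-baseline (MS1)
    variant.  ``ig`` defaults to the empirical-Bayes prior moment-matched from
    the pooled clinic sample variances.  ``fix_sigma2``/``fix_tau2``/
    ``fix_lambda2`` pin those variances at known values instead of sampling
    them — the setting simulation studies use when the generating variances
    are part of the design.
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    prior_config = prior_config or PriorConfig()
    rng = np.random.default_rng(seed)

    design = DesignMatrix(X=design.X.copy(), columns=list(design.columns),
                          clinic_ids=design.clinic_ids,
                          system_index=design.system_index,
                          latent_columns=dict(design.latent_columns))
    if baseline_design is None:
        baseline_design = design
    elif baseline_design is not design:
        baseline_design = DesignMatrix(X=baseline_design.X.copy(),
                                       columns=list(baseline_design.columns),
                                       clinic_ids=baseline_design.clinic_ids,
                                       system_index=baseline_design.system_index,
                                       latent_columns=dict(baseline_design.latent_columns))
    baseline_shared = baseline_design is design

    if ig is None and fix_sigma2 is None:
        ig = empirical_bayes_from_sample_variances(
            data.pooled_sample_variance(), prior_config, label="outcome")
    if ig_age is None and measurement != "off" and data.age_s2 is not None:
        s2a = np.nanmean(np.where(np.isfinite(data.age_s2), data.age_s2, np.nan), axis=1)
        try:
            ig_age = empirical_bayes_from_sample_variances(s2a, prior_config, label="age")
        except ValueError:
            ig_age = IGHyper(3.0, 2.0, label="age")

    flat_sys = prior_config.system_effect_prior == "flat"
    if flat_sys:
        collapsed = False  # marginalising over an improper flat prior is undefined
    prior_ab = prior_config.variance_prior_ab
    cprec = prior_config.coef_prior_precision

    state = initial_state if initial_state is not None else init_state(
        data, design, prior_config, baseline_design=baseline_design)
    if not system_effects:
        state.psi[:] = 0.0
        state.upsilon[:] = 0.0
        state.zeta2 = 0.0
        state.omega2 = 0.0
    if fix_sigma2 is not None:
        state.sigma2 = np.full(data.n_clinics, float(fix_sigma2))
    if fix_tau2 is not None:
        state.tau2 = float(fix_tau2)
    if fix_lambda2 is not None:
        state.lambda2 = float(fix_lambda2)

    sysid = design.system_index
    n_ret = (n_iter - burn_in + thin - 1) // thin
    p, pb, S = design.X.shape[1], baseline_design.X.shape[1], data.n_systems
    out_theta = np.empty((n_ret, p))
    out_tilde = np.empty((n_ret, pb))
    out_psi = np.empty((n_ret, S))
    out_ups = np.empty((n_ret, S))
    out_var = np.empty((n_ret, 4))
    out_dev = np.empty(n_ret) if compute_deviance else None
    lat_mu09 = np.empty((n_ret, data.n_clinics)) if store_latents else None
    lat_mudiff = np.empty((n_ret, data.n_clinics)) if store_latents else None
    lat_sig = np.empty((n_ret, data.n_clinics)) if store_latents else None
    sums: dict[str, np.ndarray] = {}

    def accumulate(name, arr):
        if name in sums:
            sums[name] += arr
        else:
            sums[name] = np.array(arr, dtype=float)

    kept = 0
    for it in range(n_iter):
        if measurement == "cut":
            update_covariate_params(state, data, rng,
                                    beta_prior=prior_config.beta_prior, ig_age=ig_age)
            rebuild_latent_columns(design, state)
            if not baseline_shared:
                rebuild_latent_columns(baseline_design, state)
        elif measurement == "full":
            # latents feeding the regression get Metropolis steps targeting the
            # full conditional; the rest (plus sigma2_age) stay conjugate
            in_design = frozenset(_LATENT_FAMILIES[lab] for lab in design.latent_columns)
            update_covariate_params(state, data, rng,
                                    beta_prior=prior_config.beta_prior,
                                    ig_age=ig_age, exclude=in_design)
            rebuild_latent_columns(design, state)
            if not baseline_shared:
                rebuild_latent_columns(baseline_design, state)
            update_covariate_params_full(state, data, design, baseline_design, rng,
                                         beta_prior=prior_config.beta_prior,
                                         baseline_shared=baseline_shared)

        mean_base = baseline_design.X @ state.ThetaTilde + state.upsilon[sysid]
        mean_diff = design.X @ state.Theta + state.psi[sysid]
        state.mu09, state.mudiff = update_clinic_means(state, data, mean_base,
                                                       mean_diff, rng)
        if fix_sigma2 is None:
            state.sigma2 = update_outcome_variances(state, data, ig, rng)

        state.Theta = update_regression_coefficients(state, design, rng,
                                                     collapsed=collapsed,
                                                     prior_precision=cprec)
        if system_effects:
            r = state.mudiff - design.X @ state.Theta
            state.psi = update_system_effects(r, sysid, S, state.tau2, state.zeta2,
                                              rng, flat_prior=flat_sys)
        state.ThetaTilde = update_baseline_coefficients(state, baseline_design, rng,
                                                        collapsed=collapsed,
                                                        prior_precision=cprec)
        if system_effects:
            rb = state.mu09 - baseline_design.X @ state.ThetaTilde
            state.upsilon = update_system_effects(rb, sysid, S, state.lambda2,
                                                  state.omega2, rng,
                                                  flat_prior=flat_sys)
        tau2, lambda2, zeta2, omega2 = update_hier_variances(
            state, design, baseline_design, rng, prior_ab=prior_ab,
            system_effects=system_effects, flat_system_prior=flat_sys)
        state.tau2 = tau2 if fix_tau2 is None else state.tau2
        state.lambda2 = lambda2 if fix_lambda2 is None else state.lambda2
        state.zeta2, state.omega2 = zeta2, omega2

        if max(state.tau2, state.lambda2, state.zeta2, state.omega2) > VARIANCE_CEILING:
            raise RuntimeError(
                f"divergence guard: a hierarchical variance exceeded {VARIANCE_CEILING:g} "
                f"at iteration {it} (improper-prior pathology?)")

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_theta[kept] = state.Theta
            out_tilde[kept] = state.ThetaTilde
            out_psi[kept] = state.psi
            out_ups[kept] = state.upsilon
            out_var[kept] = (state.tau2, state.lambda2, state.zeta2, state.omega2)
            accumulate("mu09", state.mu09)
            accumulate("mudiff", state.mudiff)
            accumulate("sigma2", state.sigma2)
            if state.theta is not None:
                accumulate("theta", state.theta)
                accumulate("gamma", state.gamma)
                accumulate("kappa", state.kappa)
            if state.eta is not None:
                accumulate("eta", state.eta)
                accumulate("sigma2_age", state.sigma2_age)
            if store_latents:
                lat_mu09[kept] = state.mu09
                lat_mudiff[kept] = state.mudiff
                lat_sig[kept] = state.sigma2
            if compute_deviance:
                # DIC focus: system effects are parameters, so their prior
                # densities are excluded from the deviance (with the improper
                # log-uniform zeta2/omega2 priors those factors are unstable
                # and would swamp the model comparison)
                ll = log_joint_likelihood(data, design, baseline_design, state,
                                          system_effects=system_effects,
                                          hierarchical_system_prior=False,
                                          measurement=measurement != "off")
                if not np.isfinite(ll):
                    raise FloatingPointError(
                        f"non-finite deviance at retained draw {kept}")
                out_dev[kept] = -2.0 * ll
            kept += 1

    latent_means = {k: v / kept for k, v in sums.items()}
    return PosteriorDraws(
        columns=list(design.columns), baseline_columns=list(baseline_design.columns),
        theta=out_theta, theta_tilde=out_tilde, psi=out_psi, upsilon=out_ups,
        variances=out_var, latent_means=latent_means,
        n_iter=n_iter, burn_in=burn_in, seed=seed, thin=thin,
        deviance=out_dev, mu09_draws=lat_mu09, mudiff_draws=lat_mudiff,
        sigma2_draws=lat_sig,
        config={
            "system_effects": system_effects, "collapsed": collapsed,
            "measurement": measurement, "baseline_shared": baseline_shared,
            "prior": prior_config.to_dict(),
            "fixed": {"sigma2": fix_sigma2, "tau2": fix_tau2, "lambda2": fix_lambda2},
            "ig": [ig.shape, ig.scale] if ig is not None else None,
            "ig_age": [ig_age.shape, ig_age.scale] if ig_age is not None else None,
            "design_columns": list(design.columns),
            "baseline_columns": list(baseline_design.columns),
        },
    )


def compute_dic(draws: PosteriorDraws, data: ClinicData, design: DesignMatrix,
                baseline_design: DesignMatrix | None = None) -> float:
    """DIC = Dbar + pD with pD = Dbar − D(posterior-mean parameters).

    The deviance is −2 log of the hierarchical likelihood with the latent
    clinic means and system effects treated as parameters: the patient-outcome
    factors, the two clinic-level regression factors, and (when active) the
    covariate measurement factors.  The system-effect prior densities are not
    part of the deviance — under the log-uniform priors on their variances
    those factors are numerically unstable and carry no information about the
    candidate design columns.  ``draws`` must come from a
    ``compute_deviance=True`` run.
    """
    if draws.deviance is None:
        raise ValueError("run_gibbs(..., compute_deviance=True) is required for DIC")
    if draws.n_retained < 50:
        raise ValueError("need at least 50 retained draws for a stable DIC")
    dbar = float(draws.deviance.mean())
    if baseline_design is None:
        baseline_design = design

    lm = draws.latent_means
    mean_state = GibbsState(
        mu09=lm["mu09"], mudiff=lm["mudiff"], sigma2=lm["sigma2"],
        Theta=draws.theta.mean(axis=0), ThetaTilde=draws.theta_tilde.mean(axis=0),
        psi=draws.psi.mean(axis=0), upsilon=draws.upsilon.mean(axis=0),
        tau2=float(draws.variances[:, 0].mean()),
        lambda2=float(draws.variances[:, 1].mean()),
        zeta2=float(draws.variances[:, 2].mean()),
        omega2=float(draws.variances[:, 3].mean()),
        theta=lm.get("theta"), gamma=lm.get("gamma"), kappa=lm.get("kappa"),
        eta=lm.get("eta"), sigma2_age=lm.get("sigma2_age"),
    )
    measurement = draws.config.get("measurement", "off") != "off"
    d_at_mean = DesignMatrix(X=design.X.copy(), columns=list(design.columns),
                             clinic_ids=design.clinic_ids,
                             system_index=design.system_index,
                             latent_columns=dict(design.latent_columns))
    b_at_mean = d_at_mean if baseline_design is design else DesignMatrix(
        X=baseline_design.X.copy(), columns=list(baseline_design.columns),
        clinic_ids=baseline_design.clinic_ids,
        system_index=baseline_design.system_index,
        latent_columns=dict(baseline_design.latent_columns))
    if measurement:
        rebuild_latent_columns(d_at_mean, mean_state)
        if b_at_mean is not d_at_mean:
            rebuild_latent_columns(b_at_mean, mean_state)
    d_hat = -2.0 * log_joint_likelihood(
        data, d_at_mean, b_at_mean, mean_state,
        system_effects=draws.config.get("system_effects", True),
        hierarchical_system_prior=False, measurement=measurement)
    return 2.0 * dbar - d_hat


def intercept_only_design(design: DesignMatrix) -> DesignMatrix:
    """Baseline design with just the all-ones column (the MS1 mean structure)."""
    return DesignMatrix(X=np.ones((design.n_clinics, 1)), columns=["intercept"],
                        clinic_ids=design.clinic_ids,
                        system_index=design.system_index, latent_columns={})
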