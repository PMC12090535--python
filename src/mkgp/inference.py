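"""Bayesian fitting of multi-kernel mixed models by Gibbs sampling.

Model
-----
For observations ``y`` (one per line x environment x replicate),

    y = X beta + sum_r u_r + eps,        eps ~ N(0, sigma_e^2 I)

where ``X`` is the intercept design (a single column of ones, or one
indicator column per environment), and each random effect enters at the
observation level with covariance ``sigma_r^2 K_r`` — ``K_r`` being the
line-level kernel expanded through its incidence matrix (Z K Z'), or an
observation-level kernel (G x E, per-sample transcriptome) used directly.

Every variance component carries a scaled inverse-chi-square prior, the
conjugate choice that yields closed-form Gibbs updates; the intercept prior
is flat.

The eigen trick
---------------
Each observation-level kernel is eigendecomposed once, K = U Lambda U'.
Writing the effect as u = U s with s ~ N(0, sigma^2 Lambda) (zero
eigenvalues truncated), the full conditional of ``s`` factorises over
coordinates because U has orthonormal columns:

    s_i | rest ~ N( c_i / (sigma_e^2 d_i), 1 / d_i ),
    d_i = 1/sigma_e^2 + 1/(sigma^2 lambda_i),  c = U' (residual + u)

so every sweep costs two thin-matrix products per term instead of a dense
solve against K.  ``gibbs_fit_dense`` implements the same model without the
transformation (covariance-form conditionals) and exists to validate the
transformed sampler.

Prediction uses whole-kernel conditioning: kernels are built over all lines,
held-out phenotypes are passed as NaN and treated as missing data — imputed
from the current model state each sweep, so the masked values themselves
never influence the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import warn
from .kernels import IncidenceMatrix, KernelMatrix

__all__ = [
    "ScaledInvChi2",
    "RandomEffectTerm",
    "ModelSpec",
    "ChainConfig",
    "EigenKernel",
    "PosteriorSamples",
    "eigendecompose",
    "gibbs_fit",
    "gibbs_fit_dense",
    "posterior_predict",
    "gebv",
]

#: floor applied to sampled variances to avoid degenerate chi-square draws
VARIANCE_FLOOR = 1e-10

#: genetic kernel kinds whose posterior means constitute the GEBV
GENETIC_KINDS = frozenset({"G", "EPI", "A", "GAUSS"})


@dataclass
class ScaledInvChi2:
    """Scaled inverse-chi-square prior for a variance component.

    ``scale=None`` defers to the data-driven default: degrees of freedom 5
    and scale chosen so the prior mode equals an equal share of the
    phenotypic variance (split among all terms plus the residual), the rule
    popularised by Bayesian genomic-regression software.
    """

    df: float = 5.0
    scale: float | None = None

    def __post_init__(self):
        if self.df <= 0:
            raise ValueError("prior df must be positive")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("prior scale must be positive")


@dataclass
class RandomEffectTerm:
    """One random effect: a kernel, an optional incidence map, a prior.

    ``incidence=None`` means the kernel is already at observation level.
    ``genetic`` marks terms whose effects count toward breeding values.
    """

    name: str
    kernel: KernelMatrix
    incidence: IncidenceMatrix | None = None
    prior: ScaledInvChi2 = field(default_factory=ScaledInvChi2)
    genetic: bool | None = None

    def __post_init__(self):
        if self.genetic is None:
            self.genetic = self.kernel.kind in GENETIC_KINDS
        if self.incidence is not None and not np.array_equal(
            self.incidence.col_ids, self.kernel.axis_ids
        ):
            raise ValueError(
                f"term {self.name!r}: incidence columns do not match kernel axis ids"
            )

    def obs_kernel(self) -> np.ndarray:
        """Observation-level covariance structure Z K Z' (or K itself).

        Cached: CV refits the same model with different phenotype masks, so
        the expansion and its eigendecomposition are computed once.
        """
        cached = getattr(self, "_obs_kernel", None)
        if cached is None:
            if self.incidence is None:
                cached = self.kernel.entries
            else:
                Z = self.incidence.entries
                cached = Z @ self.kernel.entries @ Z.T
            object.__setattr__(self, "_obs_kernel", cached)
        return cached

    def eigen(self) -> "EigenKernel":
        cached = getattr(self, "_eigen", None)
        if cached is None:
            cached = eigendecompose(self.obs_kernel())
            object.__setattr__(self, "_eigen", cached)
        return cached

    def obs_ids(self) -> np.ndarray:
        if self.incidence is None:
            return self.kernel.axis_ids
        return self.incidence.row_ids


@dataclass
class ModelSpec:
    """Intercept structure plus an ordered list of random-effect terms.

    ``environments`` (one label per observation) activates per-environment
    intercepts mu_j; otherwise a single mu is fitted.
    """

    terms: list[RandomEffectTerm]
    environments: np.ndarray | None = None
    residual_prior: ScaledInvChi2 = field(default_factory=ScaledInvChi2)
    obs_ids: np.ndarray | None = None

    def __post_init__(self):
        if not self.terms:
            raise ValueError("a model needs at least one random-effect term")
        n = self.n_obs
        for t in self.terms:
            if t.obs_kernel().shape[0] != n:
                raise ValueError(f"term {t.name!r} has observation dimension != {n}")
        if self.obs_ids is None:
            self.obs_ids = self.terms[0].obs_ids()
        if self.environments is not None:
            self.environments = np.asarray(self.environments, dtype=object)
            if len(self.environments) != n:
                raise ValueError("environments length does not match observations")

    @property
    def n_obs(self) -> int:
        return self.terms[0].obs_kernel().shape[0]

    def intercept_design(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, column labels) for the intercept structure."""
        n = self.n_obs
        if self.environments is None:
            return np.ones((n, 1)), np.array(["mu"], dtype=object)
        envs = list(dict.fromkeys(self.environments))
        X = np.column_stack([(self.environments == e).astype(float) for e in envs])
        return X, np.array([f"mu[{e}]" for e in envs], dtype=object)


@dataclass
class ChainConfig:
    """Gibbs chain settings (iterations include burn-in)."""

    iterations: int = 12_000
    burn_in: int = 2_000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class EigenKernel:
    """Eigendecomposition K = U Lambda U' with zero-truncated spectrum."""

    U: np.ndarray
    eigenvalues: np.ndarray
    rank: int

    @property
    def n(self) -> int:
        return self.U.shape[0]


def eigendecompose(
    K: KernelMatrix | np.ndarray, truncate_rtol: float = 1e-10
) -> EigenKernel:
    """Eigendecompose a symmetric PSD kernel, clipping and truncating.

    Eigenvalues below ``truncate_rtol * lambda_max`` are dropped (with the
    retained rank recorded); slightly negative ones (float noise) are
    clipped at zero first.
    """
    M = K.entries if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("kernel is not symmetric")
    w, U = np.linalg.eigh(0.5 * (M + M.T))
    lam_max = max(w[-1], 0.0)
    if lam_max <= 0:
        raise ValueError("kernel has no positive eigenvalues")
    if w[0] < -1e-8 * lam_max:
        raise ValueError(f"kernel is not PSD (lambda_min = {w[0]:.3g})")
    w = np.clip(w, 0.0, None)
    keep = w > truncate_rtol * lam_max
    return EigenKernel(U=U[:, keep], eigenvalues=w[keep], rank=int(keep.sum()))


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws plus chain metadata.

    ``effects[name]`` has shape (n_draws, n_obs) — observation-level draws
    of each random effect; ``variances[name]`` and ``variances['residual']``
    are the variance-component chains; ``intercepts`` has one column per
    intercept coefficient.
    """

    intercepts: np.ndarray
    intercept_labels: np.ndarray
    variances: dict[str, np.ndarray]
    effects: dict[str, np.ndarray]
    chain: ChainConfig
    obs_ids: np.ndarray
    realised_priors: dict[str, tuple[float, float]]

    @property
    def n_draws(self) -> int:
        return self.intercepts.shape[0]

    def variance_summary(self) -> dict[str, tuple[float, float]]:
        """Posterior mean and sd of each variance component."""
        return {k: (float(v.mean()), float(v.std())) for k, v in self.variances.items()}

    def effective_sample_size(self, name: str) -> float:
        """Initial-positive-sequence ESS estimate for a variance chain."""
        x = self.variances[name]
        x = x - x.mean()
        n = len(x)
        if n < 10 or x.std() == 0:
            return float(n)
        acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
        s, t = 0.0, 1
        while t < n - 1 and acf[t] + acf[t + 1] > 0:
            s += acf[t] + acf[t + 1]
            t += 2
        return float(n / (1.0 + 2.0 * s))


def _default_priors(
    model: ModelSpec, y_obs: np.ndarray, obs_kernels: list[np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Realised (df, scale) per component under the equal-share mode rule."""
    vy = float(np.var(y_obs))
    if vy <= 0:
        vy = 1.0
    share = 0.5 / max(len(model.terms), 1)
    out: dict[str, tuple[float, float]] = {}
    for term, K in zip(model.terms, obs_kernels):
        df = term.prior.df
        if term.prior.scale is not None:
            out[term.name] = (df, term.prior.scale)
        else:
            md = max(float(np.mean(np.diag(K))), 1e-12)
            mode = share * vy / md
            out[term.name] = (df, mode * (df + 2.0) / df)
    df_e = model.residual_prior.df
    if model.residual_prior.scale is not None:
        out["residual"] = (df_e, model.residual_prior.scale)
    else:
        out["residual"] = (df_e, 0.5 * vy * (df_e + 2.0) / df_e)
    return out


def _sample_scaled_inv_chi2(rng, df: float, ss: float, n: float) -> float:
    """Draw from ScaledInvChi2(df + n, (df*scale*? + ss)/(df + n)) given ss = df*S + SS."""
    return ss / rng.chisquare(df + n)


def gibbs_fit(
    y: np.ndarray,
    model: ModelSpec,
    chain: ChainConfig | None = None,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Fit a multi-kernel model by the eigen-transformed Gibbs sampler.

    Parameters
    ----------
    y
        Observation vector; NaN entries are treated as missing (e.g. masked
        test phenotypes) and imputed by data augmentation each sweep.
    model
        Terms, intercept structure and priors.
    chain
        Iterations / burn-in / thinning / seed.
    fixed_variances
        Optional map (term name or ``'residual'``) -> value; listed
        components are held fixed instead of sampled (used for validation
        against closed-form mixed-model solutions).
    """
    chain = chain or ChainConfig()
    y = np.asarray(y, dtype=float).ravel()
    n = model.n_obs
    if len(y) != n:
        raise ValueError(f"y has {len(y)} entries; model expects {n}")
    observed = np.isfinite(y)
    if observed.sum() < 3:
        raise ValueError("need at least 3 observed phenotypes")
    fixed_variances = fixed_variances or {}

    rng = np.random.default_rng(chain.seed)
    X, x_labels = model.intercept_design()
    xtx = X.sum(axis=0)  # indicator columns: X'X is diagonal

    obs_kernels = [t.obs_kernel() for t in model.terms]
    eigs = [t.eigen() for t in model.terms]
    priors = _default_priors(model, y[observed], obs_kernels)

    # state
    y_work = y.copy()
    y_work[~observed] = float(np.mean(y[observed]))
    beta = np.linalg.lstsq(X[observed], y[observed], rcond=None)[0]
    s_list = [np.zeros(e.rank) for e in eigs]
    u_list = [np.zeros(n) for _ in eigs]
    sig = {
        t.name: fixed_variances.get(
            t.name, priors[t.name][1] * priors[t.name][0] / (priors[t.name][0] + 2.0)
        )
        for t in model.terms
    }
    sig_e = fixed_variances.get(
        "residual",
        priors["residual"][1] * priors["residual"][0] / (priors["residual"][0] + 2.0),
    )

    n_draws = chain.n_draws
    draws_beta = np.empty((n_draws, X.shape[1]))
    draws_var = {t.name: np.empty(n_draws) for t in model.terms}
    draws_var["residual"] = np.empty(n_draws)
    draws_u = {t.name: np.empty((n_draws, n)) for t in model.terms}

    e = y_work - X @ beta - np.sum(u_list, axis=0)
    d = 0
    for it in range(chain.iterations):
        # --- impute missing phenotypes from the current model state
        if not observed.all():
            fitted_miss = (X @ beta + np.sum(u_list, axis=0))[~observed]
            new_miss = fitted_miss + np.sqrt(sig_e) * rng.standard_normal(fitted_miss.size)
            e[~observed] += new_miss - y_work[~observed]
            y_work[~observed] = new_miss

        # --- intercept(s), flat prior
        e += X @ beta
        bhat = (X.T @ e) / xtx
        beta = bhat + np.sqrt(sig_e / xtx) * rng.standard_normal(len(bhat))
        e -= X @ beta

        # --- each random effect in its eigenbasis (diagonal conditional)
        for r, (term, eig) in enumerate(zip(model.terms, eigs)):
            lam = eig.eigenvalues
            e += u_list[r]
            c = eig.U.T @ e
            prec = 1.0 / sig_e + 1.0 / (sig[term.name] * lam)
            s = c / (sig_e * prec) + rng.standard_normal(eig.rank) / np.sqrt(prec)
            s_list[r] = s
            u_list[r] = eig.U @ s
            e -= u_list[r]
            if term.name not in fixed_variances:
                df, S = priors[term.name]
                ss = df * S + float(np.sum(s * s / lam))
                sig[term.name] = max(
                    _sample_scaled_inv_chi2(rng, df, ss, eig.rank), VARIANCE_FLOOR
                )

        # --- residual variance
        if "residual" not in fixed_variances:
            df_e, S_e = priors["residual"]
            ss = df_e * S_e + float(e @ e)
            sig_e = max(_sample_scaled_inv_chi2(rng, df_e, ss, n), VARIANCE_FLOOR)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thinning == 0 and d < n_draws:
            draws_beta[d] = beta
            for r, t in enumerate(model.terms):
                draws_var[t.name][d] = sig[t.name]
                draws_u[t.name][d] = u_list[r]
            draws_var["residual"][d] = sig_e
            d += 1

    samples = PosteriorSamples(
        intercepts=draws_beta,
        intercept_labels=x_labels,
        variances=draws_var,
        effects=draws_u,
        chain=chain,
        obs_ids=model.obs_ids,
        realised_priors=priors,
    )
    for name in [t.name for t in model.terms] + ["residual"]:
        if name in fixed_variances:
            continue
        ess = samples.effective_sample_size(name)
        if ess < 100:
            warn("LOW_ESS", f"effective sample size {ess:.0f} < 100 for variance '{name}'")
    return samples


def gibbs_fit_dense(
    y: np.ndarray,
    model: ModelSpec,
    chain: ChainConfig | None = None,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Reference Gibbs sampler working directly with dense kernels.

    Identical model and priors as :func:`gibbs_fit` but samples each effect
    from its joint multivariate-normal conditional in covariance form
    (no eigen-transformed likelihood).  Quadratic forms u' K^+ u use the
    pseudo-inverse on the kernel's range.  Only intended for validating the
    transformed sampler on small instances.
    """
    chain = chain or ChainConfig()
    y = np.asarray(y, dtype=float).ravel()
    n = model.n_obs
    observed = np.isfinite(y)
    fixed_variances = fixed_variances or {}
    rng = np.random.default_rng(chain.seed)
    X, x_labels = model.intercept_design()
    xtx = X.sum(axis=0)

    obs_kernels = [t.obs_kernel() for t in model.terms]
    priors = _default_priors(model, y[observed], obs_kernels)
    eigs = [eigendecompose(K) for K in obs_kernels]  # for pinv/rank only
    pinvs = [(e.U / e.eigenvalues) @ e.U.T for e in eigs]
    ranks = [e.rank for e in eigs]

    y_work = y.copy()
    y_work[~observed] = float(np.mean(y[observed]))
    beta = np.linalg.lstsq(X[observed], y[observed], rcond=None)[0]
    u_list = [np.zeros(n) for _ in model.terms]
    sig = {
        t.name: fixed_variances.get(
            t.name, priors[t.name][1] * priors[t.name][0] / (priors[t.name][0] + 2.0)
        )
        for t in model.terms
    }
    sig_e = fixed_variances.get(
        "residual",
        priors["residual"][1] * priors["residual"][0] / (priors["residual"][0] + 2.0),
    )

    n_draws = chain.n_draws
    draws_beta = np.empty((n_draws, X.shape[1]))
    draws_var = {t.name: np.empty(n_draws) for t in model.terms}
    draws_var["residual"] = np.empty(n_draws)
    draws_u = {t.name: np.empty((n_draws, n)) for t in model.terms}

    eye = np.eye(n)
    d = 0
    for it in range(chain.iterations):
        if not observed.all():
            fitted_miss = (X @ beta + np.sum(u_list, axis=0))[~observed]
            y_work[~observed] = fitted_miss + np.sqrt(sig_e) * rng.standard_normal(
                fitted_miss.size
            )
        total_u = np.sum(u_list, axis=0)
        resid0 = y_work - total_u
        bhat = (X.T @ resid0) / xtx
        beta = bhat + np.sqrt(sig_e / xtx) * rng.standard_normal(len(bhat))

        for r, (term, K) in enumerate(zip(model.terms, obs_kernels)):
            e_r = y_work - X @ beta - (np.sum(u_list, axis=0) - u_list[r])
            Ks = sig[term.name] * K
            C = Ks @ np.linalg.inv(Ks + sig_e * eye)
            mean = C @ e_r
            cov = Ks - C @ Ks
            cov = 0.5 * (cov + cov.T)
            w, V = np.linalg.eigh(cov)
            u_list[r] = mean + (V * np.sqrt(np.clip(w, 0.0, None))) @ rng.standard_normal(n)
            if term.name not in fixed_variances:
                df, S = priors[term.name]
                quad = float(u_list[r] @ pinvs[r] @ u_list[r])
                sig[term.name] = max(
                    _sample_scaled_inv_chi2(rng, df, df * S + quad, ranks[r]),
                    VARIANCE_FLOOR,
                )

        e = y_work - X @ beta - np.sum(u_list, axis=0)
        if "residual" not in fixed_variances:
            df_e, S_e = priors["residual"]
            sig_e = max(
                _sample_scaled_inv_chi2(rng, df_e, df_e * S_e + float(e @ e), n),
                VARIANCE_FLOOR,
            )

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thinning == 0 and d < n_draws:
            draws_beta[d] = beta
            for r, t in enumerate(model.terms):
                draws_var[t.name][d] = sig[t.name]
                draws_u[t.name][d] = u_list[r]
            draws_var["residual"][d] = sig_e
            d += 1

    return PosteriorSamples(
        intercepts=draws_beta,
        intercept_labels=x_labels,
        variances=draws_var,
        effects=draws_u,
        chain=chain,
        obs_ids=model.obs_ids,
        realised_priors=priors,
    )


def fitted_values(samples: PosteriorSamples, model: ModelSpec) -> np.ndarray:
    """Posterior-mean fitted value for every observation."""
    X, _ = model.intercept_design()
    out = X @ samples.intercepts.mean(axis=0)
    for t in model.terms:
        out = out + samples.effects[t.name].mean(axis=0)
    return out


def posterior_predict(
    samples: PosteriorSamples,
    model: ModelSpec,
    target_obs: Sequence | np.ndarray | None = None,
) -> np.ndarray:
    """Posterior predictive mean at the requested observations.

    Under whole-kernel conditioning every candidate observation is already a
    row of the model (its phenotype may have been masked); ``target_obs``
    selects rows by observation id.  ``None`` predicts all observations.
    """
    fit = fitted_values(samples, model)
    if target_obs is None:
        return fit
    index = {o: i for i, o in enumerate(model.obs_ids)}
    rows = []
    for o in target_obs:
        if o not in index:
            raise KeyError(
                f"observation {o!r} is not on the model's kernel axes; "
                "whole-kernel conditioning requires test lines in every kernel"
            )
        rows.append(index[o])
    return fit[rows]


def gebv(
    samples: PosteriorSamples,
    model: ModelSpec,
    line_of_obs: np.ndarray | None = None,
) -> "pd.Series":
    """Genomic estimated breeding values: per-line posterior mean of the
    genetic random effects (additive, epistatic, dominance, or the combined
    Gaussian term), excluding transcriptome and G x E terms.

    ``line_of_obs`` maps each observation to its line; by default it is
    recovered from the genetic terms' incidence matrices.
    """
    import pandas as pd

    genetic_terms = [t for t in model.terms if t.genetic]
    if not genetic_terms:
        raise ValueError("model contains no genetic term; GEBV undefined")
    total = np.zeros(model.n_obs)
    for t in genetic_terms:
        total = total + samples.effects[t.name].mean(axis=0)
    if line_of_obs is None:
        for t in genetic_terms:
            if t.incidence is not None:
                line_of_obs = t.incidence.entries @ np.arange(len(t.incidence.col_ids))
                lines = t.incidence.col_ids
                labels = lines[line_of_obs.astype(int)]
                break
        else:
            labels = model.obs_ids
    else:
        labels = np.asarray(line_of_obs, dtype=object)
    s = pd.Series(total, index=pd.Index(labels, name="line"))
    return s.groupby(level=0, sort=False).mean()
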