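"""Bayesian multi-kernel mixed models fitted by Gibbs sampling.

The general model is

    y = mu 1 + Xf beta + sum_r u_r + eps,

with each random effect u_r ~ N(0, sigma2_r K_r) for a known PSD kernel
K_r, eps ~ N(0, sigma2_e I), flat priors on (mu, beta) and scaled
inverse-chi-square priors on the variance components. Each u_r is sampled
in the eigenbasis of its kernel (one eigendecomposition per kernel per
fit), which makes every Gibbs update O(n^2). Missing phenotypes are
handled by data augmentation; their posterior-predictive mean is the
reported prediction.

The module also provides the marginal likelihood m(y) of the one-kernel
model — with u and mu integrated analytically and the two variance
components integrated by quadrature on a log-scale grid — which drives
the selection of the arc-cosine layer count l and the Gaussian
bandwidth h on training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .kernels import (
    KernelMatrix,
    KernelError,
    PSD_TOL,
    arc_cosine_layer1,
    arc_cosine_step,
    expand_to_observations,
    gaussian_kernel,
    ge_interaction_kernel,
    MarkerMatrix,
    EnvironmentDesign,
)
from .phenotypes import PhenotypeTable

#: eigenvalues below EIG_TOL * lambda_max are treated as exactly zero
EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Scaled inverse-chi-square priors for the variance components.

    ``df`` is shared by all components. ``scales`` maps a term label (or
    ``"residual"``) to the prior scale; any unset scale is resolved at fit
    time so that the prior mode splits the sample phenotypic variance
    equally between the random terms and the residual, each term's share
    divided by the mean diagonal of its kernel so that kernels of
    different magnitude (e.g. arc-cosine vs. GBLUP) receive comparable
    prior mass on the same effective variance.

    ``df = inf`` fixes every variance at its (then required) scale — used
    for closed-form BLUP cross-checks.
    """

    df: float = 5.0
    scales: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (self.df > 0):
            raise ValueError("prior df must be positive")
        if np.isinf(self.df) and self.scales is None:
            raise ValueError("df=inf (fixed variances) requires explicit scales")


@dataclass
class McmcSettings:
    """Gibbs chain length controls (defaults: 30,000 draws, 5,000 burn-in,
    thinning every 3)."""

    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Full model description passed to :func:`gibbs_fit`.

    ``fixed_effects`` is an (n_obs, k) design matrix beyond the intercept
    (possibly k=0); ``random_terms`` is an ordered list of
    (label, n_obs x n_obs kernel) pairs.
    """

    random_terms: list[tuple[str, np.ndarray]]
    fixed_effects: np.ndarray | None = None
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def __post_init__(self) -> None:
        if not self.random_terms:
            raise ValueError("at least one random term is required")
        labels = [lab for lab, _ in self.random_terms]
        if len(set(labels)) != len(labels):
            raise ValueError("random term labels must be unique")


@dataclass
class FitResult:
    """Posterior summaries and predictions from one Gibbs run."""

    mu_mean: float
    mu_sd: float
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    u_mean: dict[str, np.ndarray]
    u_sd: dict[str, np.ndarray]
    var_samples: dict[str, np.ndarray]
    predicted: np.ndarray
    n_samples: int
    seed: int

    @property
    def var_mean(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.var_samples.items()}

    @property
    def var_sd(self) -> dict[str, float]:
        return {k: float(v.std(ddof=1)) for k, v in self.var_samples.items()}

    def heritability_samples(self, term: str, mean_diag: float = 1.0) -> np.ndarray:
        """Posterior samples of the variance share of ``term``.

        ``mean_diag`` converts sigma2_term to the effective genetic
        variance when the kernel diagonal is not ~1.
        """
        g = self.var_samples[term] * mean_diag
        return g / (g + self.var_samples["residual"])


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _eigendecompose(K: np.ndarray, label: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Reduced-rank eigendecomposition; negative eigenvalues within the PSD
    tolerance are truncated to zero, larger negativity is an error."""
    K = np.asarray(K, dtype=float)
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    lam_max = max(float(w[-1]), 0.0)
    if w[0] < -PSD_TOL * max(lam_max, 1.0):
        raise KernelError(f"kernel {label!r} is not PSD (lambda_min={w[0]:.3e})")
    keep = w > EIG_TOL * max(lam_max, 1.0)
    if not keep.any():
        raise KernelError(f"kernel {label!r} has rank zero")
    return w[keep], U[:, keep]


def _resolve_scales(prior: PriorSpec, y_obs: np.ndarray,
                    terms: list[tuple[str, np.ndarray]]) -> dict[str, float]:
    scales = dict(prior.scales or {})
    vy = float(np.var(y_obs, ddof=1)) if y_obs.size > 1 else 1.0
    vy = max(vy, 1e-12)
    share = vy / (len(terms) + 1)
    df = prior.df
    mode_factor = 1.0 if np.isinf(df) else (df + 2.0) / df
    for lab, K in terms:
        if lab not in scales:
            md = max(float(np.mean(np.diag(K))), 1e-300)
            scales[lab] = share / md * mode_factor
    if "residual" not in scales:
        scales["residual"] = share * mode_factor
    return scales


def gibbs_fit(y: np.ndarray, spec: ModelSpec) -> FitResult:
    """Gibbs sampler for the multi-kernel mixed model.

    ``y`` may contain NaN for records to predict; those are imputed by
    data augmentation each iteration and receive posterior-predictive
    means ``mu + Xf beta + sum_r u_r`` in ``FitResult.predicted`` (as do
    all records).
    """
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    miss = ~np.isfinite(y)
    if miss.all():
        raise ValueError("all observations are missing")
    for lab, K in spec.random_terms:
        K = np.asarray(K)
        if K.shape != (n, n):
            raise ValueError(f"kernel {lab!r} shape {K.shape} does not match n={n}")

    Xf = spec.fixed_effects
    if Xf is None:
        W = np.ones((n, 1))
    else:
        Xf = np.asarray(Xf, dtype=float)
        if Xf.ndim != 2 or Xf.shape[0] != n:
            raise ValueError("fixed_effects must be (n_obs, k)")
        W = np.column_stack([np.ones(n), Xf])
    k_fix = W.shape[1]
    WtW = W.T @ W
    try:
        WtW_chol = np.linalg.cholesky(np.linalg.inv(WtW))
    except np.linalg.LinAlgError as exc:
        raise ValueError("fixed-effect design is rank deficient") from exc
    WtW_inv = np.linalg.inv(WtW)

    decomp = [(lab, *_eigendecompose(K, lab)) for lab, K in spec.random_terms]
    labels = [lab for lab, _, _ in decomp]

    scales = _resolve_scales(spec.prior, y[~miss], spec.random_terms)
    df0 = spec.prior.df
    fixed_var = np.isinf(df0)

    rng = np.random.default_rng(spec.mcmc.seed)

    # state
    y_cur = y.copy()
    y_cur[miss] = float(np.mean(y[~miss]))
    sigma2 = {lab: scales[lab] for lab in labels}
    sigma2_e = scales["residual"]
    alpha = {lab: np.zeros(lam.size) for lab, lam, _ in decomp}
    u = {lab: np.zeros(n) for lab in labels}
    gamma = np.zeros(k_fix)
    fixed_part = W @ gamma
    total_u = np.zeros(n)
    resid = y_cur - fixed_part - total_u

    mc = spec.mcmc
    n_keep = mc.n_samples
    var_samples = {lab: np.empty(n_keep) for lab in labels}
    var_samples["residual"] = np.empty(n_keep)
    gamma_sum = np.zeros(k_fix)
    gamma_sq = np.zeros(k_fix)
    u_sum = {lab: np.zeros(n) for lab in labels}
    u_sq = {lab: np.zeros(n) for lab in labels}
    yhat_sum = np.zeros(n)
    kept = 0

    for it in range(mc.n_iter):
        # fixed effects (flat prior)
        e_f = y_cur - total_u
        mean_g = WtW_inv @ (W.T @ e_f)
        gamma = mean_g + math.sqrt(sigma2_e) * (WtW_chol @ rng.standard_normal(k_fix))
        new_fixed = W @ gamma
        resid += fixed_part - new_fixed
        fixed_part = new_fixed

        # random terms in their eigenbases
        for lab, lam, U in decomp:
            e_r = resid + u[lab]
            t = U.T @ e_r
            v = 1.0 / (1.0 / sigma2_e + 1.0 / (sigma2[lab] * lam))
            m = v * t / sigma2_e
            a = m + np.sqrt(v) * rng.standard_normal(lam.size)
            alpha[lab] = a
            u_new = U @ a
            total_u += u_new - u[lab]
            resid = e_r - u_new
            u[lab] = u_new

        # variance components
        if not fixed_var:
            for lab, lam, _ in decomp:
                ss = float(np.sum(alpha[lab] ** 2 / lam))
                dfp = df0 + lam.size
                sigma2[lab] = (df0 * scales[lab] + ss) / rng.chisquare(dfp)
            ss_e = float(resid @ resid)
            sigma2_e = (df0 * scales["residual"] + ss_e) / rng.chisquare(df0 + n)

        # impute missing records
        if miss.any():
            mu_miss = fixed_part[miss] + total_u[miss]
            y_cur[miss] = mu_miss + math.sqrt(sigma2_e) * rng.standard_normal(miss.sum())
            resid[miss] = y_cur[miss] - mu_miss

        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            for lab in labels:
                var_samples[lab][kept] = sigma2[lab]
            var_samples["residual"][kept] = sigma2_e
            gamma_sum += gamma
            gamma_sq += gamma**2
            for lab in labels:
                u_sum[lab] += u[lab]
                u_sq[lab] += u[lab] ** 2
            yhat_sum += fixed_part + total_u
            kept += 1

    assert kept == n_keep

    def _msd(s, sq):
        m = s / kept
        var = np.maximum(sq / kept - m**2, 0.0)
        return m, np.sqrt(var)

    g_mean, g_sd = _msd(gamma_sum, gamma_sq)
    u_mean, u_sd = {}, {}
    for lab in labels:
        u_mean[lab], u_sd[lab] = _msd(u_sum[lab], u_sq[lab])
    return FitResult(
        mu_mean=float(g_mean[0]),
        mu_sd=float(g_sd[0]),
        beta_mean=g_mean[1:],
        beta_sd=g_sd[1:],
        u_mean=u_mean,
        u_sd=u_sd,
        var_samples=var_samples,
        predicted=yhat_sum / kept,
        n_samples=kept,
        seed=mc.seed,
    )


# ---------------------------------------------------------------------------
# marginal likelihood and hyperparameter selection
# ---------------------------------------------------------------------------


def _log_scaled_inv_chi2(x: np.ndarray, df: float, scale: float) -> np.ndarray:
    """Log density of the scaled inverse-chi-square distribution."""
    half = df / 2.0
    return (
        half * np.log(half * scale)
        - gammaln(half)
        - (1.0 + half) * np.log(x)
        - half * scale / x
    )


def marginal_likelihood(
    y: np.ndarray,
    K: KernelMatrix | np.ndarray,
    prior: PriorSpec | None = None,
    n_grid: int = 61,
    span: tuple[float, float] = (1e-4, 1e2),
) -> float:
    """Log marginal likelihood ``log m(y)`` of the one-kernel model.

    The random effect u and the intercept mu are integrated analytically
    (both Gaussian, flat prior on mu); the remaining two-dimensional
    integral over (sigma2_u, sigma2_e) is evaluated by trapezoid
    quadrature on a logarithmic grid spanning ``span`` times the sample
    phenotypic variance (the genetic axis additionally divided by the
    mean kernel diagonal so kernels of any magnitude are treated
    comparably). Deterministic given inputs.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("marginal likelihood requires complete (training) records")
    n = y.size
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if Kv.shape != (n, n):
        raise ValueError("kernel shape does not match y")
    prior = prior or PriorSpec()
    if np.isinf(prior.df):
        raise ValueError("marginal likelihood needs a proper (finite-df) prior")

    w, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
    lam_max = max(float(w[-1]), 0.0)
    if w[0] < -PSD_TOL * max(lam_max, 1.0):
        raise KernelError("kernel is not PSD")
    lam = np.clip(w, 0.0, None)

    vy = max(float(np.var(y, ddof=1)), 1e-12)
    md = max(float(np.mean(np.diag(Kv))), 1e-300)
    scales = _resolve_scales(prior, y, [("u", Kv)])
    s_u, s_e = scales["u"], scales["residual"]

    su = np.geomspace(span[0] * vy / md, span[1] * vy / md, n_grid)
    se = np.geomspace(span[0] * vy, span[1] * vy, n_grid)

    yt = U.T @ y
    ot = U.T @ np.ones(n)

    # D[j, a, b] = su[a] * lam[j] + se[b]
    D = lam[:, None, None] * su[None, :, None] + se[None, None, :]
    logdet = np.sum(np.log(D), axis=0)
    a_q = np.sum(ot[:, None, None] ** 2 / D, axis=0)
    b_q = np.sum((ot * yt)[:, None, None] / D, axis=0)
    c_q = np.sum(yt[:, None, None] ** 2 / D, axis=0)
    loglik = -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(a_q) + c_q - b_q**2 / a_q)

    lp_u = _log_scaled_inv_chi2(su, prior.df, s_u)
    lp_e = _log_scaled_inv_chi2(se, prior.df, s_e)

    def _logw(grid):
        dl = np.log(grid[1] / grid[0])
        w_ = np.full(grid.size, dl)
        w_[0] = w_[-1] = dl / 2.0
        return np.log(w_)

    # d sigma2 = sigma2 d log sigma2 -> add log sigma2 Jacobians
    terms = (
        loglik
        + lp_u[:, None] + lp_e[None, :]
        + np.log(su)[:, None] + np.log(se)[None, :]
        + _logw(su)[:, None] + _logw(se)[None, :]
    )
    out = float(logsumexp(terms))
    if not np.isfinite(out):
        raise FloatingPointError("marginal likelihood quadrature is non-finite")
    return out


@dataclass
class LayerSelection:
    """Outcome of the arc-cosine layer search."""

    l: int
    kernels: list[KernelMatrix]
    mml_trace: list[float]
    hit_l_max: bool = False


def select_layers(
    y: np.ndarray,
    M: MarkerMatrix,
    prior: PriorSpec | None = None,
    l_max: int = 25,
    design: EnvironmentDesign | None = None,
) -> LayerSelection:
    """Choose the arc-cosine layer count by maximum marginal likelihood.

    Builds AK^1 from the features, evaluates log m(y), then repeatedly
    applies the recursion: while MML(l+1) > MML(l) accept the deeper
    kernel; stop at the first non-improvement (ties select the shallower
    l) or at ``l_max``. ``design`` maps multi-observation records to
    lines; without it, rows of ``M`` align one-to-one with ``y``.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")

    def _obs_kernel(K: KernelMatrix) -> np.ndarray:
        return expand_to_observations(K, design) if design is not None else K.values

    K = arc_cosine_layer1(M)
    kernels = [K]
    trace = [marginal_likelihood(y, _obs_kernel(K), prior)]
    l = 1
    hit = False
    while l < l_max:
        K_next = arc_cosine_step(kernels[-1])
        mml_next = marginal_likelihood(y, _obs_kernel(K_next), prior)
        kernels.append(K_next)
        trace.append(mml_next)
        if mml_next <= trace[l - 1]:
            break
        l += 1
    else:
        hit = True
    return LayerSelection(l=l, kernels=kernels[:l], mml_trace=trace, hit_l_max=hit)


def default_bandwidth_grid(n: int = 10) -> np.ndarray:
    """Logarithmic bandwidth candidates spanning [0.01, 10]."""
    return np.geomspace(0.01, 10.0, n)


def select_bandwidth(
    y: np.ndarray,
    M: MarkerMatrix,
    prior: PriorSpec | None = None,
    h_grid: np.ndarray | None = None,
    design: EnvironmentDesign | None = None,
) -> float:
    """Empirical-Bayes bandwidth choice: argmax_h log m(y) over a grid."""
    h_grid = default_bandwidth_grid() if h_grid is None else np.asarray(h_grid, float)
    if h_grid.size == 0 or np.any(h_grid <= 0):
        raise ValueError("h_grid must be nonempty and positive")
    best_h, best_mml = None, -np.inf
    for h in h_grid:
        K = gaussian_kernel(M, float(h))
        Kobs = expand_to_observations(K, design) if design is not None else K.values
        mml = marginal_likelihood(y, Kobs, prior)
        if mml > best_mml:
            best_h, best_mml = float(h), mml
    return best_h


# ---------------------------------------------------------------------------
# model wrappers
# ---------------------------------------------------------------------------


def fit_single_env(
    pheno: PhenotypeTable,
    kernels: list[KernelMatrix],
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> FitResult:
    """Single-environment model: intercept + one random term per kernel.

    Supplying several kernels (e.g. genomic + pedigree + NIR) fits their
    joint model with one variance component each.
    """
    design = pheno.design()
    if design.n_envs != 1:
        raise ValueError("fit_single_env requires exactly one environment")
    terms = []
    for i, K in enumerate(kernels):
        label = K.kind if K.kind != "CUSTOM" else f"K{i + 1}"
        if any(lab == label for lab, _ in terms):
            label = f"{label}_{i + 1}"
        terms.append((label, expand_to_observations(K, design)))
    spec = ModelSpec(
        random_terms=terms,
        fixed_effects=None,
        prior=prior or PriorSpec(),
        mcmc=mcmc or McmcSettings(),
    )
    return gibbs_fit(pheno.values, spec)


def fit_ge(
    pheno: PhenotypeTable,
    G: KernelMatrix,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> FitResult:
    """Genotype-by-environment reaction-norm model.

    Fixed effects: intercept plus environment indicators (first dropped
    for identifiability, Xf = Ze). Random terms: the genomic main effect
    with kernel K1 = Zg G Zg' and the interaction effect with the
    Hadamard kernel K2 = K1 o Ze Ze'.
    """
    design = pheno.design()
    if design.n_envs < 2:
        raise ValueError("single environment: use fit_single_env instead")
    K1 = expand_to_observations(G, design)
    K2 = ge_interaction_kernel(K1, design)
    _, Ze = design.incidence_matrices()
    Xf = Ze[:, 1:]  # first environment absorbed by the intercept
    spec = ModelSpec(
        random_terms=[("main", K1), ("gxe", K2)],
        fixed_effects=Xf,
        prior=prior or PriorSpec(),
        mcmc=mcmc or McmcSettings(),
    )
    return gibbs_fit(pheno.values, spec)
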