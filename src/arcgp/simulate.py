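"""Synthetic genotype / phenotype / spectra generator.

Emulates the shape of multi-environment plant-breeding trials: biallelic
SNP dosage matrices, phenotypes simulated from the reaction-norm model
(additive and epistatic genetic effects, environment main effects,
genotype-by-environment interaction, residual noise) with known variance
components, and smooth NIR-like absorbance spectra optionally correlated
with the genetic values. Everything is deterministic under the scenario
seed, so each module of the package is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix, center_scale, linear_kernel
from .nir import SpectraMatrix
from .phenotypes import PhenotypeTable


@dataclass
class SimulationScenario:
    """Study conditions for one simulated data set.

    Variances are on the phenotypic scale: the heritability-like ratio is
    (var_additive + var_epistatic) / (sum of all variances). The implied
    between-environment genetic correlation is
    (var_additive + var_epistatic) / (var_additive + var_epistatic + var_ge).
    """

    n_lines: int = 300
    p_markers: int = 1000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_envs: int = 1
    mu: float = 10.0
    var_additive: float = 0.5
    var_epistatic: float = 0.0
    var_ge: float = 0.0
    var_residual: float = 0.5
    env_effect_sd: float = 1.0
    # population structure: None -> unrelated lines (iid binomial dosages);
    # an integer -> inbred lines built as founder-haplotype mosaics, giving
    # the family relatedness of a real breeding panel
    n_founders: int | None = None
    founder_block: int = 25
    # NIR-like spectra controls
    nir_mix: float = 0.7
    nir_dev_scale: float = 0.02
    nir_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        for name in ("var_additive", "var_epistatic", "var_ge", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_envs < 1:
            raise ValueError("n_envs must be >= 1")

    @property
    def heritability(self) -> float:
        vg = self.var_additive + self.var_epistatic
        tot = vg + self.var_ge + self.var_residual
        return vg / tot

    @property
    def env_correlation(self) -> float:
        vg = self.var_additive + self.var_epistatic
        return vg / (vg + self.var_ge) if vg + self.var_ge > 0 else 0.0


def additive_scenario(**overrides) -> SimulationScenario:
    """Purely additive architecture in a related breeding panel, h^2 = 0.5."""
    base = SimulationScenario(
        var_additive=1.0, var_epistatic=0.0, var_residual=1.0, n_founders=4
    )
    return replace(base, **overrides)


def epistatic_scenario(**overrides) -> SimulationScenario:
    """Architecture dominated by pairwise-product (epistatic) effects in a
    related breeding panel, h^2 = 0.5."""
    base = SimulationScenario(
        var_additive=0.15, var_epistatic=0.85, var_residual=1.0, n_founders=4
    )
    return replace(base, **overrides)


def ge_scenario(**overrides) -> SimulationScenario:
    """Three correlated environments with positive GxE variance
    (implied between-environment genetic correlation ~0.71)."""
    base = SimulationScenario(
        n_envs=3, var_additive=1.0, var_epistatic=0.0, var_ge=0.4,
        var_residual=1.0, n_founders=4,
    )
    return replace(base, **overrides)


def _sample_mvn(rng: np.random.Generator, K: np.ndarray) -> np.ndarray:
    """Draw one sample from N(0, K) for PSD K (eigendecomposition)."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return U @ (np.sqrt(w) * rng.standard_normal(w.size))


def simulate_markers(scenario: SimulationScenario) -> MarkerMatrix:
    """Biallelic dosage matrix in {0, 1, 2}.

    Default (``n_founders=None``): unrelated lines, dosages binomial(2, f)
    with per-marker allele frequency f drawn uniformly from the scenario
    range. With ``n_founders`` set, lines are inbred founder-haplotype
    mosaics: each line copies blocks of ``founder_block`` consecutive
    markers from randomly chosen founder haplotypes (doubled, as in a
    fully inbred line). Shared founder segments give the family-level
    relatedness of a breeding panel, which is what makes epistatic
    (marker-product) effects predictable across lines.
    """
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_lines, scenario.p_markers
    lo, hi = scenario.allele_freq_range
    freqs = rng.uniform(lo, hi, p)
    if scenario.n_founders is None:
        X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    else:
        nf, block = scenario.n_founders, scenario.founder_block
        if nf < 2 or block < 1:
            raise ValueError("need >=2 founders and block >=1")
        founders = rng.binomial(1, freqs, size=(nf, p)).astype(float)
        n_blocks = -(-p // block)
        X = np.empty((n, p))
        for i in range(n):
            choice = rng.integers(0, nf, n_blocks)
            hap = np.concatenate(
                [founders[choice[b], b * block:(b + 1) * block]
                 for b in range(n_blocks)]
            )
            X[i] = 2.0 * hap
    return MarkerMatrix(
        X,
        [f"L{i + 1:04d}" for i in range(n)],
        [f"M{j + 1}" for j in range(p)],
    )


def genetic_kernels(M: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Additive and epistatic correlation kernels from a dosage matrix.

    The additive kernel is GB = XX'/p on centered/scaled markers; the
    epistatic kernel is its Hadamard square GB o GB (the covariance of
    all pairwise-product marker effects). Both are normalized by their
    mean diagonal so simulated variances land on the phenotypic scale.
    """
    import warnings

    with warnings.catch_warnings():
        # founder panels routinely fix some markers; dropping them here
        # is expected, not a data problem worth surfacing
        warnings.simplefilter("ignore", UserWarning)
        GB = linear_kernel(center_scale(M)).values
    GBn = GB / np.mean(np.diag(GB))
    EPI = GB * GB
    EPIn = EPI / np.mean(np.diag(EPI))
    return GBn, EPIn


def pairwise_feature_matrix(M: MarkerMatrix, max_p: int = 60) -> MarkerMatrix:
    """Explicit pairwise-product features x_ik * x_im (all ordered pairs).

    The linear kernel on these p^2 features equals the Hadamard square of
    the linear kernel on the original features exactly — the small-p
    cross-check for the kernel-based epistasis construction.
    """
    X = M.values
    p = X.shape[1]
    if p > max_p:
        raise ValueError(f"explicit pairwise features are O(p^2); p={p} > {max_p}")
    Z = (X[:, :, None] * X[:, None, :]).reshape(X.shape[0], p * p)
    ids = [f"{a}x{b}" for a in M.feature_ids for b in M.feature_ids]
    return MarkerMatrix(Z, list(M.line_ids), ids, scaled=M.scaled)


def simulate_phenotypes(
    scenario: SimulationScenario, M: MarkerMatrix
) -> tuple[PhenotypeTable, dict]:
    """Phenotypes from the reaction-norm model with known components.

    y[line, env] = mu + env effect + g[line] + u2[line, env] + eps, with
    g drawn from N(0, va*K_add + vepi*K_epi) and u2 drawn independently
    per environment from N(0, v_ge * K_g), K_g being the normalized
    combined genetic kernel — the Hadamard (environment-block)
    interaction structure of the GE model. Returns the table (rows
    ordered environment-major) and a truth record with every component.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    n, m = scenario.n_lines, scenario.n_envs
    if M.n_lines != n:
        raise ValueError("marker matrix does not match scenario n_lines")
    K_add, K_epi = genetic_kernels(M)
    cov_g = scenario.var_additive * K_add + scenario.var_epistatic * K_epi
    g = _sample_mvn(rng, cov_g)

    vg = scenario.var_additive + scenario.var_epistatic
    K_g = cov_g / vg if vg > 0 else K_add
    u2 = np.zeros((n, m))
    if scenario.var_ge > 0:
        for e in range(m):
            u2[:, e] = _sample_mvn(rng, scenario.var_ge * K_g)

    env_effects = (
        rng.normal(0.0, scenario.env_effect_sd, m) if m > 1 else np.zeros(1)
    )
    eps = rng.normal(0.0, np.sqrt(scenario.var_residual), (n, m))

    rows = []
    for e in range(m):
        env = f"E{e + 1}"
        for i, lid in enumerate(M.line_ids):
            rows.append(
                {
                    "line": lid,
                    "env": env,
                    "value": scenario.mu + env_effects[e] + g[i] + u2[i, e] + eps[i, e],
                }
            )
    truth = {
        "g": g,
        "u2": u2,
        "env_effects": env_effects,
        "eps": eps,
        "heritability": scenario.heritability,
        "env_correlation": scenario.env_correlation,
        "K_add": K_add,
        "K_epi": K_epi,
    }
    return PhenotypeTable(pd.DataFrame(rows)), truth


def simulate_spectra(
    scenario: SimulationScenario,
    line_effects: np.ndarray | None = None,
    n_bumps: int = 4,
) -> SpectraMatrix:
    """Smooth NIR-like log(1/R) spectra on a 400-2500 nm grid at 20 nm.

    Each line's spectrum is a shared smooth mean curve (broad absorption
    bands around typical O-H/C-H overtone regions plus a gentle slope)
    plus a low-rank line-specific deviation (loadings on a few Gaussian
    bumps) plus small measurement noise. When ``line_effects`` is given,
    the first deviation loading mixes in the standardized effects with
    weight ``scenario.nir_mix`` so the NIR kernel carries predictive
    signal.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    wl = np.arange(400.0, 2500.0 + 1e-9, 20.0)
    n = scenario.n_lines

    def bump(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    mean_spec = (
        0.3
        + 2.5e-4 * (wl - 400.0)
        + bump(1450.0, 120.0, 0.35)
        + bump(1940.0, 100.0, 0.45)
        + bump(2100.0, 150.0, 0.25)
        + bump(700.0, 150.0, 0.15)
    )

    centers = rng.uniform(500.0, 2400.0, n_bumps)
    widths = rng.uniform(80.0, 250.0, n_bumps)
    basis = np.stack([bump(c, w, 1.0) for c, w in zip(centers, widths)])

    loadings = rng.standard_normal((n, n_bumps))
    if line_effects is not None:
        z = np.asarray(line_effects, float)
        z = (z - z.mean()) / z.std()
        mix = scenario.nir_mix
        loadings[:, 0] = mix * z + np.sqrt(max(1 - mix**2, 0.0)) * loadings[:, 0]

    spectra = (
        mean_spec[None, :]
        + scenario.nir_dev_scale * loadings @ basis
        + rng.normal(0.0, scenario.nir_noise_sd, (n, wl.size))
    )
    return SpectraMatrix(
        spectra, wl, [f"L{i + 1:04d}" for i in range(n)]
    )
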