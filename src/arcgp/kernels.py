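"""Covariance kernels for genomic prediction.

Builds the three marker-derived kernels used throughout the package —
the linear GBLUP kernel ``GB = XX'/p``, the Gaussian kernel
``GK = exp(-h d^2/q)`` and the arc-cosine kernel ``AK^l`` that emulates an
l-layer neural network — plus the observation-level main-effect and
genotype-by-environment interaction kernels of the reaction-norm model.

All kernels are carried as :class:`KernelMatrix` objects: a symmetric
positive-semidefinite line-by-line similarity with line identifiers and a
provenance tag. Marker (or NIR-derived feature) matrices are carried as
:class:`MarkerMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: relative symmetry tolerance for kernel validation
SYM_TOL = 1e-10
#: a kernel is accepted as PSD when lambda_min >= -PSD_TOL * lambda_max
PSD_TOL = 1e-8


class KernelError(ValueError):
    """Raised when a kernel cannot be constructed or fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Lines-by-features numeric matrix (SNP dosages or spectral features).

    Parameters
    ----------
    values
        ``(n_lines, p)`` real matrix with no missing entries.
    line_ids
        Unique, ordered line labels (one per row).
    feature_ids
        Ordered feature labels (one per column).
    scaled
        Whether columns have been centered/scaled (see :func:`center_scale`).
    """

    values: np.ndarray
    line_ids: list[str]
    feature_ids: list[str]
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        self.feature_ids = [str(x) for x in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("marker values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 lines")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match row count")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match column count")
        if len(set(self.line_ids)) != n:
            raise ValueError("line_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker matrix contains non-finite entries")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric PSD lines-by-lines similarity matrix.

    ``kind`` records provenance: ``GB`` (linear/GBLUP), ``GK`` (Gaussian,
    ``params['h']`` = bandwidth), ``AK`` (arc-cosine, ``params['l']`` =
    number of layers), ``PEDIGREE`` (numerator relationship matrix read from
    file) or ``CUSTOM``.
    """

    values: np.ndarray
    line_ids: list[str]
    kind: str = "CUSTOM"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise KernelError("kernel matrix must be square")
        if len(self.line_ids) != n or len(set(self.line_ids)) != n:
            raise KernelError("line_ids must be unique and match matrix order")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        """Check symmetry and positive semidefiniteness within tolerance."""
        K = self.values
        if not np.all(np.isfinite(K)):
            raise KernelError("kernel contains non-finite entries")
        scale = np.maximum(1.0, np.abs(K))
        if np.max(np.abs(K - K.T) / scale) > SYM_TOL:
            raise KernelError("kernel is not symmetric within tolerance")
        w = np.linalg.eigvalsh((K + K.T) / 2.0)
        lam_max = max(w[-1], 0.0)
        if w[0] < -PSD_TOL * max(lam_max, 1.0):
            raise KernelError(
                f"kernel is not PSD: lambda_min={w[0]:.3e}, lambda_max={lam_max:.3e}"
            )

    def index_of(self, line_ids: Sequence[str]) -> np.ndarray:
        """Row/column positions of ``line_ids`` in this kernel."""
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        missing = [lid for lid in line_ids if lid not in pos]
        if missing:
            raise KernelError(f"lines absent from kernel: {missing[:5]}")
        return np.array([pos[lid] for lid in line_ids], dtype=int)


@dataclass
class EnvironmentDesign:
    """Incidence structure mapping observations to lines and environments.

    Each observation is one (line, environment) cell; the binary incidence
    matrices Zg (observations x lines) and Ze (observations x environments)
    are realized implicitly through the two index vectors.
    """

    obs_line_index: np.ndarray
    obs_env_index: np.ndarray
    line_ids: list[str]
    env_ids: list[str]

    def __post_init__(self) -> None:
        self.obs_line_index = np.asarray(self.obs_line_index, dtype=int)
        self.obs_env_index = np.asarray(self.obs_env_index, dtype=int)
        if self.obs_line_index.shape != self.obs_env_index.shape:
            raise ValueError("line and environment index vectors must align")
        cells = set(zip(self.obs_line_index.tolist(), self.obs_env_index.tolist()))
        if len(cells) != self.n_obs:
            raise ValueError("duplicate (line, environment) cell in design")

    @property
    def n_obs(self) -> int:
        return len(self.obs_line_index)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    def incidence_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense Zg and Ze (used only for small oracles/tests)."""
        Zg = np.zeros((self.n_obs, self.n_lines))
        Zg[np.arange(self.n_obs), self.obs_line_index] = 1.0
        Ze = np.zeros((self.n_obs, self.n_envs))
        Ze[np.arange(self.n_obs), self.obs_env_index] = 1.0
        return Zg, Ze


# ---------------------------------------------------------------------------
# marker preprocessing
# ---------------------------------------------------------------------------


def center_scale(M: MarkerMatrix, center: bool = True, scale: bool = True) -> MarkerMatrix:
    """Center and/or scale marker columns to mean 0 / sample SD 1.

    Constant columns cannot be scaled; they are dropped with a warning.
    Raises if no informative feature survives.
    """
    X = M.values.copy()
    keep = np.ones(X.shape[1], dtype=bool)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(
                f"dropping {n_drop} constant column(s) before scaling", stacklevel=2
            )
            X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("no informative features")
        sd = sd[keep]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    feat = [f for f, k in zip(M.feature_ids, keep) if k]
    return MarkerMatrix(X, list(M.line_ids), feat, scaled=center or scale)


# ---------------------------------------------------------------------------
# line-level kernels
# ---------------------------------------------------------------------------


def linear_kernel(M: MarkerMatrix) -> KernelMatrix:
    """Linear GBLUP kernel ``GB = X X' / p``."""
    X = M.values
    K = X @ X.T / X.shape[1]
    K = (K + K.T) / 2.0
    return KernelMatrix(K, list(M.line_ids), kind="GB")


def squared_distance_matrix(M: MarkerMatrix) -> tuple[np.ndarray, float]:
    """Pairwise squared Euclidean distances and their off-diagonal median q."""
    X = M.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 lines for a distance median")
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    iu = np.triu_indices_from(D, k=1)
    q = float(np.median(D[iu]))
    return D, q


def gaussian_kernel(M: MarkerMatrix, h: float = 1.0) -> KernelMatrix:
    """Gaussian kernel ``GK[i,i'] = exp(-h d_ii'^2 / q)``.

    ``q`` is the median off-diagonal squared Euclidean distance, so ``h``
    acts on a scale-free distance and a pair at exactly the median distance
    has similarity ``exp(-h)``.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    D, q = squared_distance_matrix(M)
    if q <= 0:
        raise KernelError("degenerate distance matrix: median distance is zero")
    K = np.exp(-h * D / q)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return KernelMatrix(K, list(M.line_ids), kind="GK", params={"h": float(h)})


def j_theta(theta: np.ndarray) -> np.ndarray:
    """Angular factor ``J(theta) = sin(theta) + (pi - theta) cos(theta)``.

    Boundary values: J(0)=pi, J(pi/2)=1, J(pi)=0; continuous and
    nonnegative on [0, pi].
    """
    theta = np.asarray(theta, dtype=float)
    return np.sin(theta) + (np.pi - theta) * np.cos(theta)


def arc_cosine_layer1(M: MarkerMatrix) -> KernelMatrix:
    """Single-layer arc-cosine kernel.

    ``AK1[i,i'] = (1/pi) * ||x_i|| * ||x_i'|| * J(theta_ii')`` where theta
    is the angle between the two feature vectors. The cosine argument is
    clipped to [-1, 1] before arccos so that floating-point round-off on
    (near-)parallel lines cannot produce NaN. The diagonal equals the
    squared row norms.
    """
    X = M.values
    norms = np.linalg.norm(X, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        bad = [M.line_ids[i] for i in zero[:5]]
        raise KernelError(f"zero-norm feature row(s) for line(s) {bad}: angle undefined")
    G = X @ X.T
    cos = G / np.outer(norms, norms)
    np.clip(cos, -1.0, 1.0, out=cos)
    theta = np.arccos(cos)
    K = np.outer(norms, norms) * j_theta(theta) / np.pi
    np.fill_diagonal(K, norms**2)
    K = (K + K.T) / 2.0
    return KernelMatrix(K, list(M.line_ids), kind="AK", params={"l": 1})


def arc_cosine_step(K_l: KernelMatrix) -> KernelMatrix:
    """One recursion step ``AK^l -> AK^(l+1)``.

    ``AK^(l+1)[i,i'] = (1/pi) sqrt(K[i,i] K[i',i']) J(theta)`` with
    ``theta = arccos(K[i,i'] / sqrt(K[i,i] K[i',i']))``. Because J(0)=pi the
    diagonal is a fixed point of the recursion.
    """
    if K_l.kind != "AK":
        raise KernelError("arc_cosine_step requires an AK kernel")
    K = K_l.values
    d = np.diag(K).copy()
    if np.any(d <= 0):
        raise KernelError("arc-cosine recursion requires a strictly positive diagonal")
    norm = np.sqrt(np.outer(d, d))
    cos = K / norm
    np.clip(cos, -1.0, 1.0, out=cos)
    theta = np.arccos(cos)
    K_next = norm * j_theta(theta) / np.pi
    np.fill_diagonal(K_next, d)
    K_next = (K_next + K_next.T) / 2.0
    lay = int(K_l.params.get("l", 1)) + 1
    return KernelMatrix(K_next, list(K_l.line_ids), kind="AK", params={"l": lay})


def arc_cosine_kernel(M: MarkerMatrix, l: int = 1) -> KernelMatrix:
    """Arc-cosine kernel with ``l`` layers (layer 1 + l-1 recursion steps)."""
    if l < 1:
        raise ValueError("number of layers l must be >= 1")
    K = arc_cosine_layer1(M)
    for _ in range(l - 1):
        K = arc_cosine_step(K)
    return K


# ---------------------------------------------------------------------------
# observation-level kernels for the mixed models
# ---------------------------------------------------------------------------


def expand_to_observations(K: KernelMatrix, design: EnvironmentDesign) -> np.ndarray:
    """Observation-level main-effect kernel ``K1 = Zg G Zg'``.

    Realized by index gathering rather than forming the dense incidence
    matrix: ``K1[a,b] = G[line(a), line(b)]``.
    """
    idx = K.index_of([design.line_ids[i] for i in design.obs_line_index])
    return K.values[np.ix_(idx, idx)]


def ge_interaction_kernel(K1_obs: np.ndarray, design: EnvironmentDesign) -> np.ndarray:
    """Interaction kernel ``K2 = (Zg G Zg') o (Ze Ze')`` (Hadamard product).

    Entries between observations in different environments are zeroed, so
    K2 is block-diagonal after sorting by environment.
    """
    K1_obs = np.asarray(K1_obs, dtype=float)
    if K1_obs.shape != (design.n_obs, design.n_obs):
        raise ValueError("K1_obs shape does not match the design")
    same_env = design.obs_env_index[:, None] == design.obs_env_index[None, :]
    return K1_obs * same_env
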