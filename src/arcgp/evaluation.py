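"""Cross-validation machinery and prediction-accuracy comparisons.

Two random partitioning schemes are provided: RANDOM_LINES (a line is
entirely training or entirely testing, the 70/30 or 80/20 scheme used
for single-environment comparisons) and CV2 (cells masked per
environment so that every test line remains observed in at least one
other environment, the scheme under which genotype-by-environment
models borrow information across environments). Accuracy is the
within-environment Pearson correlation between observed and predicted
test records, averaged over partitions; methods are compared by paired
one-sided t-tests over partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import (
    EnvironmentDesign,
    KernelMatrix,
    MarkerMatrix,
    arc_cosine_kernel,
    gaussian_kernel,
    linear_kernel,
)
from .model import (
    FitResult,
    McmcSettings,
    PriorSpec,
    fit_ge,
    fit_single_env,
    select_bandwidth,
    select_layers,
)
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

Scheme = Literal["RANDOM_LINES", "CV2"]


@dataclass
class PartitionPlan:
    """Reproducible train/test masks over (line, environment) cells.

    ``masks`` is (n_partitions, n_obs) boolean, True marking test cells.
    """

    scheme: Scheme
    n_partitions: int
    train_fraction: float
    masks: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.shape[0] != self.n_partitions:
            raise ValueError("mask count does not match n_partitions")


def make_partitions(
    design: EnvironmentDesign,
    scheme: Scheme,
    n_partitions: int,
    train_fraction: float,
    seed: int,
    max_resample: int = 1000,
) -> PartitionPlan:
    """Draw reproducible random partitions.

    RANDOM_LINES: each partition samples round(train_fraction * n_lines)
    training lines; every observation of a test line is masked. CV2:
    each partition independently masks (1 - train_fraction) of the cells
    within each environment, redrawing any partition that would leave a
    line with no training observation in any environment.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_obs = design.n_obs
    masks = np.zeros((n_partitions, n_obs), dtype=bool)

    if scheme == "RANDOM_LINES":
        n_train = int(round(train_fraction * design.n_lines))
        n_test = design.n_lines - n_train
        if n_test < 2:
            raise ValueError("train_fraction leaves fewer than 2 test lines")
        for p in range(n_partitions):
            test_lines = rng.choice(design.n_lines, size=n_test, replace=False)
            masks[p] = np.isin(design.obs_line_index, test_lines)
    elif scheme == "CV2":
        env_obs = [np.where(design.obs_env_index == e)[0] for e in range(design.n_envs)]
        for p in range(n_partitions):
            for _ in range(max_resample):
                m = np.zeros(n_obs, dtype=bool)
                for obs_idx in env_obs:
                    n_mask = int(round((1 - train_fraction) * obs_idx.size))
                    chosen = rng.choice(obs_idx, size=n_mask, replace=False)
                    m[chosen] = True
                # every line must stay observed somewhere
                trained = set(design.obs_line_index[~m].tolist())
                if all(l in trained for l in set(design.obs_line_index.tolist())):
                    masks[p] = m
                    break
            else:
                raise RuntimeError(
                    "could not draw a CV2 mask keeping every line observed"
                )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return PartitionPlan(scheme, n_partitions, train_fraction, masks, seed)


def pearson_by_env(
    observed: np.ndarray,
    predicted: np.ndarray,
    design: EnvironmentDesign,
    test_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Within-environment Pearson correlation over test records.

    Environments with fewer than 3 test records or zero variance yield
    NaN (recorded as missing with a log warning).
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    mask = np.ones(design.n_obs, bool) if test_mask is None else np.asarray(test_mask, bool)
    out = np.full(design.n_envs, np.nan)
    for e in range(design.n_envs):
        sel = mask & (design.obs_env_index == e) & np.isfinite(observed)
        if sel.sum() < 3:
            logger.warning("environment %s: <3 test records, correlation undefined",
                           design.env_ids[e])
            continue
        o, pr = observed[sel], predicted[sel]
        if np.std(o) == 0 or np.std(pr) == 0:
            logger.warning("environment %s: zero variance, correlation undefined",
                           design.env_ids[e])
            continue
        out[e] = float(np.corrcoef(o, pr)[0, 1])
    return out


def paired_onesided_ttest(
    corrs_a: np.ndarray, corrs_b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Paired one-sided t-test of H1: mean(a - b) > 0 over partitions.

    Degenerate case (zero variance of the differences): p = 0 if the
    common difference is positive, 1 if negative, 0.5 if exactly zero.
    """
    a = np.asarray(corrs_a, float)
    b = np.asarray(corrs_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    if d.size < 2:
        raise ValueError("fewer than 2 finite pairs")
    if np.std(d, ddof=1) == 0:
        mean = float(d.mean())
        if mean > 0:
            t, p = np.inf, 0.0
        elif mean < 0:
            t, p = -np.inf, 1.0
        else:
            t, p = 0.0, 0.5
            logger.warning("identical paired samples; p set to 0.5 by convention")
    else:
        res = stats.ttest_rel(a[ok], b[ok], alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    return t, p, bool(p < alpha)


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class KernelMethod:
    """One column of a comparison table: how to build the kernel.

    ``kind`` is GB, GK, AK or PRECOMPUTED. For GK/AK the hyperparameter
    may be a number or "auto", in which case it is re-selected by
    marginal likelihood inside every training partition (no test
    leakage). ``markers`` supplies the feature matrix (already
    centered/scaled as desired); PRECOMPUTED uses ``kernel`` directly
    (pedigree or NIR similarity matrices).
    """

    name: str
    kind: str
    markers: MarkerMatrix | None = None
    kernel: KernelMatrix | None = None
    layers: int | str = "auto"
    bandwidth: float | str = "auto"
    l_max: int = 25

    def __post_init__(self) -> None:
        if self.kind in {"GB", "GK", "AK"} and self.markers is None:
            raise ValueError(f"method {self.name!r}: marker matrix required")
        if self.kind == "PRECOMPUTED" and self.kernel is None:
            raise ValueError(f"method {self.name!r}: kernel required")

    def build(self, y_train: np.ndarray, train_design: EnvironmentDesign,
              prior: PriorSpec) -> tuple[KernelMatrix, dict]:
        """Kernel over all lines; hyperparameters chosen on training data only.

        ``train_design`` maps the (complete) training records in
        ``y_train`` to lines, so selection works both for one record per
        line and for pooled multi-environment training data.
        """
        if self.kind == "PRECOMPUTED":
            return self.kernel, {}
        if self.kind == "GB":
            return linear_kernel(self.markers), {}
        pos = {lid: i for i, lid in enumerate(self.markers.line_ids)}
        rows = [pos[lid] for lid in train_design.line_ids]
        M_train = MarkerMatrix(
            self.markers.values[rows],
            list(train_design.line_ids),
            list(self.markers.feature_ids),
            scaled=self.markers.scaled,
        )
        if self.kind == "GK":
            h = self.bandwidth
            if h == "auto":
                h = select_bandwidth(y_train, M_train, prior, design=train_design)
            return gaussian_kernel(self.markers, float(h)), {"h": float(h)}
        if self.kind == "AK":
            l = self.layers
            if l == "auto":
                l = select_layers(
                    y_train, M_train, prior, l_max=self.l_max, design=train_design
                ).l
            return arc_cosine_kernel(self.markers, int(l)), {"l": int(l)}
        raise ValueError(f"unknown method kind {self.kind!r}")


@dataclass
class CVResult:
    """Per-partition, per-environment correlations for each method."""

    methods: list[str]
    env_ids: list[str]
    corr: np.ndarray  # (n_methods, n_partitions, n_envs)
    selected: list[list[dict]]  # per method, per partition hyperparameters
    n_skipped: int = 0
    alpha: float = 0.05
    plan: PartitionPlan | None = None

    def mean_sd(self) -> pd.DataFrame:
        """Mean and SD of the correlations over partitions."""
        rows = []
        for mi, m in enumerate(self.methods):
            for ei, e in enumerate(self.env_ids):
                c = self.corr[mi, :, ei]
                c = c[np.isfinite(c)]
                rows.append({
                    "method": m, "env": e,
                    "mean": float(np.mean(c)) if c.size else np.nan,
                    "sd": float(np.std(c, ddof=1)) if c.size > 1 else np.nan,
                    "n_partitions": int(c.size),
                })
        return pd.DataFrame(rows)

    def compare(self, method_a: str, method_b: str, env: str | None = None
                ) -> tuple[float, float, bool]:
        """Paired test that method_a beats method_b (per env or averaged)."""
        ia, ib = self.methods.index(method_a), self.methods.index(method_b)
        if env is None:
            a = np.nanmean(self.corr[ia], axis=1)
            b = np.nanmean(self.corr[ib], axis=1)
        else:
            ei = self.env_ids.index(env)
            a, b = self.corr[ia, :, ei], self.corr[ib, :, ei]
        return paired_onesided_ttest(a, b, self.alpha)

    def summary_table(self, baseline: str | None = None) -> pd.DataFrame:
        """Report table: environments as rows, methods as columns,
        cells "mean (sd)"; methods significantly above the baseline
        (default: first method) are flagged with '+'."""
        base = baseline or self.methods[0]
        ms = self.mean_sd().set_index(["method", "env"])
        tab = {}
        for m in self.methods:
            col = []
            for e in self.env_ids:
                mean = ms.loc[(m, e), "mean"]
                sd = ms.loc[(m, e), "sd"]
                flag = ""
                if m != base:
                    _, _, sig = self.compare(m, base, env=e)
                    flag = "+" if sig else ""
                col.append(f"{mean:.3f} ({sd:.3f}){flag}")
            tab[m] = col
        return pd.DataFrame(tab, index=pd.Index(self.env_ids, name="env"))


def run_cv(
    pheno: PhenotypeTable,
    methods: list[KernelMethod],
    model: Literal["single_env", "ge"],
    plan: PartitionPlan,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
) -> CVResult:
    """Run the full cross-validation comparison.

    For every partition and method: mask the test cells, re-select any
    "auto" hyperparameters on the training records only, fit the chosen
    model, predict the masked cells and score the within-environment
    Pearson correlations. Partition-level failures are logged and
    skipped (counted in ``n_skipped``).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    design = pheno.design()
    y_full = pheno.values
    n_methods = len(methods)
    corr = np.full((n_methods, plan.n_partitions, design.n_envs), np.nan)
    selected: list[list[dict]] = [[] for _ in methods]
    n_skipped = 0

    for p in range(plan.n_partitions):
        test = plan.masks[p]
        y_masked = y_full.copy()
        y_masked[test] = np.nan
        train_obs = ~test & np.isfinite(y_full)
        # training records for hyperparameter selection, centered per
        # environment (environment means are fixed effects in the model
        # but the selection likelihood carries a single intercept)
        sub = pheno.records.loc[train_obs].reset_index(drop=True)
        y_train = y_full[train_obs].copy()
        for env in pheno.env_ids:
            e_sel = (sub["env"] == env).to_numpy()
            if e_sel.any():
                y_train[e_sel] -= y_train[e_sel].mean()
        train_design = PhenotypeTable(sub).design()
        try:
            for mi, method in enumerate(methods):
                K, hyper = method.build(y_train, train_design, prior)
                mseed = mcmc.seed + 1000 * p + mi
                mc = McmcSettings(mcmc.n_iter, mcmc.burn_in, mcmc.thin, mseed)
                ph = pheno.with_values(y_masked)
                if model == "single_env":
                    pred = np.full(design.n_obs, np.nan)
                    for e, env in enumerate(design.env_ids):
                        sel = design.obs_env_index == e
                        env_records = ph.records.loc[sel]
                        fit = fit_single_env(
                            PhenotypeTable(env_records), [K], prior=prior, mcmc=mc
                        )
                        pred[np.where(sel)[0]] = fit.predicted
                elif model == "ge":
                    fit = fit_ge(ph, K, prior=prior, mcmc=mc)
                    pred = fit.predicted
                else:
                    raise ValueError(f"unknown model {model!r}")
                corr[mi, p] = pearson_by_env(y_full, pred, design, test_mask=test)
                selected[mi].append(hyper)
        except Exception:
            logger.exception("partition %d failed; skipping", p)
            n_skipped += 1
            corr[:, p] = np.nan

    if n_skipped:
        logger.warning("%d of %d partitions skipped", n_skipped, plan.n_partitions)
    return CVResult(
        methods=[m.name for m in methods],
        env_ids=design.env_ids,
        corr=corr,
        selected=selected,
        n_skipped=n_skipped,
        plan=plan,
    )
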