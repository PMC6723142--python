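"""Delimited-text readers and writers.

All matrices travel as comma- or tab-delimited text: first row holds
feature/line/wavelength identifiers, first column holds line
identifiers. Kernel files carry a two-line ``#`` header recording kind
and parameters (bandwidth h or layer count l) so a kernel re-read from
disk keeps its provenance.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import EnvironmentDesign, KernelMatrix, MarkerMatrix
from .model import FitResult
from .nir import SpectraMatrix
from .phenotypes import PhenotypeTable


def _read_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate line id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return df


def _kernel_header(path: str | Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*kind:\s*(\S+)", line)
            if m:
                meta["kind"] = m.group(1)
            m = re.match(r"#\s*params:\s*(.*)", line)
            if m:
                params = {}
                for item in re.split(r"[;,]\s*", m.group(1).strip()):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        try:
                            params[k.strip()] = int(v)
                        except ValueError:
                            params[k.strip()] = float(v)
                meta["params"] = params
    return meta


def read_matrix(path: str | Path, kind: str = "markers"):
    """Read a delimited matrix as markers, kernel or spectra.

    Kernel files are additionally validated for symmetry and positive
    semidefiniteness; spectra files must have numeric (nm) column
    headers on an even grid.
    """
    df = _read_frame(path)
    line_ids = [str(x) for x in df.index]
    if kind == "markers":
        return MarkerMatrix(df.to_numpy(), line_ids, [str(c) for c in df.columns])
    if kind == "kernel":
        if list(map(str, df.columns)) != line_ids:
            raise ValueError(f"{path}: kernel row/column ids differ")
        meta = _kernel_header(path)
        K = KernelMatrix(
            df.to_numpy(), line_ids,
            kind=meta.get("kind", "CUSTOM"), params=meta.get("params", {}),
        )
        K.validate()
        return K
    if kind == "spectra":
        try:
            wl = np.array([float(c) for c in df.columns])
        except ValueError as exc:
            raise ValueError(f"{path}: spectra headers must be wavelengths") from exc
        return SpectraMatrix(df.to_numpy(), wl, line_ids)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path: str | Path, delimiter: str = ",") -> None:
    """Write a marker/kernel/spectra matrix; kernels get a provenance header."""
    path = Path(path)
    if isinstance(obj, MarkerMatrix):
        df = pd.DataFrame(obj.values, index=obj.line_ids, columns=obj.feature_ids)
        df.to_csv(path, sep=delimiter)
    elif isinstance(obj, KernelMatrix):
        df = pd.DataFrame(obj.values, index=obj.line_ids, columns=obj.line_ids)
        with open(path, "w") as fh:
            fh.write(f"# kind: {obj.kind}\n")
            params = "; ".join(f"{k}={v}" for k, v in obj.params.items())
            fh.write(f"# params: {params}\n")
            df.to_csv(fh, sep=delimiter)
    elif isinstance(obj, SpectraMatrix):
        df = pd.DataFrame(
            obj.values, index=obj.line_ids, columns=[f"{w:g}" for w in obj.wavelengths]
        )
        df.to_csv(path, sep=delimiter)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_phenotypes(path: str | Path) -> tuple[PhenotypeTable, EnvironmentDesign]:
    """Long-format phenotypes (line, env, value); NaN marks records to predict."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("line", "env", "value"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    df = df.rename(columns={cols["line"]: "line", cols["env"]: "env",
                            cols["value"]: "value"})
    pheno = PhenotypeTable(df)
    return pheno, pheno.design()


def write_phenotypes(pheno: PhenotypeTable, path: str | Path,
                     delimiter: str = ",") -> None:
    pheno.records.to_csv(path, sep=delimiter, index=False)


def write_fit_result(fit: FitResult, pheno: PhenotypeTable, outdir: str | Path,
                     prefix: str = "fit") -> None:
    """Posterior summary and predictions tables for one fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"parameter": "mu", "posterior_mean": fit.mu_mean, "posterior_sd": fit.mu_sd}]
    for i, (bm, bs) in enumerate(zip(fit.beta_mean, fit.beta_sd)):
        rows.append({"parameter": f"beta_{i + 1}", "posterior_mean": bm,
                     "posterior_sd": bs})
    for lab in fit.var_samples:
        rows.append({
            "parameter": f"sigma2_{lab}",
            "posterior_mean": fit.var_mean[lab],
            "posterior_sd": fit.var_sd[lab],
        })
    pd.DataFrame(rows).to_csv(outdir / f"{prefix}_summary.csv", index=False)
    pred = pheno.records.copy()
    pred = pred.rename(columns={"value": "observed"})
    pred["predicted"] = fit.predicted
    pred.to_csv(outdir / f"{prefix}_predictions.csv", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Reproducibility record (config echo, seeds, selections, version)."""
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
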