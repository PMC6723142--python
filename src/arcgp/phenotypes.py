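"""Long-format phenotype records and their incidence design."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import EnvironmentDesign


@dataclass
class PhenotypeTable:
    """Long-format phenotype records (line, env, value).

    ``value`` may be NaN for records to be predicted. Each (line, env)
    cell appears at most once; observation order is the row order of
    ``records`` and defines the y vector of the mixed models.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"line", "env", "value"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"phenotype table needs columns {sorted(req)}")
        df = self.records[["line", "env", "value"]].copy()
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if df.duplicated(subset=["line", "env"]).any():
            dup = df[df.duplicated(subset=["line", "env"])].iloc[0]
            raise ValueError(f"duplicated (line, env) cell: ({dup['line']}, {dup['env']})")
        self.records = df.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return len(self.records)

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["line"]))

    @property
    def env_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["env"]))

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def design(self) -> EnvironmentDesign:
        lines = self.line_ids
        envs = self.env_ids
        lpos = {x: i for i, x in enumerate(lines)}
        epos = {x: i for i, x in enumerate(envs)}
        return EnvironmentDesign(
            obs_line_index=np.array([lpos[x] for x in self.records["line"]]),
            obs_env_index=np.array([epos[x] for x in self.records["env"]]),
            line_ids=lines,
            env_ids=envs,
        )

    def restrict_env(self, env: str) -> "PhenotypeTable":
        sub = self.records[self.records["env"] == str(env)]
        if sub.empty:
            raise ValueError(f"no records for environment {env!r}")
        return PhenotypeTable(sub.reset_index(drop=True))

    def with_values(self, values: np.ndarray) -> "PhenotypeTable":
        df = self.records.copy()
        df["value"] = np.asarray(values, dtype=float)
        return PhenotypeTable(df)
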