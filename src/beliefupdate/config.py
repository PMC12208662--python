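"""Run configuration and artifact I/O.

A :class:`RunConfig` captures everything a pipeline run needs (cohort
configuration, priors, model subset, BMS/recovery/power settings, seed,
output directory) and round-trips through YAML.  Artifact CSVs carry a
header comment declaring the seed and a hash of the configuration, so a
results directory is self-describing; :func:`read_artifact` skips those
comments transparently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .fitting import PriorSpec
from .synthetic import CohortConfig, GroupCovariates


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    models: list = field(default_factory=lambda: list(range(1, 13)))
    seed: int = 0
    outdir: str = "results"
    # model selection
    bms_alpha0: float = 1.0
    bms_mc_samples: int = 100_000
    # recovery
    recovery_n_subjects: int = 123
    recovery_n_trials: int = 40
    model_recovery_n_subjects: int = 40
    # power analysis
    power_iterations: int = 1000
    power_alpha: float = 0.05
    power_re_structure: str = "full"

    def with_seed(self, seed: int) -> "RunConfig":
        cohort = dataclasses.replace(self.cohort, seed=seed)
        return dataclasses.replace(self, seed=seed, cohort=cohort)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["covariates"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
            for k, v in self.cohort.covariates.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        cohort = dict(d.pop("cohort", {}))
        if "covariates" in cohort:
            cohort["covariates"] = {
                k: GroupCovariates(**v) for k, v in cohort["covariates"].items()}
        for key in ("param_mean", "param_sd", "context_param_shift"):
            if key in cohort and cohort[key] is not None:
                cohort[key] = tuple(cohort[key])
        prior = d.pop("prior", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig(**cohort), prior=PriorSpec(**prior), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Digest of the scientific configuration (the output path is
        excluded, so moving a run does not change its identity)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        return hashlib.sha1(json.dumps(payload, sort_keys=True,
                                       default=str).encode()).hexdigest()[:10]


def write_artifact(df: pd.DataFrame, path, seed: int, config_hash: str,
                   index: bool = False) -> None:
    """Write a CSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=index)


def read_artifact(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_json(obj: dict, path, seed: int, config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"seed": seed, "config": config_hash, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
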