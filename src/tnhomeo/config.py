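"""Run configuration: YAML-backed, strictly validated (unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    counts_total: Optional[str] = None
    counts_unique: Optional[str] = None
    design: Optional[str] = None
    annotation: Optional[str] = None
    outdir: str = "tnhomeo_out"


class SimulateConfig(_Strict):
    L: int = 500
    K_true: int = 2
    strains: list[str] = Field(default_factory=lambda: ["wt"])
    stresses: list[str] = Field(
        default_factory=lambda: ["heat", "oxidative", "canavanine"])
    levels: list[str] = Field(default_factory=lambda: ["low", "medium", "high"])
    n_reps: int = 4
    n_batches: int = 2
    fractions: dict = Field(default_factory=lambda: {
        "essential": 0.05, "cond_essential": 0.05,
        "cond_beneficial": 0.03, "cond_detrimental": 0.03})
    baseline_mu: float = 80.0
    essential_mu: float = 1.0
    dispersion_range: list[float] = Field(default_factory=lambda: [0.5, 5.0])
    p_unique: float = 0.6
    batch_sigma: float = 0.15
    stress_cluster_map: Optional[dict] = None


class McmcConfig(_Strict):
    iters: int = 2000
    burnin: int = 1000
    thin: int = 5


class StagesConfig(_Strict):
    batch_adjust: bool = True
    classify: bool = True
    fitness: bool = True
    glm: bool = True
    emd: bool = True
    knockoff: bool = True
    gpmodel: bool = True


class SeedsConfig(_Strict):
    simulate: int = 1
    knockoff: int = 1
    gpmodel: int = 1


class RunConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    simulate: Optional[SimulateConfig] = None
    stages: StagesConfig = Field(default_factory=StagesConfig)
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    tau_ess: float = 3.0
    rho_fc: float = 4.0
    lfdr_cut: float = 0.2
    q: float = 0.1
    K: int = 20
    eps0: float = 0.1
    a: float = 0.1
    drop_all_zero: bool = True
    glm_n_lambda: int = 8

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Load YAML config and apply ``key.sub=value`` overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    for ov in overrides or []:
        key, _, val = ov.partition("=")
        node = raw
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(val)
    return RunConfig(**raw)
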