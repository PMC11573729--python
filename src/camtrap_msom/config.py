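"""Run configuration: YAML parsing, defaults, validation, and the
end-to-end pipeline orchestration (ingest -> covariates -> fit ->
summarize) with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import build_design_matrix, disturbance_count
from .ingest import (build_detection_history, filter_independent,
                     naive_estimates, read_camera_records, read_deployments,
                     aggregate_taxa)
from .msom import MCMCConfig, augment, derive_richness, run_mcmc
from .postprocess import (accumulation_curve, plot_accumulation,
                          richness_regression, site_richness)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_INGEST_DEFAULTS = {"window_minutes": 60.0, "occasion_days": 1,
                    "taxon_map": None}
_COV_DEFAULTS = {"radius": 100.0, "columns": None, "table": None}
_MCMC_DEFAULTS = {"n_chains": 3, "n_iter": 100_000, "burn_in": 5_000,
                  "thin": 60, "n_aug": None}
_TOP_KEYS = {"records", "deployments", "covariates", "ingest", "mcmc",
             "out", "seed"}


@dataclass
class RunConfig:
    """Validated pipeline configuration with all defaults filled."""

    records: str
    deployments: str
    out: str
    seed: int = 0
    ingest: dict = field(default_factory=lambda: dict(_INGEST_DEFAULTS))
    covariates: dict = field(default_factory=lambda: dict(_COV_DEFAULTS))
    mcmc: dict = field(default_factory=lambda: dict(_MCMC_DEFAULTS))


def _merge(defaults: dict, given: dict, section: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


def validate_config(source) -> RunConfig:
    """Parse and validate a config (path to YAML, or a dict).

    Unknown keys are rejected by name; MCMC settings must satisfy
    burn_in < n_iter and thin >= 1.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for req in ("records", "deployments", "out"):
        if req not in raw:
            raise ValueError(f"config is missing required key '{req}'")
    cfg = RunConfig(
        records=str(raw["records"]),
        deployments=str(raw["deployments"]),
        out=str(raw["out"]),
        seed=int(raw.get("seed", 0)),
        ingest=_merge(_INGEST_DEFAULTS, raw.get("ingest") or {}, "ingest"),
        covariates=_merge(_COV_DEFAULTS, raw.get("covariates") or {},
                          "covariates"),
        mcmc=_merge(_MCMC_DEFAULTS, raw.get("mcmc") or {}, "mcmc"),
    )
    if cfg.ingest["window_minutes"] < 0:
        raise ValueError("window_minutes must be non-negative")
    if cfg.ingest["occasion_days"] < 1:
        raise ValueError("occasion_days must be >= 1")
    m = cfg.mcmc
    if m["burn_in"] >= m["n_iter"]:
        raise ValueError("burn_in must be smaller than n_iter")
    if m["thin"] < 1:
        raise ValueError("thin must be >= 1")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return the artifact manifest."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    records = read_camera_records(cfg.records)
    deployments = read_deployments(cfg.deployments)
    if cfg.ingest["taxon_map"]:
        with open(cfg.ingest["taxon_map"]) as fh:
            records = aggregate_taxa(records, yaml.safe_load(fh) or {})
    independent = filter_independent(records, cfg.ingest["window_minutes"])
    history = build_detection_history(independent, deployments,
                                      cfg.ingest["occasion_days"])
    history.to_csv(out / "detection_history.csv", out / "effort.csv")
    naive_estimates(history).to_csv(out / "naive_estimates.csv", index=False)

    design = None
    if cfg.covariates["table"]:
        cov = pd.read_csv(cfg.covariates["table"], dtype={"site": str})
        cov = cov.set_index("site").loc[[str(s) for s in history.sites]]
        cov = cov.reset_index()
        if "disturbance" not in cov.columns:
            cov["disturbance"] = disturbance_count(
                independent, history.sites).to_numpy()
        design = build_design_matrix(cov)
        design.to_frame().to_csv(out / "design_matrix.csv")

    m = cfg.mcmc
    mcfg = MCMCConfig(n_chains=m["n_chains"], n_iter=m["n_iter"],
                      burn_in=m["burn_in"], thin=m["thin"], seed=cfg.seed)
    data = augment(history, design=design, n_aug=m["n_aug"],
                   columns=cfg.covariates["columns"])
    samples = run_mcmc(data, mcfg)
    samples.summary().to_csv(out / "posterior_summary.csv")
    samples.species_summary().to_csv(out / "species_summary.csv", index=False)
    samples.save(out / "draws.npz")
    _write_long_csv(samples, out / "draws_scalar.csv")

    richness = derive_richness(samples)
    sr = site_richness(samples)
    sr_frame = sr.to_frame()
    sr_frame["site"] = history.sites
    sr_frame.to_csv(out / "site_richness.csv", index=False)
    if design is not None:
        reg = richness_regression(sr.mean, design)
        reg.to_csv(out / "richness_regression.csv", index=False)
    curve = accumulation_curve(independent,
                               start=deployments["start"].min())
    curve.to_csv(out / "accumulation_curve.csv", index=False)
    plot_accumulation(curve, n_mean=richness["mean"], n_sd=richness["sd"],
                      path=out / "accumulation_curve.png")

    manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in
                   [cfg.records, cfg.deployments]
                   + ([cfg.covariates["table"]]
                      if cfg.covariates["table"] else [])},
        "config": asdict(cfg),
        "outputs": sorted({p.name for p in out.iterdir() if p.is_file()}
                          | {"manifest.json"}),
        "richness": {k: float(v) for k, v in richness.items()},
        "accept_rates": samples.accept_rates,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_long_csv(samples, path) -> None:
    """Scalar traces in long (chain, draw, parameter, value) layout."""
    rows = []
    C, D = samples.draws["N"].shape
    scalars = {"omega": samples.draws["omega"],
               "N": samples.draws["N"],
               "mu_p": samples.draws["mu_p"],
               "sigma_p": samples.draws["sigma_p"]}
    for j in range(samples.draws["mu"].shape[-1]):
        scalars[f"mu[{j}]"] = samples.draws["mu"][:, :, j]
        scalars[f"sigma[{j}]"] = samples.draws["sigma"][:, :, j]
    for name, arr in scalars.items():
        for c in range(C):
            rows.append(pd.DataFrame({
                "chain": c, "draw": np.arange(D), "parameter": name,
                "value": arr[c]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
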