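"""Run configuration: schema-validated YAML/JSON config files.

A run config ties together a network file, one or more dataset files, the
parameter-space block (bounds, priors, optional module groups), constraint
block, sampler block and reduction block.  Unknown keys are rejected with a
close-match suggestion; every run writes the fully resolved config (defaults
filled in) next to its outputs so results are regenerable.

Example (YAML)::

    network: k3_network.yaml
    datasets: [k3_data.tsv]
    parameter_space:
      bounds: [-12, 3]
      prior: {type: laplace, mu: -10, b: 1}
    sampler:
      n_chains: 6
      n_mcmc: 25
      n_swaps: 1000
      burn_in_swaps: 200
    reduction:
      c: 3.0
      mass_threshold: 0.95
    output: out/
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .energy import (
    ConstraintSet,
    EnergyModel,
    Experiment,
    GroupedEnergyModel,
    GroupedSpec,
    HardConstraint,
    LaplacePrior,
    LikelihoodSpec,
    ParameterSpace,
    SoftConstraint,
    UniformPrior,
)
from .errors import ConfigError
from .networks import ReactionNetwork, StimulusSegment, load_network
from .sampler import PTSettings
from .synthetic import ObservedDataset

__all__ = ["RunConfig", "load_config", "build_problem"]


_SCHEMA = {
    "network": None,
    "datasets": None,
    "parameter_space": {
        "bounds": None,
        "per_param_bounds": None,
        "prior": {"type": None, "mu": None, "b": None},
        "grouped": {"mu": None, "b": None, "lb": None, "ub": None, "lambda_bounds": None},
    },
    "constraints": {"hard": None, "soft": None},
    "sampler": {
        "n_chains": None,
        "betas": None,
        "beta_min": None,
        "n_mcmc": None,
        "n_swaps": None,
        "burn_in_swaps": None,
        "adapt": None,
        "target_acceptance": None,
        "adapt_eta": None,
        "initial_scale": None,
        "init_mode": None,
        "init_threshold": None,
        "warm_start": None,
        "seed": None,
    },
    "reduction": {
        "c": None,
        "mass_threshold": None,
        "active_threshold": None,
        "b_grid": None,
        "psrf_threshold": None,
    },
    "sd_floor": None,
    "output": None,
}

_DEFAULTS = {
    "datasets": [],
    "parameter_space": {
        "bounds": [-12.0, 3.0],
        "per_param_bounds": {},
        "prior": {"type": "laplace", "mu": -10.0, "b": 1.0},
        "grouped": {"mu": -25.0, "b": 2.0, "lb": -5.0, "ub": 10.0, "lambda_bounds": [-30.0, 6.0]},
    },
    "constraints": {"hard": [], "soft": []},
    "sampler": {
        "n_chains": 6,
        "betas": None,
        "beta_min": 0.05,
        "n_mcmc": 25,
        "n_swaps": 500,
        "burn_in_swaps": 100,
        "adapt": True,
        "target_acceptance": 0.234,
        "adapt_eta": 0.5,
        "initial_scale": 0.5,
        "init_mode": "prior-threshold",
        "init_threshold": None,
        "warm_start": None,
        "seed": 0,
    },
    "reduction": {
        "c": 3.0,
        "mass_threshold": 0.95,
        "active_threshold": -5.0,
        "b_grid": [0.1, 0.25, 0.5, 1.0, 2.0],
        "psrf_threshold": 1.2,
    },
    "sd_floor": 1e-6,
    "output": None,
}


def _check_keys(data: dict, schema: dict, path: str = ""):
    for key, value in data.items():
        if key not in schema:
            suggestion = difflib.get_close_matches(key, schema.keys(), n=1)
            hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
            where = f" in section {path!r}" if path else ""
            raise ConfigError(f"unknown config key {key!r}{where}{hint}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {path + key!r} must be a mapping")
            _check_keys(value, sub, path + key + ".")


def _merge(defaults, data):
    if not isinstance(defaults, dict):
        return defaults if data is None else data
    out = {}
    data = data or {}
    for key, dval in defaults.items():
        out[key] = _merge(dval, data.get(key))
    for key in data:
        if key not in out:
            out[key] = data[key]
    return out


@dataclass
class RunConfig:
    network: str | None
    datasets: list
    parameter_space: dict
    constraints: dict
    sampler: dict
    reduction: dict
    sd_floor: float
    output: str | None
    source: str | None = None
    raw: dict = field(default_factory=dict)

    def resolved_dict(self) -> dict:
        return {
            "network": self.network,
            "datasets": list(self.datasets),
            "parameter_space": self.parameter_space,
            "constraints": self.constraints,
            "sampler": self.sampler,
            "reduction": self.reduction,
            "sd_floor": self.sd_floor,
            "output": self.output,
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved_dict(), fh, sort_keys=True)

    def require_datasets(self):
        if not self.datasets:
            raise ConfigError("this command requires at least one dataset path under 'datasets'")

    def require_network(self):
        if not self.network:
            raise ConfigError("this command requires a 'network' path")


def load_config(path) -> RunConfig:
    """Load, validate and default-fill a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, _SCHEMA)
    merged = _merge(_DEFAULTS, data)
    merged["network"] = data.get("network")
    return RunConfig(
        network=merged["network"],
        datasets=list(merged["datasets"] or []),
        parameter_space=merged["parameter_space"],
        constraints=merged["constraints"],
        sampler=merged["sampler"],
        reduction=merged["reduction"],
        sd_floor=float(merged["sd_floor"]),
        output=merged["output"],
        source=str(path),
        raw=data,
    )


# ---------------------------------------------------------------------------
# turning a config into a fittable problem
# ---------------------------------------------------------------------------

def _experiment_from_dataset(ds: ObservedDataset, sd_floor: float) -> Experiment:
    inputs = []
    for d in ds.provenance.get("inputs") or []:
        inputs.append(StimulusSegment(d["name"], d["value"], d["start"], d["end"]))
    return Experiment(
        LikelihoodSpec.from_dataset(ds, sd_floor=sd_floor),
        inputs=inputs,
        name=str(ds.provenance.get("experiment", "")),
    )


def _constraints_from_config(block: dict) -> ConstraintSet:
    hard = [HardConstraint(expr) for expr in block.get("hard", [])]
    soft = [
        SoftConstraint(
            species=d["species"],
            target=float(d["target"]),
            weight=float(d["weight"]),
            time=d.get("time"),
            experiment=int(d.get("experiment", 0)),
        )
        for d in block.get("soft", [])
    ]
    return ConstraintSet(hard=hard, soft=soft)


def build_problem(config: RunConfig, mode: str = "ptlasso", base_dir=None):
    """Construct (network, model, space, settings, datasets) from a config.

    ``mode``: ``pt`` (uniform priors), ``ptlasso`` (Laplace priors on every
    rate parameter) or ``grouped`` (module-level Lasso; the network file
    must carry a module partition).
    """
    config.require_network()
    config.require_datasets()
    base = Path(base_dir) if base_dir else (Path(config.source).parent if config.source else Path("."))

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    network = load_network(resolve(config.network))
    datasets = [ObservedDataset.read_tsv(resolve(p)) for p in config.datasets]
    experiments = [_experiment_from_dataset(ds, config.sd_floor) for ds in datasets]
    constraints = _constraints_from_config(config.constraints)

    ps = config.parameter_space
    lo, hi = (float(v) for v in ps["bounds"])
    names = network.param_names
    lower = np.full(len(names), lo)
    upper = np.full(len(names), hi)
    for pname, bnds in (ps.get("per_param_bounds") or {}).items():
        if pname not in names:
            raise ConfigError(f"per_param_bounds references unknown parameter {pname!r}")
        lower[names.index(pname)], upper[names.index(pname)] = map(float, bnds)

    if mode == "grouped":
        if not network.modules:
            raise ConfigError("grouped mode requires a module partition in the network file")
        g = ps["grouped"]
        spec = GroupedSpec(
            modules=network.modules,
            mu=float(g["mu"]),
            b=float(g["b"]),
            lb=float(g["lb"]),
            ub=float(g["ub"]),
            lambda_bounds=tuple(float(v) for v in g["lambda_bounds"]),
        )
        model = GroupedEnergyModel(network, spec, experiments, constraints=constraints)
        space = model.space
    else:
        prior_block = ps["prior"]
        if mode == "pt" or prior_block.get("type", "laplace") == "uniform":
            priors = [UniformPrior()] * len(names)
        elif prior_block.get("type") == "laplace":
            priors = [LaplacePrior(float(prior_block["mu"]), float(prior_block["b"]))] * len(names)
        else:
            raise ConfigError(f"unknown prior type {prior_block.get('type')!r}")
        space = ParameterSpace(names, lower, upper, priors=priors)
        model = EnergyModel(network, space, experiments, constraints=constraints)

    sb = config.sampler
    settings = PTSettings(
        n_chains=int(sb["n_chains"]),
        betas=None if sb["betas"] is None else np.asarray(sb["betas"], dtype=float),
        beta_min=float(sb["beta_min"]),
        n_mcmc=int(sb["n_mcmc"]),
        n_swaps=int(sb["n_swaps"]),
        burn_in_swaps=int(sb["burn_in_swaps"]),
        adapt=bool(sb["adapt"]),
        target_acceptance=float(sb["target_acceptance"]),
        adapt_eta=float(sb["adapt_eta"]),
        initial_scale=float(sb["initial_scale"]),
    )
    return network, model, space, settings, datasets


def config_hash(config: RunConfig) -> str:
    import hashlib

    blob = json.dumps(config.resolved_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
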