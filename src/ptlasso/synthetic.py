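"""Synthetic observed-data generation.

Two noise models are emulated, both fully seeded:

* *noise on trajectories*: the network is simulated at the true parameters
  on a fine grid ("true data"); at a coarser set of observation points,
  replicates are produced by adding zero-mean Gaussian noise whose standard
  deviation is a fraction of the true value (10% or 30% in the studies
  here; a flag switches to the variance reading).  The replicate mean and
  standard deviation form the observed data.
* *noise on parameters*: the log10 true parameters are perturbed per
  replicate (sd 0.05 by default), each perturbed set is simulated, and the
  pointwise mean/sd of the model outputs form the observed data -- a
  cruder emulation of cell-to-cell variability.

Negative noisy replicates are kept as-is (the noise is additive); only the
likelihood's sigma flooring deals with degenerate standard deviations.
Every dataset carries provenance sufficient to regenerate it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationFailure, SpecificationError
from .networks import ReactionNetwork, StimulusSegment
from .simulate import simulate

__all__ = [
    "ObservedDataset",
    "generate_observed",
    "generate_param_noise_observed",
    "dose_response_protocol",
    "linear_dose_protocol",
    "adapting_dose_protocol",
]


@dataclass
class ObservedDataset:
    """Tidy records of (species, time, mean, sd) plus provenance."""

    species: list
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.species) == len(self.times) == len(self.means) == len(self.sds)):
            raise SpecificationError("dataset columns must have equal length")
        if np.any(self.sds < 0):
            raise SpecificationError("sd must be >= 0")

    def __len__(self):
        return len(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "time": self.times,
                "mean": self.means,
                "sd": self.sds,
            }
        )

    def write_tsv(self, path) -> None:
        """TSV records plus a JSON provenance sidecar ``<path>.prov.json``."""
        path = str(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        with open(path + ".prov.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)

    @classmethod
    def read_tsv(cls, path) -> "ObservedDataset":
        path = str(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        try:
            with open(path + ".prov.json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(
            species=list(df["species"]),
            times=df["time"].to_numpy(),
            means=df["mean"].to_numpy(),
            sds=df["sd"].to_numpy(),
            provenance=prov,
        )


def _check_obs_times(obs_times, fine_grid):
    obs_times = np.asarray(obs_times, dtype=float)
    fine_grid = np.asarray(fine_grid, dtype=float)
    for t in obs_times:
        if not np.any(np.isclose(fine_grid, t, rtol=1e-9, atol=1e-9)):
            raise SpecificationError(f"observation time {t} not on the fine grid")
    return obs_times, fine_grid


def generate_observed(
    network: ReactionNetwork,
    theta_true: dict,
    fine_grid,
    obs_times,
    observed_species,
    noise_frac: float,
    n_rep: int = 10,
    rng=None,
    seed: int | None = None,
    inputs=None,
    noise_as_variance: bool = False,
) -> ObservedDataset:
    """Noise-on-trajectories observed data.

    ``theta_true`` maps parameter name -> rate constant in linear space.
    Noise sd per replicate is ``noise_frac * |true value|`` (or
    ``sqrt(noise_frac) * ...`` scaling when ``noise_as_variance``, i.e. the
    variance equals ``noise_frac * |true value|``).
    """
    if noise_frac < 0:
        raise SpecificationError("noise_frac must be >= 0")
    if n_rep < 2:
        raise SpecificationError("n_rep must be >= 2")
    obs_times, fine_grid = _check_obs_times(obs_times, fine_grid)
    rng = _resolve_rng(rng, seed)
    traj = simulate(network, theta_true, fine_grid, inputs=inputs)  # truth must simulate

    species_col, time_col, mean_col, sd_col = [], [], [], []
    for sp in observed_species:
        truth = np.array([traj.value_at(sp, t) for t in obs_times])
        noise_sd = (
            np.sqrt(noise_frac * np.abs(truth)) if noise_as_variance else noise_frac * np.abs(truth)
        )
        reps = truth[None, :] + rng.normal(0.0, 1.0, size=(n_rep, len(obs_times))) * noise_sd
        species_col += [sp] * len(obs_times)
        time_col += list(obs_times)
        mean_col += list(reps.mean(axis=0))
        sd_col += list(reps.std(axis=0, ddof=1))

    return ObservedDataset(
        species=species_col,
        times=time_col,
        means=mean_col,
        sds=sd_col,
        provenance={
            "generator": "generate_observed",
            "network": network.name or None,
            "theta_true": {k: float(v) for k, v in theta_true.items()},
            "fine_grid": [float(t) for t in fine_grid],
            "obs_times": [float(t) for t in obs_times],
            "observed_species": list(observed_species),
            "noise_frac": float(noise_frac),
            "noise_as_variance": bool(noise_as_variance),
            "n_rep": int(n_rep),
            "seed": seed,
            "inputs": _inputs_dict(inputs),
        },
    )


def generate_param_noise_observed(
    network: ReactionNetwork,
    log10_theta_true: dict,
    obs_times,
    observed_species,
    sd_log: float = 0.05,
    n_rep: int = 10,
    rng=None,
    seed: int | None = None,
    inputs=None,
) -> ObservedDataset:
    """Noise-on-parameters observed data.

    Each replicate perturbs the log10 true parameters with N(0, sd_log)
    noise (so linear-space rate constants are log-normal around truth),
    simulates the perturbed model, and the pointwise mean/sd over the
    replicate *model outputs* form the observed data.
    """
    if sd_log < 0:
        raise SpecificationError("sd_log must be >= 0")
    if n_rep < 2:
        raise SpecificationError("n_rep must be >= 2")
    obs_times = np.asarray(obs_times, dtype=float)
    rng = _resolve_rng(rng, seed)
    names = list(log10_theta_true)
    base = np.array([log10_theta_true[n] for n in names])

    outputs = {sp: np.empty((n_rep, len(obs_times))) for sp in observed_species}
    for rep in range(n_rep):
        pert = base + rng.normal(0.0, sd_log, size=base.shape)
        params = {n: 10.0**v for n, v in zip(names, pert)}
        try:
            traj = simulate(network, params, obs_times, inputs=inputs)
        except SimulationFailure as exc:
            raise SimulationFailure(
                f"replicate {rep} failed to simulate: {exc}", params
            ) from exc
        for sp in observed_species:
            outputs[sp][rep] = traj.series(sp)

    species_col, time_col, mean_col, sd_col = [], [], [], []
    for sp in observed_species:
        species_col += [sp] * len(obs_times)
        time_col += list(obs_times)
        mean_col += list(outputs[sp].mean(axis=0))
        sd_col += list(outputs[sp].std(axis=0, ddof=1))

    return ObservedDataset(
        species=species_col,
        times=time_col,
        means=mean_col,
        sds=sd_col,
        provenance={
            "generator": "generate_param_noise_observed",
            "network": network.name or None,
            "log10_theta_true": {k: float(v) for k, v in log10_theta_true.items()},
            "obs_times": [float(t) for t in obs_times],
            "observed_species": list(observed_species),
            "sd_log": float(sd_log),
            "n_rep": int(n_rep),
            "seed": seed,
            "inputs": _inputs_dict(inputs),
        },
    )


# ---------------------------------------------------------------------------
# dose-response protocols
# ---------------------------------------------------------------------------

def linear_dose_protocol(doses=(1.0, 2.0, 3.0, 4.0), obs_times=(0.0, 100.0, 200.0, 300.0)):
    """Constant-signal experiments for the linear dose-response study.

    One experiment per dose, each observed at the given time points
    (including t = 0); the default four doses x four times yield 16
    observation records.
    """
    doses = list(doses)
    protocols = []
    t_end = max(obs_times) if len(obs_times) else 0.0
    for dose in doses:
        protocols.append(
            {
                "name": f"S={dose:g}",
                "inputs": [StimulusSegment("S", float(dose), 0.0, float(t_end) + 1.0)],
                "obs_times": list(obs_times),
            }
        )
    return protocols


def adapting_dose_protocol(steps=(1.0, 2.0), step_time=10.0, t_end=20.0, obs_times=None):
    """Single experiment with successive step increases of the signal."""
    if len(steps) != 2:
        raise SpecificationError("adapting protocol uses two successive S values")
    if obs_times is None:
        obs_times = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.5, 11.0, 12.0, 14.0, 18.0]
        obs_times = [t for t in obs_times if t <= t_end]
    segments = [
        StimulusSegment("S", float(steps[0]), 0.0, float(step_time)),
        StimulusSegment("S", float(steps[1]), float(step_time), float(t_end) + 1.0),
    ]
    return [{"name": f"S={steps[0]:g}->{steps[1]:g}", "inputs": segments, "obs_times": list(obs_times)}]


def dose_response_protocol(kind: str, **kwargs):
    """Dispatch to :func:`linear_dose_protocol` or :func:`adapting_dose_protocol`."""
    if kind == "linear":
        return linear_dose_protocol(**kwargs)
    if kind == "adapting":
        return adapting_dose_protocol(**kwargs)
    raise SpecificationError(f"unknown dose-response protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _resolve_rng(rng, seed):
    if rng is not None:
        return rng
    return np.random.default_rng(0 if seed is None else seed)


def _inputs_dict(inputs):
    if not inputs:
        return None
    return [
        {"name": s.name, "value": s.value, "start": s.start, "end": s.end} for s in inputs
    ]


def regenerate(dataset: ObservedDataset, network: ReactionNetwork) -> ObservedDataset:
    """Rebuild a dataset from its provenance (round-trip check helper)."""
    prov = dataset.provenance
    inputs = None
    if prov.get("inputs"):
        inputs = [
            StimulusSegment(d["name"], d["value"], d["start"], d["end"])
            for d in prov["inputs"]
        ]
    if prov.get("generator") == "generate_observed":
        return generate_observed(
            network,
            prov["theta_true"],
            prov["fine_grid"],
            prov["obs_times"],
            prov["observed_species"],
            prov["noise_frac"],
            n_rep=prov["n_rep"],
            seed=prov["seed"],
            inputs=inputs,
            noise_as_variance=prov.get("noise_as_variance", False),
        )
    if prov.get("generator") == "generate_param_noise_observed":
        return generate_param_noise_observed(
            network,
            prov["log10_theta_true"],
            prov["obs_times"],
            prov["observed_species"],
            sd_log=prov["sd_log"],
            n_rep=prov["n_rep"],
            seed=prov["seed"],
            inputs=inputs,
        )
    raise SpecificationError("dataset provenance does not name a known generator")
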