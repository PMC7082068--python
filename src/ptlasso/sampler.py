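"""Metropolis-Hastings kernel and Parallel Tempering orchestration.

A ladder of chains runs at inverse temperatures ``beta`` (1 = the posterior,
smaller = flatter).  Each "swap" consists of ``n_mcmc`` MH steps per chain
followed by one sweep of configuration-exchange attempts between adjacent
temperatures, accepted with probability ``min(1, exp(dbeta * dE))``.  The
parameter vector recorded from the beta=1 chain at each post-burn-in swap is
one posterior sample.

Proposal scales adapt multiplicatively toward the optimal acceptance rate
0.234 during the burn-in swaps only; they are frozen afterwards so that the
sampling phase satisfies detailed balance.  Chains are run serially in a
fixed order with per-chain random streams plus a dedicated stream for swap
decisions, so results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InitializationError, PTLassoError, SpecificationError

__all__ = [
    "ChainState",
    "PTSettings",
    "SampleStore",
    "propose",
    "mh_step",
    "attempt_swaps",
    "adapt_burn_in",
    "init_chains",
    "run_pt",
    "geometric_ladder",
    "TARGET_ACCEPTANCE",
]

#: Optimal random-walk Metropolis acceptance rate targeted by adaptation.
TARGET_ACCEPTANCE = 0.234


@dataclass
class ChainState:
    """State of one tempered chain.

    ``proposal_scale`` is the per-parameter Gaussian proposal width, the
    product of a scalar ``base_scale`` (tuned to the target acceptance
    rate) and a per-coordinate ``shape`` (tuned during burn-in to the
    coordinate spreads, so that prior-confined parameters take usefully
    large steps while data-pinned parameters take small ones).
    """

    theta: np.ndarray
    energy: float
    beta: float
    proposal_scale: np.ndarray
    rng: np.random.Generator
    accept_count: int = 0
    step_count: int = 0
    base_scale: float = None
    shape: np.ndarray = None
    ema_mean: np.ndarray = None
    ema_var: np.ndarray = None
    rate_ema: float = None
    bold_prob: float = 0.0
    bold_scale: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise SpecificationError(f"beta must be in (0, 1], got {self.beta}")
        self.theta = np.asarray(self.theta, dtype=float).copy()
        self.proposal_scale = np.broadcast_to(
            np.asarray(self.proposal_scale, dtype=float), self.theta.shape
        ).copy()
        if np.any(self.proposal_scale <= 0):
            raise SpecificationError("proposal scales must be > 0")
        if self.base_scale is None:
            self.base_scale = float(np.exp(np.mean(np.log(self.proposal_scale))))
        if self.shape is None:
            self.shape = self.proposal_scale / self.base_scale

    def update_spread(self, alpha: float):
        """EMA estimate of per-coordinate mean/variance (burn-in only)."""
        if self.ema_mean is None:
            self.ema_mean = self.theta.copy()
            self.ema_var = np.zeros_like(self.theta)
            return
        delta = self.theta - self.ema_mean
        self.ema_mean = self.ema_mean + alpha * delta
        self.ema_var = (1.0 - alpha) * (self.ema_var + alpha * delta**2)


def geometric_ladder(n_chains: int = 6, beta_min: float = 0.05) -> np.ndarray:
    """Geometric inverse-temperature ladder from 1 down to ``beta_min``."""
    if n_chains < 1:
        raise SpecificationError("n_chains must be >= 1")
    if n_chains == 1:
        return np.array([1.0])
    return np.geomspace(1.0, beta_min, n_chains)


@dataclass
class PTSettings:
    """Sampler settings: ladder, steps per swap, swap counts, adaptation."""

    n_chains: int = 6
    betas: np.ndarray | None = None
    n_mcmc: int = 25
    n_swaps: int = 500
    burn_in_swaps: int = 100
    adapt: bool = True
    target_acceptance: float = TARGET_ACCEPTANCE
    adapt_eta: float = 0.5
    beta_min: float = 0.05
    initial_scale: float = 0.5
    spread_alpha: float = 0.005  # EMA rate for the burn-in spread estimate
    bold_prob: float = 0.2  # weight of the single-coordinate bold component
    bold_scale: float = 1.5

    def __post_init__(self):
        if self.betas is None:
            self.betas = geometric_ladder(self.n_chains, self.beta_min)
        self.betas = np.asarray(self.betas, dtype=float)
        self.n_chains = len(self.betas)
        if self.betas[0] != 1.0:
            raise SpecificationError("betas must start at 1")
        if len(self.betas) > 1 and np.any(np.diff(self.betas) >= 0):
            raise SpecificationError("betas must be strictly decreasing")
        if self.n_mcmc < 1:
            raise SpecificationError("n_mcmc must be >= 1")
        if self.n_swaps < 1 or self.burn_in_swaps < 0:
            raise SpecificationError("swap counts must be positive")


# ---------------------------------------------------------------------------
# kernel operations
# ---------------------------------------------------------------------------

def propose(theta: np.ndarray, proposal_scale, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Gaussian proposal: independent perturbation per coordinate."""
    theta = np.asarray(theta, dtype=float)
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), theta.shape)
    if np.any(scale <= 0):
        raise SpecificationError("proposal scales must be > 0")
    return theta + rng.normal(0.0, scale)


def mh_step(state: ChainState, energy_fn) -> ChainState:
    """One Metropolis-Hastings step, in place.

    Accepts with probability ``min(1, exp(-beta * dE))``; a NaN energy is
    treated as +inf (certain rejection).  On rejection the chain stays put.

    The proposal is a symmetric mixture: with probability ``bold_prob`` a
    single random coordinate is perturbed with the fixed ``bold_scale``
    (guaranteeing every coordinate a mobility floor independent of the
    adapted per-coordinate widths), otherwise all coordinates receive the
    adapted Gaussian perturbation.  Both components are symmetric, so no
    Hastings correction is needed.
    """
    if state.bold_prob > 0.0 and state.rng.uniform() < state.bold_prob:
        theta_new = state.theta.copy()
        j = int(state.rng.integers(state.theta.shape[0]))
        theta_new[j] += state.rng.normal(0.0, state.bold_scale)
    else:
        theta_new = propose(state.theta, state.proposal_scale, state.rng)
    e_new = energy_fn(theta_new)
    if math.isnan(e_new):
        e_new = math.inf
    d_e = e_new - state.energy
    accept = d_e <= 0
    if not accept and np.isfinite(d_e):
        accept = state.rng.uniform() < math.exp(-state.beta * d_e)
    if accept:
        state.theta = theta_new
        state.energy = float(e_new)
        state.accept_count += 1
    state.step_count += 1
    return state


def attempt_swaps(chains, rng: np.random.Generator):
    """One sweep of configuration swaps between adjacent temperatures.

    ``chains`` must be ladder-ordered cold to hot (beta strictly
    decreasing); the sweep visits consecutive pairs hottest-first so a
    favourable configuration can ride the ladder down to the cold chain
    within one sweep.  Returns per-pair acceptance flags, index i for the
    pair (chains[i], chains[i+1]).
    """
    n = len(chains)
    if n < 2:
        raise SpecificationError("swaps need at least 2 chains")
    accepted = np.zeros(n - 1, dtype=bool)
    for i in range(n - 2, -1, -1):
        cold, hot = chains[i], chains[i + 1]
        d_beta = cold.beta - hot.beta
        d_e = cold.energy - hot.energy
        log_p = d_beta * d_e
        if log_p >= 0 or (np.isfinite(log_p) and rng.uniform() < math.exp(log_p)):
            cold.theta, hot.theta = hot.theta, cold.theta
            cold.energy, hot.energy = hot.energy, cold.energy
            accepted[i] = True
    return accepted


def adapt_burn_in(chains, window_rates, settings: PTSettings, swap_index: int):
    """Adjust proposal scales toward the target acceptance rate.

    ``window_rates`` is the per-chain acceptance rate observed over the last
    swap block.  The scalar base scale moves by ``exp(eta * (rate -
    target))``: up when acceptance is high, down when it is low.  When a
    chain carries an EMA spread estimate (see
    :meth:`ChainState.update_spread`), the per-coordinate shape is pulled
    toward the estimated coordinate standard deviations (normalized to
    geometric mean 1, clamped to [0.05, 20]).  Only legal during burn-in;
    scales are frozen afterwards to preserve detailed balance.
    """
    if swap_index >= settings.burn_in_swaps:
        raise PTLassoError("adapt_burn_in called after the burn-in phase")
    # diminishing adaptation: late windows move the scale less, so the
    # frozen value is not at the mercy of one noisy 25-step window
    frac = swap_index / max(settings.burn_in_swaps, 1)
    eta = settings.adapt_eta * (1.0 - 0.8 * frac)
    for chain, rate in zip(chains, window_rates):
        if chain.rate_ema is None:
            chain.rate_ema = float(rate)
        else:
            chain.rate_ema += 0.25 * (float(rate) - chain.rate_ema)
        chain.base_scale *= math.exp(eta * (chain.rate_ema - settings.target_acceptance))
        chain.base_scale = min(max(chain.base_scale, 0.02), 3.0)
        if chain.ema_var is not None and np.all(chain.ema_var > 0):
            sd = np.sqrt(chain.ema_var)
            shape = sd / np.exp(np.mean(np.log(sd)))
            # lower clip keeps a transiently quiescent coordinate mobile
            # enough to escape if the landscape later pulls on it
            chain.shape = np.clip(shape, 0.2, 10.0)
        chain.proposal_scale = chain.base_scale * chain.shape
    return chains


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_chains(
    space,
    energy_fn,
    settings: PTSettings,
    seed: int,
    mode: str = "prior-threshold",
    threshold: float = np.inf,
    warm_start=None,
    max_attempts: int = 10000,
):
    """Build one :class:`ChainState` per ladder rung.

    ``prior-threshold`` draws from the prior (restricted to the sampling
    box) until the energy falls below ``threshold``; ``warm-start`` seeds
    every chain from a supplied parameter vector (e.g. a stored sample from
    an earlier run).  Chains receive distinct random streams spawned from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(settings.n_chains + 1)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[:-1]]
    swap_rng = np.random.Generator(np.random.PCG64(children[-1]))

    chains = []
    for beta, rng in zip(settings.betas, rngs):
        if mode == "warm-start":
            if warm_start is None:
                raise SpecificationError("warm-start mode requires a start vector")
            theta = np.asarray(warm_start, dtype=float).copy()
            e = float(energy_fn(theta))
            if not np.isfinite(e):
                raise InitializationError("warm-start vector has non-finite energy", best_energy=e)
        elif mode == "prior-threshold":
            if not np.isfinite(threshold) and threshold != np.inf:
                raise SpecificationError("threshold must be finite or +inf")
            best = np.inf
            theta, e = None, np.inf
            for _ in range(max_attempts):
                cand = space.sample(rng)
                e_cand = float(energy_fn(cand))
                if e_cand < best:
                    best = e_cand
                if e_cand < threshold and np.isfinite(e_cand):
                    theta, e = cand, e_cand
                    break
            if theta is None:
                raise InitializationError(
                    f"no start point with energy < {threshold} found in "
                    f"{max_attempts} prior draws",
                    best_energy=best,
                )
        else:
            raise SpecificationError(f"unknown initialization mode {mode!r}")
        chains.append(
            ChainState(
                theta=theta,
                energy=e,
                beta=float(beta),
                proposal_scale=np.full(space.n_params, settings.initial_scale),
                rng=rng,
                bold_prob=settings.bold_prob,
                bold_scale=settings.bold_scale,
            )
        )
    return chains, swap_rng


# ---------------------------------------------------------------------------
# sample storage
# ---------------------------------------------------------------------------

@dataclass
class SampleStore:
    """Per-swap record of every chain's (theta, E) plus run tallies.

    The posterior sample is the beta=1 chain's record at each post-burn-in
    swap; ``posterior()`` returns exactly ``n_swaps - burn_in`` vectors.
    """

    param_names: list
    betas: np.ndarray
    thetas: np.ndarray  # (n_swaps_total, n_chains, n_params)
    energies: np.ndarray  # (n_swaps_total, n_chains)
    burn_in: int
    step_accepts: np.ndarray = None  # sampling-phase tallies per chain
    step_attempts: np.ndarray = None
    swap_accepts: np.ndarray = None  # per adjacent pair
    swap_attempts: np.ndarray = None
    proposal_scales: np.ndarray = None  # frozen post-burn-in scales
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.betas)

    @property
    def n_swaps_total(self) -> int:
        return self.thetas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.n_swaps_total - self.burn_in

    def posterior(self, chain: int = 0) -> np.ndarray:
        """Post-burn-in samples of one chain, shape (n_samples, n_params)."""
        return self.thetas[self.burn_in :, chain, :]

    def posterior_energies(self, chain: int = 0) -> np.ndarray:
        return self.energies[self.burn_in :, chain]

    def marginal(self, name: str, chain: int = 0) -> np.ndarray:
        return self.posterior(chain)[:, self.param_names.index(name)]

    # -- persistence -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.thetas[:, c, :], columns=self.param_names)
            df.insert(0, "energy", self.energies[:, c])
            df.insert(0, "beta", self.betas[c])
            df.insert(0, "chain", c)
            df.insert(0, "swap", np.arange(self.n_swaps_total))
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def _meta_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "param_names": list(self.param_names),
            "betas": arr(self.betas),
            "burn_in": int(self.burn_in),
            "step_accepts": arr(self.step_accepts),
            "step_attempts": arr(self.step_attempts),
            "swap_accepts": arr(self.swap_accepts),
            "swap_attempts": arr(self.swap_attempts),
            "proposal_scales": arr(self.proposal_scales),
            "seed": self.seed,
            "meta": self.meta,
        }

    def write_tsv(self, path) -> None:
        """Canonical tabular form: one row per (swap, chain) plus a JSON
        sidecar ``<path>.meta.json`` holding ladder and tally metadata."""
        path = str(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        with open(path + ".meta.json", "w") as fh:
            json.dump(self._meta_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def read_tsv(cls, path) -> "SampleStore":
        path = str(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        try:
            with open(path + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = None
        param_names = [c for c in df.columns if c not in ("swap", "chain", "beta", "energy")]
        chains = sorted(df["chain"].unique())
        n_swaps = df["swap"].max() + 1
        thetas = np.empty((n_swaps, len(chains), len(param_names)))
        energies = np.empty((n_swaps, len(chains)))
        betas = np.empty(len(chains))
        for c in chains:
            sub = df[df["chain"] == c].sort_values("swap")
            thetas[:, c, :] = sub[param_names].to_numpy()
            energies[:, c] = sub["energy"].to_numpy()
            betas[c] = sub["beta"].iloc[0]
        if meta is None:
            return cls(param_names, betas, thetas, energies, burn_in=0)

        def arr(x):
            return None if x is None else np.asarray(x)

        return cls(
            param_names=meta["param_names"],
            betas=np.asarray(meta["betas"]),
            thetas=thetas,
            energies=energies,
            burn_in=meta["burn_in"],
            step_accepts=arr(meta["step_accepts"]),
            step_attempts=arr(meta["step_attempts"]),
            swap_accepts=arr(meta["swap_accepts"]),
            swap_attempts=arr(meta["swap_attempts"]),
            proposal_scales=arr(meta["proposal_scales"]),
            seed=meta.get("seed"),
            meta=meta.get("meta", {}),
        )

    def write_hdf5(self, path) -> None:
        """Compact binary container for large runs."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("thetas", data=self.thetas, compression="gzip")
            fh.create_dataset("energies", data=self.energies, compression="gzip")
            fh.create_dataset("betas", data=self.betas)
            fh.attrs["meta_json"] = json.dumps(self._meta_dict())

    @classmethod
    def read_hdf5(cls, path) -> "SampleStore":
        import h5py

        with h5py.File(path, "r") as fh:
            meta = json.loads(fh.attrs["meta_json"])
            thetas = fh["thetas"][()]
            energies = fh["energies"][()]

        def arr(x):
            return None if x is None else np.asarray(x)

        return cls(
            param_names=meta["param_names"],
            betas=np.asarray(meta["betas"]),
            thetas=thetas,
            energies=energies,
            burn_in=meta["burn_in"],
            step_accepts=arr(meta["step_accepts"]),
            step_attempts=arr(meta["step_attempts"]),
            swap_accepts=arr(meta["swap_accepts"]),
            swap_attempts=arr(meta["swap_attempts"]),
            proposal_scales=arr(meta["proposal_scales"]),
            seed=meta.get("seed"),
            meta=meta.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def run_pt(
    energy_fn,
    space,
    settings: PTSettings,
    seed: int,
    init_mode: str = "prior-threshold",
    init_threshold: float = np.inf,
    warm_start=None,
    log_every: int | None = None,
) -> SampleStore:
    """Run Parallel Tempering and return the full sample store.

    Executes ``burn_in_swaps + n_swaps`` swap cycles; each cycle runs
    ``n_mcmc`` MH steps on every chain (serially, in ladder order), records
    each chain's final state, then performs one swap sweep.  With a single
    chain this reduces exactly to plain Metropolis-Hastings.
    """
    chains, swap_rng = init_chains(
        space,
        energy_fn,
        settings,
        seed,
        mode=init_mode,
        threshold=init_threshold,
        warm_start=warm_start,
    )
    n_chains = settings.n_chains
    total = settings.burn_in_swaps + settings.n_swaps
    n_par = space.n_params

    thetas = np.empty((total, n_chains, n_par))
    energies = np.empty((total, n_chains))
    swap_accepts = np.zeros(max(n_chains - 1, 0), dtype=int)
    swap_attempts = np.zeros(max(n_chains - 1, 0), dtype=int)
    burn_step_accepts = np.zeros(n_chains, dtype=int)
    burn_step_attempts = np.zeros(n_chains, dtype=int)
    adapt_until = int(0.6 * settings.burn_in_swaps)
    probe_accepts = np.zeros(n_chains, dtype=int)
    probe_steps = np.zeros(n_chains, dtype=int)

    for swap in range(total):
        in_burn = swap < settings.burn_in_swaps
        window_accepts = np.empty(n_chains)
        for c, chain in enumerate(chains):
            a0, s0 = chain.accept_count, chain.step_count
            if in_burn and settings.adapt:
                alpha = settings.spread_alpha
                for _ in range(settings.n_mcmc):
                    mh_step(chain, energy_fn)
                    chain.update_spread(alpha)
            else:
                for _ in range(settings.n_mcmc):
                    mh_step(chain, energy_fn)
            window_accepts[c] = (chain.accept_count - a0) / (chain.step_count - s0)
            thetas[swap, c, :] = chain.theta
            energies[swap, c] = chain.energy
        if n_chains > 1:
            accepted = attempt_swaps(chains, swap_rng)
            if not in_burn:
                swap_attempts += 1
                swap_accepts += accepted
        if in_burn:
            adapt_phase = swap < adapt_until
            if settings.adapt and adapt_phase:
                adapt_burn_in(chains, window_accepts, settings, swap)
            elif settings.adapt and swap == adapt_until:
                # start of the measurement phase: scales frozen, acceptance
                # accumulated from here with the chains near equilibrium
                for c, chain in enumerate(chains):
                    probe_accepts[c] = chain.accept_count
                    probe_steps[c] = chain.step_count
            if settings.adapt and swap == settings.burn_in_swaps - 1 and adapt_until < settings.burn_in_swaps:
                # one calibrated correction from the measured rate: the
                # local slope of acceptance vs log scale is about -1/3, so
                # kappa ~ 3 maps a rate error onto a log-scale move
                for c, chain in enumerate(chains):
                    steps = chain.step_count - probe_steps[c]
                    if steps > 0:
                        measured = (chain.accept_count - probe_accepts[c]) / steps
                        chain.base_scale *= math.exp(
                            3.0 * (measured - settings.target_acceptance)
                        )
                        chain.base_scale = min(max(chain.base_scale, 0.02), 3.0)
                        chain.proposal_scale = chain.base_scale * chain.shape
            if swap == settings.burn_in_swaps - 1:
                for c, chain in enumerate(chains):
                    burn_step_accepts[c] = chain.accept_count
                    burn_step_attempts[c] = chain.step_count
        if log_every and (swap + 1) % log_every == 0:
            import sys

            print(
                f"swap {swap + 1}/{total} E=" + " ".join(f"{c.energy:.3g}" for c in chains),
                file=sys.stderr,
            )

    step_accepts = np.array([c.accept_count for c in chains]) - burn_step_accepts
    step_attempts = np.array([c.step_count for c in chains]) - burn_step_attempts

    return SampleStore(
        param_names=list(space.names),
        betas=settings.betas.copy(),
        thetas=thetas,
        energies=energies,
        burn_in=settings.burn_in_swaps,
        step_accepts=step_accepts,
        step_attempts=step_attempts,
        swap_accepts=swap_accepts,
        swap_attempts=swap_attempts,
        proposal_scales=np.array([c.proposal_scale for c in chains]),
        seed=seed,
    )
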