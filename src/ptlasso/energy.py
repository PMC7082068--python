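"""Posterior energy: Gaussian likelihood, Laplace (Lasso) priors, grouped
Lasso penalties and hard/soft constraints.

All sampling happens in log10 parameter space; a parameter vector ``theta``
is the vector of log10 rate constants.  The energy of a vector is

    E(theta) = -log L(theta) - log p(theta) + soft penalties,

with the likelihood the unnormalized Gaussian

    log L = -sum_S sum_T (Y_sim - Y_expt)^2 / (2 sigma^2)

over observed species S and time points T, and the prior either a uniform
box (contributing 0 inside, +inf outside) or a Laplace density whose log is
``-|theta - mu| / b`` (the -log 2b normalization constant is dropped
throughout; it shifts the energy by a constant that cancels in every
Metropolis ratio).  Hard-constraint violations, box violations and failed
simulations all give exactly ``+inf``.

Grouped (module-level) Lasso composes each penalized log rate constant from
a shared module penalty parameter and a box-bounded reaction-specific
parameter, ``theta'_i = k'_i + lambda'_m``; the Laplace penalty acts on the
module parameters only, so driving one ``lambda'_m`` to its prior location
removes the entire module from the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidHyperparameterError,
    SimulationFailure,
    SpecificationError,
)
from .networks import ReactionNetwork, Trajectory
from .simulate import (  # noqa: F401  (simulate re-exported for callers)
    simulate,
    simulate_values,
    simulate_values_stacked,
)

__all__ = [
    "UniformPrior",
    "LaplacePrior",
    "ParameterSpace",
    "LikelihoodSpec",
    "Experiment",
    "HardConstraint",
    "SoftConstraint",
    "ConstraintSet",
    "GroupedSpec",
    "laplace_log_prior",
    "log_likelihood",
    "check_hard_constraints",
    "EnergyModel",
    "GroupedEnergyModel",
    "energy",
    "grouped_energy",
]


# ---------------------------------------------------------------------------
# priors and parameter space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformPrior:
    """Uniform box prior; contributes zero inside the sampling bounds."""


@dataclass(frozen=True)
class LaplacePrior:
    """Laplace prior in log10 space with location ``mu`` and width ``b``."""

    mu: float
    b: float

    def __post_init__(self):
        if not self.b > 0:
            raise InvalidHyperparameterError(f"Laplace width b must be > 0, got {self.b}")


def laplace_log_prior(theta: float, mu: float, b: float):
    """Unnormalized Laplace log density ``-|theta - mu| / b``.

    The constant ``-log 2b`` is dropped; see module docstring.
    """
    if not b > 0:
        raise InvalidHyperparameterError(f"Laplace width b must be > 0, got {b}")
    return -np.abs(np.asarray(theta, dtype=float) - mu) / b


class ParameterSpace:
    """Ordered parameters with per-parameter log10 bounds and priors.

    Parameters
    ----------
    names : sequence of str
    lower, upper : per-parameter log10 bounds, lower < upper
    priors : per-parameter UniformPrior or LaplacePrior (default uniform)
    groups : optional map name -> module id (grouped mode bookkeeping)
    """

    def __init__(self, names, lower, upper, priors=None, groups=None):
        self.names = list(names)
        self.lower = np.broadcast_to(np.asarray(lower, dtype=float), (len(self.names),)).copy()
        self.upper = np.broadcast_to(np.asarray(upper, dtype=float), (len(self.names),)).copy()
        if np.any(self.lower >= self.upper):
            bad = [n for n, lo, up in zip(self.names, self.lower, self.upper) if lo >= up]
            raise SpecificationError(f"lower bound must be < upper bound for {bad}")
        if priors is None:
            priors = [UniformPrior()] * len(self.names)
        self.priors = list(priors)
        if len(self.priors) != len(self.names):
            raise SpecificationError("one prior per parameter required")
        self.groups = dict(groups or {})
        self._index = {n: i for i, n in enumerate(self.names)}
        # cached arrays for the Laplace penalty
        lap = [(i, p.mu, p.b) for i, p in enumerate(self.priors) if isinstance(p, LaplacePrior)]
        self._lap_idx = np.array([i for i, _, _ in lap], dtype=int)
        self._lap_mu = np.array([m for _, m, _ in lap])
        self._lap_b = np.array([b for _, _, b in lap])

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SpecificationError(f"unknown parameter {name!r}") from None

    def in_bounds(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def log_prior(self, theta: np.ndarray) -> float:
        """Sum of unnormalized log prior terms; -inf outside the box."""
        theta = np.asarray(theta, dtype=float)
        if not self.in_bounds(theta):
            return -np.inf
        if self._lap_idx.size == 0:
            return 0.0
        return float(-np.sum(np.abs(theta[self._lap_idx] - self._lap_mu) / self._lap_b))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One draw from the prior restricted to the sampling box.

        Uniform parameters are drawn uniformly; Laplace parameters via the
        inverse CDF of the Laplace distribution truncated to the box.
        """
        theta = rng.uniform(self.lower, self.upper)
        for i, mu, b in zip(self._lap_idx, self._lap_mu, self._lap_b):
            theta[i] = _truncated_laplace(rng, mu, b, self.lower[i], self.upper[i])
        return theta

    def theta_dict(self, theta: np.ndarray) -> dict:
        return dict(zip(self.names, np.asarray(theta, dtype=float)))


def _laplace_cdf(x, mu, b):
    z = (x - mu) / b
    return np.where(z < 0, 0.5 * np.exp(z), 1.0 - 0.5 * np.exp(-z))


def _truncated_laplace(rng, mu, b, lo, hi):
    u = rng.uniform(_laplace_cdf(lo, mu, b), _laplace_cdf(hi, mu, b))
    if u < 0.5:
        return mu + b * np.log(2.0 * u)
    return mu - b * np.log(2.0 * (1.0 - u))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class LikelihoodSpec:
    """Gaussian likelihood target: records of (species, time, mean, sd).

    ``sigma`` can differ between records.  Zero replicate standard
    deviations (e.g. a t=0 point whose true value is 0, where proportional
    noise vanishes) would make the Gaussian ill-defined, so every sigma is
    floored at ``max(sd_floor, 0.01 * max |observed mean|)``.
    """

    def __init__(self, species, times, means, sds, sd_floor: float = 1e-6):
        self.species = list(species)
        self.times = np.asarray(times, dtype=float)
        self.means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        if not (len(self.species) == len(self.times) == len(self.means) == len(sds)):
            raise SpecificationError("species, times, means, sds must have equal length")
        if np.any(sds < 0):
            raise SpecificationError("negative sd in likelihood spec")
        if not sd_floor > 0:
            raise SpecificationError("sd_floor must be > 0")
        floor = max(sd_floor, 1e-2 * float(np.max(np.abs(self.means))) if self.means.size else sd_floor)
        self.sd_floor = floor
        self.sds = np.maximum(sds, floor)

    @classmethod
    def from_dataset(cls, dataset, sd_floor: float = 1e-6) -> "LikelihoodSpec":
        df = dataset.to_frame() if hasattr(dataset, "to_frame") else dataset
        return cls(df["species"], df["time"], df["mean"], df["sd"], sd_floor=sd_floor)

    def __len__(self):
        return len(self.means)


def log_likelihood(traj: Trajectory, lik: LikelihoodSpec) -> float:
    """Unnormalized Gaussian log likelihood of a trajectory.

    Returns ``-sum (Y_sim - Y_expt)^2 / (2 sigma^2)``; ``-inf`` when the
    trajectory contains non-finite values.  A (species, time) record absent
    from the trajectory grid is a specification error.
    """
    sims = np.empty(len(lik))
    sp_col = {sp: i for i, sp in enumerate(traj.species)}
    for r, (sp, t) in enumerate(zip(lik.species, lik.times)):
        if sp not in sp_col:
            raise SpecificationError(f"observed species {sp!r} not in trajectory")
        idx = np.flatnonzero(np.isclose(traj.times, t, rtol=1e-9, atol=1e-9))
        if idx.size == 0:
            raise SpecificationError(f"observation time {t} not on trajectory grid")
        sims[r] = traj.values[idx[0], sp_col[sp]]
    if not np.all(np.isfinite(sims)):
        return -np.inf
    return float(-np.sum((sims - lik.means) ** 2 / (2.0 * lik.sds**2)))


@dataclass
class Experiment:
    """One stimulus protocol together with its observations."""

    likelihood: LikelihoodSpec
    inputs: list = field(default_factory=list)
    name: str = ""


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HardConstraint:
    """Strict inequality over named parameters, evaluated in log10 space.

    ``expression`` uses whitespace-separated tokens: parameter names or
    numbers joined by ``+``/``-``, with a single ``<`` or ``>``, e.g.
    ``"k_exit_complex > k_exit_free"`` or ``"k_AB > k_BC - 1"``.
    """

    expression: str

    def evaluate(self, values: dict) -> bool:
        for op in ("<", ">"):
            if op in self.expression:
                left, right = self.expression.split(op, 1)
                lv = _eval_linear(left, values, self.expression)
                rv = _eval_linear(right, values, self.expression)
                return lv < rv if op == "<" else lv > rv
        raise SpecificationError(f"constraint {self.expression!r} has no comparison operator")


def _eval_linear(text: str, values: dict, expr: str) -> float:
    tokens = text.split()
    if not tokens:
        raise SpecificationError(f"empty side in constraint {expr!r}")
    total, sign = 0.0, 1.0
    expect_operand = True
    for tok in tokens:
        if tok in ("+", "-"):
            if expect_operand:
                raise SpecificationError(f"misplaced operator in constraint {expr!r}")
            sign = 1.0 if tok == "+" else -1.0
            expect_operand = True
            continue
        if not expect_operand:
            raise SpecificationError(f"missing operator in constraint {expr!r}")
        if tok in values:
            total += sign * values[tok]
        else:
            try:
                total += sign * float(tok)
            except ValueError:
                raise SpecificationError(
                    f"unresolvable name {tok!r} in constraint {expr!r}"
                ) from None
        expect_operand = False
    if expect_operand:
        raise SpecificationError(f"dangling operator in constraint {expr!r}")
    return total


@dataclass(frozen=True)
class SoftConstraint:
    """Finite quadratic penalty on a trajectory feature.

    ``weight * (feature - target)^2`` is added to the energy, where the
    feature is the simulated abundance of ``species`` at ``time`` (the final
    grid point when ``time`` is None) in experiment ``experiment``.
    """

    species: str
    target: float
    weight: float
    time: float | None = None
    experiment: int = 0

    def penalty(self, traj: Trajectory) -> float:
        col = traj.species.index(self.species)
        if self.time is None:
            value = traj.values[-1, col]
        else:
            value = traj.value_at(self.species, self.time)
        return self.weight * (value - self.target) ** 2


@dataclass
class ConstraintSet:
    hard: list = field(default_factory=list)
    soft: list = field(default_factory=list)


def check_hard_constraints(theta_values: dict, constraints: ConstraintSet):
    """Evaluate all hard constraints; returns (passed, violated list)."""
    violated = [c for c in constraints.hard if not c.evaluate(theta_values)]
    return (len(violated) == 0, violated)


# ---------------------------------------------------------------------------
# energy models
# ---------------------------------------------------------------------------

class EnergyModel:
    """Posterior energy for a network fit to one or more experiments.

    Callable on a log10 parameter vector ordered as ``space.names`` (which
    must coincide with the network's reaction parameters, in any order).
    """

    def __init__(
        self,
        network: ReactionNetwork,
        space: ParameterSpace,
        experiments,
        constraints: ConstraintSet | None = None,
        sim_method: str = "auto",
    ):
        self.network = network
        self.space = space
        if isinstance(experiments, Experiment):
            experiments = [experiments]
        self.experiments = list(experiments)
        if not self.experiments:
            raise SpecificationError("at least one experiment is required")
        self.constraints = constraints or ConstraintSet()
        self.sim_method = sim_method
        missing = set(network.param_names) - set(space.names)
        if missing:
            raise SpecificationError(f"parameter space missing network parameters {sorted(missing)}")
        # per-experiment simulation grids (sorted unique observation times)
        # plus precomputed record -> (row, column) matching for fast reuse
        self._sim_times = []
        self._match = []
        sp_col = {sp: i for i, sp in enumerate(network.species)}
        for exp in self.experiments:
            times = np.unique(exp.likelihood.times)
            rows = np.searchsorted(times, exp.likelihood.times)
            try:
                cols = np.array([sp_col[sp] for sp in exp.likelihood.species])
            except KeyError as exc:
                raise SpecificationError(
                    f"observed species {exc.args[0]!r} not in the network"
                ) from None
            self._sim_times.append(times)
            self._match.append((rows, cols, exp.likelihood.means, exp.likelihood.sds))
        # rate-vector ordering: space order -> network reaction order
        self._net_order = np.array([space.index(p) for p in network.param_names])
        self._stacked_inputs = self._stackable()

    def _stackable(self):
        """Constant-stimulus experiments on one shared grid can be
        integrated as a single stacked ODE system (a several-fold saving
        in the sampler's hot loop).  Returns the (n_exp, n_inputs) input
        levels, or None when the experiments are not batchable."""
        if len(self.experiments) < 2 or not self.network.input_species:
            return None
        if self.network.is_conversion_only():
            return None  # exact linear path is already cheap
        t0 = self._sim_times[0]
        if any(len(t) != len(t0) or not np.array_equal(t, t0) for t in self._sim_times):
            return None
        t_end = t0[-1]
        levels = np.zeros((len(self.experiments), len(self.network.input_species)))
        for e, exp in enumerate(self.experiments):
            for i, sp in enumerate(self.network.input_species):
                segs = [s for s in exp.inputs if s.name == sp]
                if len(segs) != 1 or segs[0].start > 0.0 or segs[0].end < t_end:
                    return None
                levels[e, i] = segs[0].value
        return levels

    # -- pieces ----------------------------------------------------------
    def _values(self, theta: np.ndarray):
        k = 10.0 ** np.asarray(theta, dtype=float)[self._net_order]
        for exp, times in zip(self.experiments, self._sim_times):
            yield exp, simulate_values(
                self.network, k, times, exp.inputs, method=self.sim_method
            )

    def _trajectories(self, theta: np.ndarray):
        for (exp, values), times in zip(self._values(theta), self._sim_times):
            yield exp, Trajectory(times=times, values=values, species=tuple(self.network.species))

    def log_likelihood(self, theta: np.ndarray) -> float:
        """Summed log likelihood across experiments; -inf on simulation failure."""
        total = 0.0
        try:
            if self._stacked_inputs is not None and self.sim_method == "auto":
                k = 10.0 ** np.asarray(theta, dtype=float)[self._net_order]
                stacked = simulate_values_stacked(
                    self.network, k, self._sim_times[0], self._stacked_inputs
                )
                for values, (rows, cols, means, sds) in zip(stacked, self._match):
                    sims = values[rows, cols]
                    total += float(-np.sum((sims - means) ** 2 / (2.0 * sds**2)))
                return total
            for (exp, values), (rows, cols, means, sds) in zip(
                self._values(theta), self._match
            ):
                sims = values[rows, cols]
                total += float(-np.sum((sims - means) ** 2 / (2.0 * sds**2)))
        except SimulationFailure:
            return -np.inf
        return total

    def soft_penalty(self, theta: np.ndarray) -> float:
        if not self.constraints.soft:
            return 0.0
        trajs = [traj for _, traj in self._trajectories(theta)]
        return float(sum(sc.penalty(trajs[sc.experiment]) for sc in self.constraints.soft))

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.space.n_params,):
            raise SpecificationError(
                f"theta must have one entry per parameter ({self.space.n_params}), got shape {theta.shape}"
            )
        lp = self.space.log_prior(theta)
        if not np.isfinite(lp):
            return np.inf
        if self.constraints.hard:
            ok, _ = check_hard_constraints(self.space.theta_dict(theta), self.constraints)
            if not ok:
                return np.inf
        ll = self.log_likelihood(theta)
        if not np.isfinite(ll):
            return np.inf
        return -ll - lp + self.soft_penalty(theta)


def energy(theta, model: EnergyModel) -> float:
    """Functional form of :class:`EnergyModel`: ``E = -log L - log prior + soft``."""
    return model(theta)


# ---------------------------------------------------------------------------
# grouped Lasso
# ---------------------------------------------------------------------------

@dataclass
class GroupedSpec:
    """Hyperparameters of the grouped (module-level) Lasso.

    ``mu``/``b`` locate the shared Laplace prior on each module penalty
    parameter lambda'_m; ``lb``/``ub`` bound every reaction-specific
    parameter k'_i in an *open* interval (the boundary itself carries
    infinite penalty); ``lambda_bounds`` is the sampling box for the module
    parameters.  Defaults follow the module-selection study conditions:
    mu=-25, lb=-5, ub=10, so with lambda' at the prior location the largest
    effective log10 rate constant is about ub + mu = -15, far below any
    dynamically relevant value.
    """

    modules: dict  # module id -> list of reaction parameter names
    mu: float = -25.0
    b: float = 2.0
    lb: float = -5.0
    ub: float = 10.0
    lambda_bounds: tuple = (-30.0, 6.0)

    def __post_init__(self):
        if not self.b > 0:
            raise InvalidHyperparameterError(f"Laplace width b must be > 0, got {self.b}")
        if not self.lb < self.ub:
            raise SpecificationError("grouped lb must be < ub")
        for mod, params in self.modules.items():
            if not params:
                raise SpecificationError(f"module {mod!r} has no member reactions")


class GroupedEnergyModel:
    """Grouped-Lasso posterior energy.

    The sampled vector is ``[lambda'_m for each module] + [k'_i for each
    penalized reaction]``; the effective log10 rate constant passed to the
    simulator is ``theta'_i = k'_i + lambda'_{m(i)}``.

        E = -log L(theta') + sum_m |lambda'_m - mu| / b + sum_i f(k'_i),

    with f zero inside the open interval (lb, ub) and +inf otherwise.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        spec: GroupedSpec,
        experiments,
        constraints: ConstraintSet | None = None,
        sim_method: str = "auto",
    ):
        self.network = network
        self.spec = spec
        assigned = [p for params in spec.modules.values() for p in params]
        if sorted(assigned) != sorted(network.param_names):
            raise SpecificationError(
                "grouped modules must partition the network's reaction parameters"
            )
        self.module_ids = list(spec.modules)
        self.k_names = list(network.param_names)
        self._module_of = np.array(
            [self.module_ids.index(self._lookup(spec, p)) for p in self.k_names]
        )
        names = [f"lambda_{m}" for m in self.module_ids] + list(self.k_names)
        n_mod = len(self.module_ids)
        lower = np.concatenate(
            [np.full(n_mod, spec.lambda_bounds[0]), np.full(len(self.k_names), spec.lb)]
        )
        upper = np.concatenate(
            [np.full(n_mod, spec.lambda_bounds[1]), np.full(len(self.k_names), spec.ub)]
        )
        priors = [LaplacePrior(spec.mu, spec.b)] * n_mod + [UniformPrior()] * len(self.k_names)
        groups = {f"lambda_{m}": m for m in self.module_ids}
        for p, m in zip(self.k_names, self._module_of):
            groups[p] = self.module_ids[m]
        self.space = ParameterSpace(names, lower, upper, priors=priors, groups=groups)
        self.n_modules = n_mod
        # inner likelihood model over effective theta'; wide box, no priors
        inner_space = ParameterSpace(
            self.k_names,
            lower=np.full(len(self.k_names), -1e6),
            upper=np.full(len(self.k_names), 1e6),
        )
        self._inner = EnergyModel(
            network, inner_space, experiments, constraints=constraints, sim_method=sim_method
        )

    @staticmethod
    def _lookup(spec, param):
        for i, (mod, params) in enumerate(spec.modules.items()):
            if param in params:
                return mod
        raise SpecificationError(f"parameter {param!r} not assigned to a module")

    # -- composition -----------------------------------------------------
    def split(self, vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        return vector[: self.n_modules], vector[self.n_modules :]

    def effective_theta(self, vector: np.ndarray) -> np.ndarray:
        lam, k = self.split(vector)
        return k + lam[self._module_of]

    def log_likelihood(self, vector: np.ndarray) -> float:
        return self._inner.log_likelihood(self.effective_theta(vector))

    def penalty(self, vector: np.ndarray) -> float:
        lam, k = self.split(vector)
        if np.any(k <= self.spec.lb) or np.any(k >= self.spec.ub):
            return np.inf  # f(k') = +inf outside the open interval
        lo, hi = self.spec.lambda_bounds
        if np.any(lam < lo) or np.any(lam > hi):
            return np.inf
        return float(np.sum(np.abs(lam - self.spec.mu) / self.spec.b))

    def __call__(self, vector: np.ndarray) -> float:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.space.n_params,):
            raise SpecificationError(
                f"vector must have length {self.space.n_params}, got shape {vector.shape}"
            )
        pen = self.penalty(vector)
        if not np.isfinite(pen):
            return np.inf
        theta = self.effective_theta(vector)
        if self._inner.constraints.hard:
            ok, _ = check_hard_constraints(
                dict(zip(self.k_names, theta)), self._inner.constraints
            )
            if not ok:
                return np.inf
        ll = self._inner.log_likelihood(theta)
        if not np.isfinite(ll):
            return np.inf
        return -ll + pen + self._inner.soft_penalty(theta)

    @property
    def lambda_names(self):
        return [f"lambda_{m}" for m in self.module_ids]


def grouped_energy(lam: dict, k: dict, model: GroupedEnergyModel) -> float:
    """Grouped energy from named module penalties and reaction parameters."""
    vector = np.concatenate(
        [
            [lam[m] for m in model.module_ids],
            [k[p] for p in model.k_names],
        ]
    )
    return model(vector)
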