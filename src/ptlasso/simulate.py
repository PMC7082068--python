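"""Deterministic simulation of mass-action reaction networks.

Two integration paths share one contract:

* purely unimolecular conversion networks (linear ODE ``dx/dt = M(k) x``)
  are propagated exactly with matrix exponentials -- cheap and exact, which
  matters because the tempered chains evaluate the model tens of thousands
  of times per run;
* everything else goes through LSODA (stiff-capable, ``rtol=1e-6``,
  ``atol=1e-9``) via :func:`scipy.integrate.odeint`.

Piecewise-constant stimuli are handled by restarting the integration at
every schedule discontinuity: the input species is clamped to the segment
value and carries zero derivative inside a segment.  A non-finite state or
integrator failure raises :class:`~ptlasso.errors.SimulationFailure`, which
the sampler maps to infinite energy.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import ODEintWarning, odeint
from scipy.linalg import expm

from .errors import SimulationFailure, SpecificationError
from .networks import ReactionNetwork, Trajectory

__all__ = ["simulate", "RATE_FLOOR"]

#: Linear-space stand-in for a removed reaction.  A rate constant at (or
#: below) this value cannot affect the dynamics on the timescales of the
#: studies in this package; reactions are never removed structurally.
RATE_FLOOR = 1e-12

_NEG_TOL = 1e-9  # negative slop tolerated before clipping to zero


class _Compiled:
    """Cached structural arrays for fast right-hand-side evaluation."""

    __slots__ = ("exponents", "net", "input_idx", "linear_pairs", "grid_cache")

    def __init__(self, network: ReactionNetwork):
        n_sp = network.n_species
        n_rx = len(network.reactions)
        sp_idx = {sp: i for i, sp in enumerate(network.species)}
        self.exponents = np.zeros((n_rx, n_sp))
        net = np.zeros((n_sp, n_rx))
        for j, rxn in enumerate(network.reactions):
            for sp, coef in rxn.reactants.items():
                self.exponents[j, sp_idx[sp]] += coef
                net[sp_idx[sp], j] -= coef
            for sp, coef in rxn.products.items():
                net[sp_idx[sp], j] += coef
            for sp in rxn.modifiers:
                self.exponents[j, sp_idx[sp]] += 1
        self.input_idx = np.array([sp_idx[sp] for sp in network.input_species], dtype=int)
        net[self.input_idx, :] = 0.0  # clamped inputs have no dynamics
        self.net = net
        if network.is_conversion_only():
            self.linear_pairs = [
                (sp_idx[next(iter(r.reactants))], sp_idx[next(iter(r.products))])
                for r in network.reactions
            ]
        else:
            self.linear_pairs = None
        self.grid_cache = {}


def _compiled(network: ReactionNetwork) -> _Compiled:
    cache = getattr(network, "_compiled_cache", None)
    if cache is None:
        cache = _Compiled(network)
        network._compiled_cache = cache
    return cache


def _resolve_rates(network: ReactionNetwork, params: dict) -> np.ndarray:
    try:
        return np.array([float(params[name]) for name in network.param_names])
    except KeyError as exc:
        raise SpecificationError(f"missing rate constant for parameter {exc.args[0]!r}") from None


def _schedule_value(network: ReactionNetwork, inputs, name: str, t: float) -> float:
    for seg in inputs:
        if seg.name == name and seg.start <= t < seg.end:
            return seg.value
    return 0.0


def _simulate_linear(network, k, times, compiled) -> np.ndarray:
    """Exact propagation for conversion-only networks via expm steps."""
    n = network.n_species
    M = np.zeros((n, n))
    for (i, j), rate in zip(compiled.linear_pairs, k):
        M[i, i] -= rate
        M[j, i] += rate
    key = times.tobytes()
    cached = compiled.grid_cache.get(key)
    if cached is None:
        dts = np.diff(times, prepend=0.0)
        cached = np.unique(np.round(dts, 12), return_inverse=True)
        compiled.grid_cache[key] = cached
    uniq, inverse = cached
    propagators = [None if dt <= 0 else expm(M * dt) for dt in uniq]
    x = network.initial_vector()
    out = np.empty((len(times), n))
    for row, key in enumerate(inverse):
        P = propagators[key]
        if P is not None:
            x = P @ x
        out[row] = x
    return out


try:  # LSODA calls the RHS thousands of times per fit; JIT when available
    from numba import njit

    @njit(cache=True)
    def _mass_action_rhs(x, k, expo, net, n_exp, n_sp):
        n_rx = expo.shape[0]
        dx = np.zeros(n_exp * n_sp)
        for e in range(n_exp):
            off = e * n_sp
            for j in range(n_rx):
                r = k[j]
                for s in range(n_sp):
                    p = expo[j, s]
                    if p != 0.0:
                        xs = x[off + s]
                        if xs < 0.0:
                            xs = 0.0
                        if p == 1.0:
                            r *= xs
                        else:
                            r *= xs**p
                for s in range(n_sp):
                    c = net[s, j]
                    if c != 0.0:
                        dx[off + s] += c * r
        return dx

except ImportError:  # pragma: no cover - numba is a declared dependency

    def _mass_action_rhs(x, k, expo, net, n_exp, n_sp):
        xc = np.maximum(x, 0.0).reshape(n_exp, n_sp)
        rates = k * np.prod(xc[:, None, :] ** expo[None, :, :], axis=2)
        return (rates @ net.T).reshape(-1)


def _rhs(x, t, k, compiled):
    return _mass_action_rhs(x, k, compiled.exponents, compiled.net, 1, x.shape[0])


def _rhs_batch(x, t, k, compiled, n_exp, n_sp):
    return _mass_action_rhs(x, k, compiled.exponents, compiled.net, n_exp, n_sp)


def simulate_values_stacked(network, k, times, input_values, rtol=1e-6, atol=1e-9):
    """Integrate several constant-stimulus experiments as one stacked system.

    ``input_values`` is an (n_exp, n_inputs) array of clamped input levels,
    one row per experiment, held constant over the whole window.  All
    experiments share the time grid.  Returns values of shape
    (n_exp, n_times, n_species).  This exists because evaluating several
    dose experiments in one LSODA call is several-fold cheaper than looping.
    """
    compiled = _compiled(network)
    n_exp = len(input_values)
    n_sp = network.n_species
    x0 = np.tile(network.initial_vector(), (n_exp, 1))
    x0[:, compiled.input_idx] = input_values
    seg_times = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        sol, info = odeint(
            _rhs_batch,
            x0.reshape(-1),
            seg_times,
            args=(k, compiled, n_exp, n_sp),
            rtol=rtol,
            atol=atol,
            mxstep=3000,
            full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise SimulationFailure(f"LSODA failed on stacked system: {info['message']}")
    sol = sol.reshape(len(seg_times), n_exp, n_sp)
    if len(seg_times) != len(times):
        sol = sol[1:]
    values = np.swapaxes(sol, 0, 1)
    np.clip(values, 0.0, None, out=values)
    return values


def simulate(
    network: ReactionNetwork,
    params: dict,
    times,
    inputs=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "auto",
) -> Trajectory:
    """Integrate the mass-action ODEs and return abundances at ``times``.

    Parameters
    ----------
    params
        Map parameter name -> rate constant (linear space).  Every reaction
        parameter must be resolvable.
    times
        Strictly increasing grid with ``times[0] >= 0``.  Integration always
        starts from the initial state at t=0.
    inputs
        Optional stimulus schedule (list of StimulusSegment) overriding
        ``network.inputs``.  Input species are clamped piecewise-constant;
        outside any segment their value is 0.
    method
        ``"auto"`` uses the exact linear path when the network is
        conversion-only, else LSODA.  ``"ode"`` forces LSODA.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise SpecificationError("times must be a non-empty 1-D grid")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise SpecificationError("times must be strictly increasing with times[0] >= 0")
    k = _resolve_rates(network, params)
    if inputs is None:
        inputs = network.inputs
    try:
        values = simulate_values(network, k, times, inputs, rtol=rtol, atol=atol, method=method)
    except SimulationFailure as exc:
        raise SimulationFailure(str(exc), params) from None
    return Trajectory(times=times, values=values, species=tuple(network.species))


def simulate_values(
    network, k, times, inputs, rtol=1e-6, atol=1e-9, method="auto"
) -> np.ndarray:
    """Low-overhead core of :func:`simulate`: rate-constant *vector* in
    network reaction order, pre-validated time grid; returns the raw value
    array.  Used directly by the energy model's hot loop."""
    compiled = _compiled(network)
    if method == "auto" and compiled.linear_pairs is not None:
        values = _simulate_linear(network, k, times, compiled)
        if not np.all(np.isfinite(values)):
            raise SimulationFailure("non-finite state in linear propagation")
    else:
        values = _simulate_ode(network, k, times, inputs, compiled, rtol, atol, None)
    if np.min(values) < -_NEG_TOL * max(1.0, np.max(np.abs(values))):
        # more than integrator slop; still physical to clip, but flag loudly
        raise SimulationFailure("integration produced substantially negative abundances")
    if values.dtype != float:
        values = values.astype(float)
    np.clip(values, 0.0, None, out=values)
    return values


def _simulate_ode(network, k, times, inputs, compiled, rtol, atol, params):
    t_end = times[-1]
    edges = {0.0, float(t_end)}
    for seg in inputs:
        for edge in (seg.start, seg.end):
            if 0.0 < edge < t_end:
                edges.add(float(edge))
    edges = sorted(edges)

    x = network.initial_vector()
    out = np.empty((len(times), network.n_species))
    filled = 0
    if times[0] == 0.0:
        x0 = x.copy()
        for sp_i, sp in zip(compiled.input_idx, network.input_species):
            x0[sp_i] = _schedule_value(network, inputs, sp, 0.0)
        out[0] = x0
        filled = 1

    for a, b in zip(edges[:-1], edges[1:]):
        for sp_i, sp in zip(compiled.input_idx, network.input_species):
            x[sp_i] = _schedule_value(network, inputs, sp, a)
        inside = times[(times > a) & (times <= b)]
        seg_times = np.concatenate(([a], inside))
        if seg_times[-1] < b:
            seg_times = np.concatenate((seg_times, [b]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ODEintWarning)
            sol, info = odeint(
                _rhs,
                x,
                seg_times,
                args=(k, compiled),
                rtol=rtol,
                atol=atol,
                mxstep=3000,
                full_output=True,
            )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
            raise SimulationFailure(
                f"LSODA failed on segment [{a}, {b}]: {info['message']}", params
            )
        n_inside = len(inside)
        if n_inside:
            out[filled : filled + n_inside] = sol[1 : 1 + n_inside]
            filled += n_inside
        x = sol[-1]
    return out
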