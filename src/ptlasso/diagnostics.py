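"""Convergence diagnostics: PSRF, MPSRF, chain combining, acceptance rates.

The Potential Scale Reduction Factor compares within-chain and
between-chain variance of a scalar parameter across independently seeded
runs; values near 1 are consistent with convergence and values above a
threshold (1.2 by convention here) are not.  The classical non-split,
non-rank-normalized form is used:

    R^2 = (n - 1)/n + ((m + 1)/m) * B_n / W,

with W the mean within-chain variance and B_n the variance of the chain
means (m chains of length n).  The multivariate MPSRF replaces the variance
ratio with the largest eigenvalue of W^-1 B_n and bounds every univariate
PSRF from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, eigh

from .errors import DegenerateChainError, SpecificationError

__all__ = [
    "psrf",
    "mpsrf",
    "combine_chains",
    "CombineReport",
    "acceptance_report",
    "DiagnosticsReport",
    "diagnose",
    "PSRF_THRESHOLD",
]

PSRF_THRESHOLD = 1.2


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise SpecificationError("psrf expects m chains of equal length (2-D input)")
    m, n = arr.shape
    if m < 2 or n < 2:
        raise SpecificationError("psrf needs >= 2 chains of length >= 2")
    return arr


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor of a scalar parameter.

    ``chains``: m equal-length sequences (m >= 2).  Raises
    :class:`DegenerateChainError` when the within-chain variance vanishes.
    """
    arr = _as_chain_matrix(chains)
    m, n = arr.shape
    w = float(np.mean(np.var(arr, axis=1, ddof=1)))
    if w == 0.0:
        raise DegenerateChainError("constant chains: within-chain variance is zero")
    b_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    r2 = (n - 1) / n + ((m + 1) / m) * b_n / w
    return float(np.sqrt(r2))


def mpsrf(chains) -> float:
    """Brooks-Gelman multivariate PSRF.

    ``chains``: array-like of shape (m, n, p).  Uses the largest
    generalized eigenvalue of (B_n, W); raises
    :class:`DegenerateChainError` when W is singular.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise SpecificationError("mpsrf expects chains of shape (m, n, p)")
    m, n, p = arr.shape
    if m < 2 or n < 2:
        raise SpecificationError("mpsrf needs >= 2 chains of length >= 2")
    if p == 1:
        return psrf(arr[:, :, 0])
    w = np.zeros((p, p))
    for j in range(m):
        w += np.cov(arr[j], rowvar=False, ddof=1)
    w /= m
    means = arr.mean(axis=1)
    b_n = np.cov(means, rowvar=False, ddof=1)
    try:
        lam_max = float(eigh(b_n, w, eigvals_only=True)[-1])
    except LinAlgError as exc:
        raise DegenerateChainError(f"singular within-chain covariance: {exc}") from None
    r2 = (n - 1) / n + ((m + 1) / m) * lam_max
    return float(np.sqrt(r2))


# ---------------------------------------------------------------------------
# chain combining
# ---------------------------------------------------------------------------

@dataclass
class CombineReport:
    passed: bool
    energy_psrf: float | None
    message: str
    n_stores: int


def combine_chains(stores, threshold: float = PSRF_THRESHOLD):
    """Gate-and-concatenate M parallel runs started from one start point.

    Computes the univariate PSRF of the M lowest-temperature energy traces;
    below ``threshold`` the runs are assumed to sample the same energy
    basin and their posterior segments are concatenated into one store.
    Returns ``(combined_store_or_None, CombineReport)``; a single store
    passes through with a warning (no PSRF computable).
    """
    stores = list(stores)
    if not stores:
        raise SpecificationError("no stores to combine")
    if len(stores) == 1:
        return stores[0], CombineReport(
            passed=True,
            energy_psrf=None,
            message="single store: pass-through, PSRF not computable",
            n_stores=1,
        )
    lengths = {s.n_samples for s in stores}
    if len(lengths) > 1:
        raise SpecificationError(f"stores have unequal post-burn-in lengths {sorted(lengths)}")
    traces = np.stack([s.posterior_energies() for s in stores])
    value = psrf(traces)
    if value >= threshold:
        return None, CombineReport(
            passed=False,
            energy_psrf=value,
            message=f"energy PSRF {value:.4f} >= {threshold}: refusing to combine",
            n_stores=len(stores),
        )
    first = stores[0]
    from .sampler import SampleStore

    combined = SampleStore(
        param_names=list(first.param_names),
        betas=first.betas.copy(),
        thetas=np.concatenate([s.thetas[s.burn_in :] for s in stores], axis=0),
        energies=np.concatenate([s.energies[s.burn_in :] for s in stores], axis=0),
        burn_in=0,
        step_accepts=_sum_or_none([s.step_accepts for s in stores]),
        step_attempts=_sum_or_none([s.step_attempts for s in stores]),
        swap_accepts=_sum_or_none([s.swap_accepts for s in stores]),
        swap_attempts=_sum_or_none([s.swap_attempts for s in stores]),
        meta={"combined_from": len(stores), "energy_psrf": value},
    )
    return combined, CombineReport(
        passed=True,
        energy_psrf=value,
        message=f"energy PSRF {value:.4f} < {threshold}: combined {len(stores)} runs",
        n_stores=len(stores),
    )


def _sum_or_none(arrays):
    if any(a is None for a in arrays):
        return None
    return np.sum(arrays, axis=0)


# ---------------------------------------------------------------------------
# acceptance reporting
# ---------------------------------------------------------------------------

def acceptance_report(store) -> dict:
    """Step acceptance per chain and swap acceptance per adjacent pair.

    Rates with zero attempts are reported as None (undefined-rate flag).
    """
    def rates(accepts, attempts):
        if accepts is None or attempts is None:
            return None
        return [
            (int(a) / int(t)) if t > 0 else None for a, t in zip(accepts, attempts)
        ]

    return {
        "step_acceptance": rates(store.step_accepts, store.step_attempts),
        "swap_acceptance": rates(store.swap_accepts, store.swap_attempts),
    }


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    psrf_per_parameter: dict
    mpsrf: float
    max_psrf: float
    step_acceptance: list = field(default_factory=list)
    swap_acceptance: list = field(default_factory=list)
    threshold: float = PSRF_THRESHOLD
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "psrf_per_parameter": self.psrf_per_parameter,
            "mpsrf": self.mpsrf,
            "max_psrf": self.max_psrf,
            "step_acceptance": self.step_acceptance,
            "swap_acceptance": self.swap_acceptance,
            "threshold": self.threshold,
            "converged": self.converged,
        }


def diagnose(stores, threshold: float = PSRF_THRESHOLD) -> DiagnosticsReport:
    """Convergence report from >= 2 independently seeded runs.

    PSRF per parameter and MPSRF are computed from the lowest-temperature
    posterior samples of each run; ``converged`` is max PSRF < threshold.
    """
    stores = list(stores)
    if len(stores) < 2:
        raise SpecificationError("diagnose needs >= 2 independent runs")
    names = stores[0].param_names
    for s in stores[1:]:
        if list(s.param_names) != list(names):
            raise SpecificationError("stores have different parameter names")
    samples = np.stack([s.posterior() for s in stores])  # (m, n, p)
    per_param = {
        name: psrf(samples[:, :, j]) for j, name in enumerate(names)
    }
    max_psrf = max(per_param.values())
    return DiagnosticsReport(
        psrf_per_parameter=per_param,
        mpsrf=mpsrf(samples),
        max_psrf=max_psrf,
        step_acceptance=[acceptance_report(s)["step_acceptance"] for s in stores],
        swap_acceptance=[acceptance_report(s)["swap_acceptance"] for s in stores],
        threshold=threshold,
        converged=bool(max_psrf < threshold),
    )
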