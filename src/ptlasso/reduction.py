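"""Model-reduction calls from posterior samples.

A Laplace-penalized parameter whose marginal posterior stays confined
within the prior boundary interval ``[mu - c*b, mu + c*b]`` is *extraneous*
-- the data never pulled it away from the prior, so its reaction can be
dropped.  A parameter whose posterior escapes the interval is *necessary*.
With the default half-width ``c = 3`` the interval carries 1 - e^-3 (~95%)
of the Laplace prior mass, and a parameter is called extraneous when at
least ``mass_threshold`` (default 0.95) of its posterior mass lies inside.

Support extraction maps each posterior sample to the set of parameters
above an activity threshold in log10 space and tallies the distinct
supports; mutually exclusive supports reveal alternate reduced models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .energy import LaplacePrior
from .errors import SpecificationError

__all__ = [
    "ParameterCall",
    "ReductionReport",
    "SupportCluster",
    "classify_parameters",
    "extract_supports",
    "select_b",
    "sensitivity_mu",
    "marginal_mode",
]


@dataclass
class ParameterCall:
    name: str
    confinement: float | None
    classification: str  # "extraneous" | "necessary" | "skipped"
    boundary: tuple | None
    note: str = ""


@dataclass
class ReductionReport:
    calls: list
    c: float
    mass_threshold: float

    def classification(self, name: str) -> str:
        for call in self.calls:
            if call.name == name:
                return call.classification
        raise KeyError(name)

    @property
    def extraneous(self):
        return [c.name for c in self.calls if c.classification == "extraneous"]

    @property
    def necessary(self):
        return [c.name for c in self.calls if c.classification == "necessary"]

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "mass_threshold": self.mass_threshold,
            "calls": [
                {
                    "name": c.name,
                    "confinement": c.confinement,
                    "classification": c.classification,
                    "boundary": list(c.boundary) if c.boundary else None,
                    "note": c.note,
                }
                for c in self.calls
            ],
        }


def classify_parameters(
    samples: np.ndarray,
    names,
    priors,
    c: float = 3.0,
    mass_threshold: float = 0.95,
    mu_shift: float = 0.0,
    bounds=None,
) -> ReductionReport:
    """Extraneous/necessary calls by prior confinement.

    Parameters
    ----------
    samples : (n_samples, n_params) posterior log10 samples
    names : parameter names matching columns
    priors : per-parameter prior objects; only Laplace-penalized parameters
        are classified, others are skipped with a notice
    c : boundary half-width in units of the Laplace width b
    mass_threshold : posterior mass inside the boundary required to call a
        parameter extraneous
    mu_shift : added to every prior location before classifying (used by
        :func:`sensitivity_mu`)
    bounds : optional (lower, upper) per-parameter sampling bounds.  The
        boundary interval is intersected with the sampling box: a sample
        pressed against the box floor below mu - c*b is maximally shrunk,
        which is confinement, not escape.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise SpecificationError("samples must be a non-empty (n, p) array")
    if samples.shape[1] != len(names) or len(names) != len(priors):
        raise SpecificationError("names/priors must match sample columns")
    calls = []
    for j, (name, prior) in enumerate(zip(names, priors)):
        if not isinstance(prior, LaplacePrior):
            calls.append(
                ParameterCall(
                    name=name,
                    confinement=None,
                    classification="skipped",
                    boundary=None,
                    note="no Laplace prior on this parameter",
                )
            )
            continue
        mu = prior.mu + mu_shift
        lo, hi = mu - c * prior.b, mu + c * prior.b
        if bounds is not None:
            # a sample between the box floor and mu - c*b is maximally
            # shrunk (reaction off): only upward escape is meaningful
            box_lo = float(np.asarray(bounds[0]).reshape(-1)[j] if np.ndim(bounds[0]) else bounds[0])
            lo = min(lo, box_lo)
        frac = float(np.mean((samples[:, j] >= lo) & (samples[:, j] <= hi)))
        calls.append(
            ParameterCall(
                name=name,
                confinement=frac,
                classification="extraneous" if frac >= mass_threshold else "necessary",
                boundary=(lo, hi),
            )
        )
    return ReductionReport(calls=calls, c=c, mass_threshold=mass_threshold)


@dataclass
class SupportCluster:
    support: frozenset
    frequency: float
    count: int


def extract_supports(samples: np.ndarray, names, threshold: float):
    """Census of active-parameter sets across posterior samples.

    A parameter is active in a sample when its log10 value exceeds
    ``threshold`` (chosen between the prior location and the smallest
    plausible true value; with mu = -10 and data-informed values near 0,
    the midpoint -5 is the usual default).  Returns clusters sorted by
    frequency, frequencies summing to 1.
    """
    samples = np.asarray(samples, dtype=float)
    active = samples > threshold
    counts: dict = {}
    for row in active:
        key = frozenset(np.compress(row, names))
        counts[key] = counts.get(key, 0) + 1
    n = samples.shape[0]
    clusters = [
        SupportCluster(support=k, frequency=v / n, count=v) for k, v in counts.items()
    ]
    clusters.sort(key=lambda cl: (-cl.count, sorted(cl.support)))
    return clusters


@dataclass
class BSelection:
    b: float
    qualified: bool
    reference_mean: float
    tolerance: float
    mean_nll: dict


def select_b(
    b_grid,
    mean_nll,
    reference_mean: float,
    reference_sd: float,
    tolerance: float | None = None,
) -> BSelection:
    """Elbow rule for the Lasso width b.

    Returns the smallest b (strongest regularization) whose mean negative
    log likelihood does not exceed the unregularized reference mean by more
    than ``tolerance`` (default: one reference sd).  Degrades to the
    largest b with ``qualified=False`` when none qualifies.
    """
    b_grid = list(b_grid)
    if not b_grid:
        raise SpecificationError("empty b grid")
    if sorted(b_grid) != b_grid:
        raise SpecificationError("b grid must be sorted ascending")
    mean_nll = list(mean_nll)
    if len(mean_nll) != len(b_grid):
        raise SpecificationError("one mean NLL per grid point required")
    tol = float(reference_sd) if tolerance is None else float(tolerance)
    cutoff = reference_mean + tol
    for b, nll in zip(b_grid, mean_nll):
        if nll <= cutoff:
            return BSelection(
                b=b,
                qualified=True,
                reference_mean=reference_mean,
                tolerance=tol,
                mean_nll=dict(zip(b_grid, mean_nll)),
            )
    return BSelection(
        b=b_grid[-1],
        qualified=False,
        reference_mean=reference_mean,
        tolerance=tol,
        mean_nll=dict(zip(b_grid, mean_nll)),
    )


@dataclass
class MuSensitivity:
    delta: float
    stable: bool
    flipped: list
    reports: dict


def sensitivity_mu(
    samples,
    names,
    priors,
    delta: float = 1.0,
    c: float = 3.0,
    mass_threshold: float = 0.95,
    bounds=None,
) -> MuSensitivity:
    """Stability of extraneous/necessary calls under prior-location shifts.

    Re-runs the confinement classification with every Laplace location
    shifted by -delta, 0 and +delta and reports parameters whose call
    changes.  delta = 0 trivially reproduces the base classification.
    """
    reports = {
        shift: classify_parameters(
            samples, names, priors, c=c, mass_threshold=mass_threshold,
            mu_shift=shift, bounds=bounds,
        )
        for shift in (-delta, 0.0, delta)
    }
    base = reports[0.0]
    flipped = []
    for call in base.calls:
        if call.classification == "skipped":
            continue
        for shift in (-delta, delta):
            if reports[shift].classification(call.name) != call.classification:
                flipped.append(call.name)
                break
    return MuSensitivity(
        delta=delta, stable=not flipped, flipped=flipped, reports=reports
    )


def marginal_mode(samples_1d: np.ndarray, grid_size: int = 2001) -> float:
    """Location of the dominant mode of a 1-D marginal posterior.

    Gaussian KDE evaluated on a fine grid spanning the samples; returns the
    grid point of maximum density.  Degenerate (constant) samples return
    that constant.
    """
    x = np.asarray(samples_1d, dtype=float)
    if x.size == 0:
        raise SpecificationError("no samples")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])
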