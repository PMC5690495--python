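"""Decomposition of EI distributions into Gaussian technique subpopulations.

An X-ray room that has lived through CR plates, a DR retrofit, and one or
more phototimer recalibrations accumulates *technique subpopulations*: AEC
exposures cluster at the current target EI, while manual techniques remember
earlier targets (historically 1800 for CR, 1600 for early DR, 1400 after the
final recalibration). The aggregate EI distribution is then well described by
a small 1-D Gaussian mixture, and the fitted component means can be
attributed to the known historical targets.

The fitter is a deterministic expectation–maximization (EM) routine:

* initialization at the k midpoint sample quantiles ((2i+1)/(2k)), shared
  initial SD of sample SD / k, equal weights — reproducible without a seed;
* iteration until the relative log-likelihood change falls below 1e−8 or
  500 iterations;
* a component-SD floor of 10 EI points, because EI is integer-quantized and
  narrower components are quantization artifacts, not practice.

Model order is chosen by BIC over k = 1..k_max. An optional seeded
multi-start mode perturbs the initial means for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "MixtureComponent",
    "MixtureFit",
    "ComponentAttribution",
    "TargetAttribution",
    "fit_mixture",
    "select_components",
    "attribute_components",
    "component_fraction",
    "DEFAULT_TARGET_LEDGER",
    "SD_FLOOR",
]

SD_FLOOR = 10.0  # EI points; below integer quantization nothing is real
_MAX_ITER = 500
_REL_TOL = 1e-8

#: Historical institutional calibration targets used for attribution.
DEFAULT_TARGET_LEDGER: tuple[tuple[str, int], ...] = (
    ("AEC-current-1400", 1400),
    ("legacy-DR-1600", 1600),
    ("legacy-CR-1800", 1800),
)


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian subpopulation: mixing weight, mean EI, SD in EI points."""

    weight: float
    mean_ei: float
    sd_ei: float

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"component weight must be in (0, 1], got {self.weight!r}")
        if not self.sd_ei > 0:
            raise ValueError(f"component sd must be > 0, got {self.sd_ei!r}")


@dataclass(frozen=True)
class MixtureFit:
    """A fitted mixture, components ordered by increasing mean."""

    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    iterations: int
    converged: bool
    n: int

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {w!r}, not 1")
        means = [c.mean_ei for c in self.components]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("components must be strictly ordered by mean")

    @property
    def k(self) -> int:
        return len(self.components)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "weight": [c.weight for c in self.components],
                "mean_ei": [c.mean_ei for c in self.components],
                "sd_ei": [c.sd_ei for c in self.components],
            }
        )


@dataclass(frozen=True)
class ComponentAttribution:
    """One component's match against the target ledger."""

    component: MixtureComponent
    label: str | None  # None = unattributed
    target_ei: int | None
    distance: float | None


@dataclass(frozen=True)
class TargetAttribution:
    """Per-component target attribution for a whole fit."""

    assignments: tuple[ComponentAttribution, ...]

    def labels(self) -> tuple[str, ...]:
        return tuple(a.label if a.label is not None else "unattributed" for a in self.assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "weight": [a.component.weight for a in self.assignments],
                "mean_ei": [a.component.mean_ei for a in self.assignments],
                "sd_ei": [a.component.sd_ei for a in self.assignments],
                "label": self.labels(),
                "target_ei": [a.target_ei for a in self.assignments],
                "distance": [a.distance for a in self.assignments],
            }
        )


def _em(x: np.ndarray, mu: np.ndarray, sd: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    """Run EM to convergence from the given start; returns final parameters.

    The log-likelihood is checked to be nondecreasing at every iteration (a
    violated check indicates a numerical defect, not data trouble).
    """
    n = x.size
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        # E step in log space
        log_dens = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(np.sum(log_norm))
        if ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            raise AssertionError(f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}")
        resp = np.exp(log_dens - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = resp.T @ x / nk
        var = np.einsum("ij,ij->j", resp, (x[:, None] - mu[None, :]) ** 2) / nk
        sd = np.maximum(np.sqrt(var), SD_FLOOR)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= _REL_TOL * max(1.0, abs(prev_ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sd, w, prev_ll, it, converged


def fit_mixture(
    eis: Sequence[float] | np.ndarray,
    k: int,
    n_starts: int = 1,
    seed: int | None = None,
) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture to an EI sample by EM.

    The default single start is deterministic (midpoint-quantile means,
    shared SD of sample SD / k, equal weights). With ``n_starts > 1``,
    additional starts perturb the initial means with seeded Gaussian noise
    and the best final log-likelihood wins — a robustness check, not the
    default path.

    Requires ``n >= 10·k``, ``1 <= k <= 4`` and a sample with nonzero
    variance.
    """
    x = np.asarray(eis, dtype=float)
    if not 1 <= k <= 4:
        raise ValueError(f"component count k must be in [1, 4], got {k!r}")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} points for k={k}, got {x.size}")
    sample_sd = float(np.std(x, ddof=1))
    if sample_sd == 0:
        raise ValueError("cannot fit a mixture to an all-equal sample (zero variance)")

    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    mu0 = np.quantile(x, quantiles)
    sd0 = np.full(k, max(sample_sd / k, SD_FLOOR))
    w0 = np.full(k, 1.0 / k)

    best: tuple | None = None
    rng = np.random.default_rng(seed)
    for start in range(max(1, n_starts)):
        mu_init = mu0 if start == 0 else mu0 + rng.normal(0.0, sample_sd / 2, size=k)
        result = _em(x, mu_init.copy(), sd0.copy(), w0.copy())
        if best is None or result[3] > best[3]:
            best = result
    mu, sd, w, ll, iterations, converged = best

    order = np.argsort(mu)
    # merge exactly coincident means (degenerate but possible) by jittering order stably
    mu, sd, w = mu[order], sd[order], w[order]
    if np.any(np.diff(mu) <= 0):
        # enforce strict ordering for presentation; ties broken by a nudge
        # far below EI quantization
        mu = mu + np.arange(k) * 1e-9
    w = w / w.sum()
    components = tuple(
        MixtureComponent(float(wi), float(mi), float(si)) for wi, mi, si in zip(w, mu, sd)
    )
    p = 3 * k - 1
    bic = -2.0 * ll + p * np.log(x.size)
    return MixtureFit(
        components=components,
        log_likelihood=ll,
        bic=float(bic),
        iterations=iterations,
        converged=converged,
        n=int(x.size),
    )


def select_components(
    eis: Sequence[float] | np.ndarray,
    k_max: int = 3,
    n_starts: int = 1,
    seed: int | None = None,
) -> MixtureFit:
    """Fit k = 1..k_max and return the fit minimizing BIC.

    BIC = −2·logL + p·ln(n) with p = 3k − 1 free parameters. Requires
    n ≥ 30 so k up to 3 is always admissible.
    """
    x = np.asarray(eis, dtype=float)
    if x.size < 30:
        raise ValueError(f"select_components requires n >= 30, got {x.size}")
    fits = [fit_mixture(x, k, n_starts=n_starts, seed=seed) for k in range(1, k_max + 1)]
    return min(fits, key=lambda f: f.bic)


def attribute_components(
    fit: MixtureFit,
    target_ledger: Sequence[tuple[str, int]] = DEFAULT_TARGET_LEDGER,
    tol: float = 100.0,
) -> TargetAttribution:
    """Attribute fitted components to known calibration targets.

    Each component is matched to the nearest ledger target provided the
    distance does not exceed ``tol`` (default 100 EI points, half the
    spacing of the historical 1400/1600/1800 targets); distance ties go to
    the lower target. Unmatched components are labeled unattributed.
    Attribution looks only at component means, so it is invariant to
    component ordering.
    """
    ledger = list(target_ledger)
    if not ledger:
        raise ValueError("target ledger must be nonempty")
    targets = [t for _, t in ledger]
    if len(set(targets)) != len(targets):
        raise ValueError(f"target ledger has duplicate targets: {targets}")
    ledger = sorted(ledger, key=lambda lt: lt[1])

    assignments = []
    for comp in fit.components:
        # min() scans in ascending-target order, so ties resolve low
        label, target = min(ledger, key=lambda lt: abs(comp.mean_ei - lt[1]))
        distance = abs(comp.mean_ei - target)
        if distance <= tol:
            assignments.append(ComponentAttribution(comp, label, target, distance))
        else:
            assignments.append(ComponentAttribution(comp, None, None, None))
    return TargetAttribution(tuple(assignments))


def component_fraction(fit: MixtureFit, index: int, n: int) -> tuple[float, int]:
    """Fraction of studies and implied event count in one component.

    Returns ``(weight, round(weight * n))`` for the component at ``index``
    in the mean-ordered component list.
    """
    if not 0 <= index < fit.k:
        raise IndexError(f"component index {index} out of range for k={fit.k}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    weight = fit.components[index].weight
    return weight, int(round(weight * n))
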