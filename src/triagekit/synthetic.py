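"""Gaussian-mixture generators with analytically known posteriors and risks.

Every property of the triage machinery is checked against models where the
truth is computable: one-dimensional finite Gaussian mixtures, for which the
posterior p(a_k | x), the Bayes risk, and the population triage risk at any
refusal budget epsilon are available in closed or quadrature-exact form.
Sampling is fully seeded; `corrupt_scores` turns exact posteriors into
M-consistent "soft-max-like" scores by applying a monotone transform (and
optional logit noise), emulating an upstream classifier whose scores track a
monotone function of the truth without equaling it.

One dimension is deliberate: the max-posterior is a piecewise-smooth function
of a scalar, so decision regions are unions of intervals whose probability
is an exact difference of normal CDFs, and quadrature is fast and tight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .core import CondProbMatrix
from .softmax import ScoreMatrix

__all__ = [
    "GaussianMixtureModel",
    "SyntheticSample",
    "sample",
    "exact_bayes_risk",
    "exact_triage_risk",
    "corrupt_scores",
    "two_class_symmetric",
    "three_class_default",
]

#: integration support in pooled standard deviations beyond the extreme means
_SUPPORT_SDS = 10.0
#: grid resolution used to bracket roots/kinks before brentq refinement
_GRID_POINTS = 4001
#: bisection tolerance on the population threshold b
_B_TOL = 1e-10


@dataclass(frozen=True)
class GaussianMixtureModel:
    """1-D finite Gaussian mixture: class priors, means and scales.

    The joint density is sum_k pi_k N(x; mu_k, sigma_k^2); the posterior
    p(a_k | x) = pi_k phi_k(x) / f(x) is exact, which is the whole point.
    """

    priors: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        priors = np.asarray(self.priors, dtype=float)
        means = np.asarray(self.means, dtype=float)
        sigmas = np.broadcast_to(
            np.asarray(self.sigmas, dtype=float), means.shape
        ).copy()
        if priors.ndim != 1 or priors.shape != means.shape:
            raise ValueError("priors and means must be 1-D and equally long")
        if priors.shape[0] < 2:
            raise ValueError("need at least two classes")
        if np.any(priors < 0) or not np.isclose(priors.sum(), 1.0, atol=1e-12):
            raise ValueError("priors must be non-negative and sum to 1")
        if np.any(sigmas <= 0):
            raise ValueError("sigmas must be positive")
        labels = (
            [f"a_{k + 1}" for k in range(priors.shape[0])]
            if self.labels is None
            else [str(lab) for lab in self.labels]
        )
        if len(labels) != priors.shape[0]:
            raise ValueError("one label per class required")
        object.__setattr__(self, "priors", priors)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sigmas", sigmas)
        object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        return self.priors.shape[0]

    def support(self) -> tuple[float, float]:
        """Interval holding all but a negligible sliver of the mass."""
        lo = float(np.min(self.means - _SUPPORT_SDS * self.sigmas))
        hi = float(np.max(self.means + _SUPPORT_SDS * self.sigmas))
        return lo, hi

    def joint(self, x: np.ndarray) -> np.ndarray:
        """p(a_k, x) = pi_k N(x; mu_k, sigma_k), shape (len(x), m)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.priors * stats.norm.pdf(
            x[:, None], loc=self.means, scale=self.sigmas
        )

    def density(self, x: np.ndarray) -> np.ndarray:
        return self.joint(x).sum(axis=1)

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Exact conditional class probabilities p(a_k | x), row-stochastic."""
        joint = self.joint(x)
        return joint / joint.sum(axis=1, keepdims=True)

    def max_posterior(self, x: np.ndarray) -> np.ndarray:
        return self.posterior(x).max(axis=1)

    def interval_mass(self, lo: float, hi: float) -> float:
        """P[lo < X <= hi] from the exact mixture CDF."""
        upper = self.priors * stats.norm.cdf(hi, self.means, self.sigmas)
        lower = self.priors * stats.norm.cdf(lo, self.means, self.sigmas)
        return float((upper - lower).sum())


@dataclass(frozen=True)
class SyntheticSample:
    """An i.i.d. draw (features, labels) with the exact posterior matrix."""

    features: np.ndarray
    true_labels: np.ndarray
    probs: CondProbMatrix
    seed: int


def sample(model: GaussianMixtureModel, n: int, seed: int) -> SyntheticSample:
    """Draw n labeled points; attach the exact posterior at each feature."""
    if n < 1:
        raise ValueError(f"n={n!r} must be >= 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(model.n_classes, size=n, p=model.priors)
    features = rng.normal(model.means[classes], model.sigmas[classes])
    probs = CondProbMatrix(
        values=model.posterior(features), labels=list(model.labels)
    )
    labels_arr = np.asarray(model.labels, dtype=object)
    return SyntheticSample(
        features=features,
        true_labels=labels_arr[classes],
        probs=probs,
        seed=seed,
    )


def _kink_points(model: GaussianMixtureModel) -> np.ndarray:
    """Feature values where the winning class changes (max-posterior kinks)."""
    lo, hi = model.support()
    grid = np.linspace(lo, hi, _GRID_POINTS)
    winner = np.argmax(model.posterior(grid), axis=1)
    switches = np.nonzero(np.diff(winner))[0]
    points = []
    for i in switches:
        a, b = winner[i], winner[i + 1]

        def diff(x: float, a: int = a, b: int = b) -> float:
            j = model.joint(np.array([x]))[0]
            return j[a] - j[b]

        xl, xr = grid[i], grid[i + 1]
        if diff(xl) * diff(xr) <= 0:
            points.append(float(optimize.brentq(diff, xl, xr, xtol=1e-12)))
        else:  # crossing through a third class; the midpoint is close enough
            points.append(float(0.5 * (xl + xr)))
    return np.asarray(points)


def _integrate_piecewise(
    fun: Callable[[float], float],
    lo: float,
    hi: float,
    breaks: np.ndarray,
) -> float:
    """Adaptive quadrature split at interior kink locations."""
    cuts = np.concatenate(
        [[lo], np.sort(breaks[(breaks > lo) & (breaks < hi)]), [hi]]
    )
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        val, _ = integrate.quad(fun, a, b, epsabs=1e-12, epsrel=1e-10, limit=200)
        total += val
    return total


def exact_bayes_risk(model: GaussianMixtureModel) -> float:
    """P[Bayes label != Y]: one minus the integrated winning joint density."""
    lo, hi = model.support()
    kinks = _kink_points(model)

    def winning_joint(x: float) -> float:
        return float(model.joint(np.array([x]))[0].max())

    return 1.0 - _integrate_piecewise(winning_joint, lo, hi, kinks)


def _decision_intervals(
    model: GaussianMixtureModel, b: float
) -> list[tuple[float, float]]:
    """Intervals where max_k p(a_k | x) > b, by bracketed root refinement."""
    lo, hi = model.support()
    grid = np.linspace(lo, hi, _GRID_POINTS)
    above = model.max_posterior(grid) > b
    edges: list[float] = []
    for i in np.nonzero(np.diff(above))[0]:

        def diff(x: float) -> float:
            return float(model.max_posterior(np.array([x]))[0]) - b

        edges.append(float(optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-13)))
    bounds = [lo] + edges + [hi] if above[0] else edges + [hi]
    if not above[-1]:
        bounds = bounds[:-1]
    if len(bounds) % 2:  # pragma: no cover - defensive; parity is structural
        raise RuntimeError("unpaired decision-region boundary")
    return [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]


def _coverage(model: GaussianMixtureModel, b: float) -> float:
    return sum(model.interval_mass(a, c) for a, c in _decision_intervals(model, b))


def exact_triage_risk(
    model: GaussianMixtureModel, epsilon: float
) -> tuple[float, float, float]:
    """Population threshold, joint loss and coverage at refusal budget epsilon.

    Solves P[max_k p(a_k | X) > b] >= 1 - epsilon for the largest feasible b
    by bisection (the coverage is non-increasing in b, possibly with flat
    stretches; bisection then lands on the largest feasible value), and
    integrates the joint loss — density minus winning joint density — over
    the resulting decision region.

    Returns ``(threshold_b, joint_loss, coverage)``.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(
            f"epsilon={epsilon!r} must lie in [0, 1): refusing everything "
            "leaves no population decision region to characterize"
        )
    target = 1.0 - epsilon
    b_lo, b_hi = 0.0, 1.0  # coverage(0) = 1 >= target; coverage(1) = 0 < target
    while b_hi - b_lo > _B_TOL:
        mid = 0.5 * (b_lo + b_hi)
        if _coverage(model, mid) >= target:
            b_lo = mid
        else:
            b_hi = mid
    b = b_lo
    intervals = _decision_intervals(model, b)
    coverage = sum(model.interval_mass(a, c) for a, c in intervals)
    kinks = _kink_points(model)

    def local_loss(x: float) -> float:
        j = model.joint(np.array([x]))[0]
        return float(j.sum() - j.max())

    joint_loss = sum(
        _integrate_piecewise(local_loss, a, c, kinks) for a, c in intervals
    )
    return b, joint_loss, coverage


_TransformSpec = str | tuple[str, float] | Callable[[np.ndarray], np.ndarray]


def _resolve_transform(transform: _TransformSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone increasing map on [0, 1]; the shipped catalogue or a callable.

    Catalogue: ``"identity"``; ``("power", gamma)`` with gamma > 0, i.e.
    p -> p**gamma; ``("temperature", T)`` with T > 0, the temperature-scaled
    soft-max p -> p**(1/T) (renormalization happens downstream).  A callable
    is spot-checked for monotonicity and non-negativity on a grid.
    """
    if transform == "identity":
        return lambda p: p
    if isinstance(transform, tuple) and len(transform) == 2:
        name, param = transform
        if name == "power":
            if param <= 0:
                raise ValueError("power transform needs gamma > 0")
            return lambda p, g=float(param): p**g
        if name == "temperature":
            if param <= 0:
                raise ValueError("temperature transform needs T > 0")
            return lambda p, t=float(param): p ** (1.0 / t)
        raise ValueError(f"unknown transform {name!r}")
    if callable(transform):
        grid = np.linspace(0.0, 1.0, 513)
        vals = np.asarray(transform(grid), dtype=float)
        if np.any(np.diff(vals) <= 0):
            raise ValueError("transform must be strictly increasing on [0, 1]")
        if np.any(vals < 0):
            raise ValueError("transform must be non-negative on [0, 1]")
        return transform
    raise ValueError(f"unrecognized transform spec {transform!r}")


def corrupt_scores(
    sample: SyntheticSample,
    transform: _TransformSpec = "identity",
    noise_level: float = 0.0,
    seed: int | None = None,
) -> ScoreMatrix:
    """Turn exact posteriors into M-consistent estimated scores.

    Applies a monotone increasing transform phi entrywise to the posterior
    rows, renormalizes each row to sum to 1, and optionally perturbs on the
    logit scale with seeded Gaussian noise.  At noise 0 the per-row class
    ranking is always preserved (phi is increasing); the across-row ranking
    of the row maxima — what the triage threshold acts on — survives
    renormalization for two-class rows and for the identity, but can break
    for m > 2 under aggressive transforms, in which case a warning reports it.
    """
    phi = _resolve_transform(transform)
    exact = sample.probs.values
    raw = phi(exact)
    if np.any(raw.sum(axis=1) <= 0):
        raise ValueError("transform collapsed a posterior row to zero mass")
    values = raw / raw.sum(axis=1, keepdims=True)

    if noise_level == 0.0:
        before = exact.max(axis=1)
        after = values.max(axis=1)
        # rank agreement of row maxima, ignoring exact ties
        order = np.argsort(before, kind="stable")
        reordered = after[order]
        if np.any(np.diff(reordered) < -1e-12):
            warnings.warn(
                "renormalization of the transformed scores does not preserve "
                "the across-row ranking of row maxima; threshold-based triage "
                "on these scores may disagree with the oracle rule",
                stacklevel=2,
            )
    else:
        if noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        rng = np.random.default_rng(seed)
        logits = np.log(np.clip(values, 1e-300, None))
        logits = logits + rng.normal(0.0, noise_level, size=logits.shape)
        shifted = np.exp(logits - logits.max(axis=1, keepdims=True))
        values = shifted / shifted.sum(axis=1, keepdims=True)

    return ScoreMatrix(values=values, labels=list(sample.probs.labels))


def two_class_symmetric(
    mu: float = 1.0, sigma: float = 1.0
) -> GaussianMixtureModel:
    """Equal-prior classes at -mu and +mu: Bayes risk Phi(-mu/sigma) exactly."""
    return GaussianMixtureModel(
        priors=np.array([0.5, 0.5]),
        means=np.array([-mu, mu]),
        sigmas=np.array([sigma, sigma]),
    )


def three_class_default() -> GaussianMixtureModel:
    """Mildly unbalanced three-class mixture used as the default m > 2 oracle."""
    return GaussianMixtureModel(
        priors=np.array([0.3, 0.45, 0.25]),
        means=np.array([-2.0, 0.0, 2.5]),
        sigmas=np.array([1.0, 0.9, 1.2]),
    )
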