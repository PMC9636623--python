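"""Effect sizes and random-effects machinery.

Implements the pieces of a standard inverse-variance meta-analysis needed
to contrast two estimates of the same between-group effect:

* the between-group mean difference (MD) with its sampling variance
  ``sd_A^2/n_A + sd_B^2/n_B`` and Wald 95% confidence interval;
* restricted maximum likelihood (REML) estimation of the between-estimate
  variance tau^2;
* the random-effects fit itself: inverse-variance weights proportional to
  ``1/(v_i + tau^2)`` and the weighted pooled mean.

The REML objective is the profiled restricted log-likelihood

    ll(tau^2) = -1/2 sum log(v_i + tau^2) - 1/2 log sum w_i
                - 1/2 sum w_i (y_i - mu_hat)^2,   w_i = 1/(v_i + tau^2),

maximised over tau^2 >= 0 by bounded scalar optimisation, with truncation
at the zero boundary.  With only two estimates -- the typical case here,
one MD per scale of an analysis pair -- tau^2 is frequently truncated to
zero, and the weights then reduce to fixed-effect inverse-variance
weights.

Crossover trials are treated exactly like parallel trials: each arm
contributes its own n/mean/SD and the within-participant correlation is
ignored.  This leaves the MD untouched but makes its variance (and hence
the CI and weight) that of a parallel design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .scales import ArmSummary, ScaleDefinition

__all__ = [
    "EffectEstimate",
    "RandomEffectsFit",
    "md_estimate",
    "reml_tau2",
    "random_effects_fit",
    "inverse_variance_weights",
    "restricted_loglik",
]

#: Normal quantile for a two-sided 95% interval.
Z_95 = float(norm.ppf(0.975))

#: Upper bound for the tau^2 search, generous for effects on a 0-100 scale.
TAU2_MAX = 1.0e4


class DegenerateVarianceError(ValueError):
    """An arm with SD = 0 gives the MD no sampling variance."""


class InvalidPairingError(ValueError):
    """Arms from different trial/comparison/timepoint keys were paired."""


@dataclass(frozen=True)
class EffectEstimate:
    """A between-group mean difference on a common scale.

    ``md`` is mean(A) - mean(B); for placebo-controlled comparisons A is
    the treatment arm and B the placebo arm.
    """

    md: float
    variance: float
    ci_lower: float
    ci_upper: float
    scale: ScaleDefinition
    trial_id: str
    comparison_id: str
    timepoint: str

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class RandomEffectsFit:
    """Result of a random-effects fit: tau^2, pooled mean, weights."""

    tau2: float
    mu: float
    weights: np.ndarray  # proportions summing to 1

    @property
    def weights_pct(self) -> np.ndarray:
        return self.weights * 100.0


def md_estimate(
    arm_a: ArmSummary,
    arm_b: ArmSummary,
    rescale_to: ScaleDefinition,
    *,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Between-group MD of two arms, expressed on ``rescale_to``.

    Both arms are first rescaled to the target scale, then
    ``md = mean_A - mean_B`` with variance ``sd_A^2/n_A + sd_B^2/n_B`` and
    a Wald interval ``md +/- z * sqrt(variance)``.  Crossover arms are
    handled identically to parallel arms.

    Raises
    ------
    InvalidPairingError
        If the arms do not share trial/comparison/timepoint keys or are
        not on the same source scale.
    DegenerateVarianceError
        If either arm has SD = 0.
    """
    keys_a = (arm_a.trial_id, arm_a.comparison_id, arm_a.timepoint)
    keys_b = (arm_b.trial_id, arm_b.comparison_id, arm_b.timepoint)
    if keys_a != keys_b:
        raise InvalidPairingError(
            f"cannot pair arms from {keys_a} and {keys_b}"
        )
    if arm_a.scale != arm_b.scale:
        raise InvalidPairingError(
            f"arms measured on different scales ({arm_a.scale.name} vs "
            f"{arm_b.scale.name}); pair arms within one scale"
        )
    if arm_a.sd == 0.0 or arm_b.sd == 0.0:
        raise DegenerateVarianceError(
            f"{arm_a.trial_id}/{arm_a.comparison_id}/{arm_a.timepoint} on "
            f"{arm_a.scale.name}: SD of 0 leaves the mean difference "
            "without a sampling variance"
        )
    a = arm_a.rescaled(rescale_to)
    b = arm_b.rescaled(rescale_to)
    md = a.mean - b.mean
    variance = a.sd**2 / a.n + b.sd**2 / b.n
    z = float(norm.ppf(0.5 + ci_level / 2.0))
    half = z * float(np.sqrt(variance))
    return EffectEstimate(
        md=md,
        variance=variance,
        ci_lower=md - half,
        ci_upper=md + half,
        scale=arm_a.scale,
        trial_id=arm_a.trial_id,
        comparison_id=arm_a.comparison_id,
        timepoint=arm_a.timepoint,
    )


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Profiled restricted log-likelihood of the random-effects model."""
    w = 1.0 / (v + tau2)
    sw = w.sum()
    mu = (w * y).sum() / sw
    return float(
        -0.5 * np.log(v + tau2).sum()
        - 0.5 * np.log(sw)
        - 0.5 * (w * (y - mu) ** 2).sum()
    )


def _grid_tau2(y: np.ndarray, v: np.ndarray, hi: float, step: float = 1e-4) -> float:
    taus = np.arange(0.0, hi + step, step)
    vt = v[None, :] + taus[:, None]
    w = 1.0 / vt
    sw = w.sum(axis=1)
    mu = (w * y[None, :]).sum(axis=1) / sw
    ll = (
        -0.5 * np.log(vt).sum(axis=1)
        - 0.5 * np.log(sw)
        - 0.5 * (w * (y[None, :] - mu[:, None]) ** 2).sum(axis=1)
    )
    return float(taus[int(ll.argmax())])


def reml_tau2(
    estimates: list[tuple[float, float]] | np.ndarray,
    *,
    tau2_max: float = TAU2_MAX,
    tol: float = 1e-8,
) -> float:
    """REML estimate of the between-estimate variance tau^2.

    Parameters
    ----------
    estimates
        Sequence of ``(effect, sampling_variance)`` pairs; at least two,
        all variances strictly positive.
    tau2_max
        Upper bound of the search interval.
    tol
        Convergence tolerance of the bounded optimiser.

    Returns
    -------
    tau^2 >= 0, truncated at the zero boundary when the unconstrained
    maximiser is negative.
    """
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (effect, variance) estimates")
    y, v = arr[:, 0], arr[:, 1]
    if np.any(v <= 0.0):
        raise ValueError("all sampling variances must be > 0")
    if np.allclose(y, y[0]):
        return 0.0

    res = minimize_scalar(
        lambda t: -restricted_loglik(t, y, v),
        bounds=(0.0, tau2_max),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        warnings.warn(
            "bounded REML optimisation did not converge; falling back to "
            "grid search",
            RuntimeWarning,
        )
        return _grid_tau2(y, v, tau2_max, step=tau2_max / 1e6)
    tau2 = float(res.x)
    # The bounded optimiser never lands exactly on the boundary; snap to 0
    # when 0 is at least as likely.
    if restricted_loglik(0.0, y, v) >= restricted_loglik(tau2, y, v):
        return 0.0
    return tau2


def inverse_variance_weights(v: np.ndarray, tau2: float) -> np.ndarray:
    """Normalised weights proportional to 1/(v_i + tau^2)."""
    w = 1.0 / (np.asarray(v, dtype=float) + tau2)
    return w / w.sum()


def random_effects_fit(estimates: list[EffectEstimate]) -> RandomEffectsFit:
    """Random-effects fit of several estimates of one effect.

    Estimates tau^2 by REML, weights each estimate by the inverse of
    ``v_i + tau^2`` (normalised to sum to one), and pools the effects by
    those weights.  Within an analysis pair the two weights, expressed as
    percentages, are the per-scale weights: 50%/50% indicates the two
    scales' confidence intervals are equally wide.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two estimates to fit")
    y = np.array([e.md for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    tau2 = reml_tau2(np.column_stack([y, v]))
    w = inverse_variance_weights(v, tau2)
    mu = float((w * y).sum())
    return RandomEffectsFit(tau2=tau2, mu=mu, weights=w)
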