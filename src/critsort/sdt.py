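"""Closed-form equal-variance signal-detection primitives.

Conventions
-----------
The internal-signal axis is anchored at the noise distribution: noise
trials are ``Normal(0, 1)`` and signal trials ``Normal(d', 1)``.
Criteria (thresholds) live on this axis.  The behavioural criterion
``c`` estimated from hit/false-alarm rates is measured from the midpoint
between the two distributions, so an axis threshold ``t`` corresponds to
``c = t - d'/2``.

Everything here is pure and deterministic; the Monte-Carlo counterparts
live in :mod:`critsort.simulator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = [
    "SDTModel",
    "RatePair",
    "dprime_from_rates",
    "criterion_c_from_rates",
    "rates_from_model",
    "auc_from_dprime",
    "truncated_normal_mean",
    "hedges_g_paired",
    "expected_sorted_auc",
    "expected_sorted_d",
]

Correction = Literal["none", "loglinear"]
Baseline = Literal["cell", "signal_vs_noise", "pooled_vs_noise"]

_LOG_MIN_MASS = math.log(1e-300)


@dataclass(frozen=True)
class SDTModel:
    """Equal-variance Gaussian observer.

    Parameters
    ----------
    d_prime
        Standardised distance between the noise and signal-plus-noise
        means, in units of their common standard deviation.
    criteria
        Strictly increasing thresholds on the internal-signal axis.
        Length 1 for a yes/no observer, length 3 for a 4-level
        visibility-rating observer.
    noise_mean, sigma
        Fixed at 0 and 1 for the equal-variance model; exposed for
        clarity only.
    """

    d_prime: float
    criteria: tuple[float, ...] = (0.0,)
    noise_mean: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.d_prime):
            raise ValueError("d_prime must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        crit = tuple(float(c) for c in self.criteria)
        if len(crit) == 0:
            raise ValueError("at least one criterion is required")
        if any(b <= a for a, b in zip(crit, crit[1:])):
            raise ValueError(f"criteria must be strictly increasing, got {crit}")
        object.__setattr__(self, "criteria", crit)

    @property
    def signal_mean(self) -> float:
        return self.noise_mean + self.d_prime * self.sigma

    @property
    def n_categories(self) -> int:
        return len(self.criteria) + 1


@dataclass(frozen=True)
class RatePair:
    """Hit and false-alarm proportions with the trial counts behind them."""

    hit_rate: float
    fa_rate: float
    n_signal: int = 0
    n_noise: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_rate", "fa_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.n_signal < 0 or self.n_noise < 0:
            raise ValueError("trial counts must be non-negative")


def _z_rates(rates: RatePair, correction: Correction) -> tuple[float, float]:
    h, f = rates.hit_rate, rates.fa_rate
    if correction == "loglinear":
        if rates.n_signal <= 0 or rates.n_noise <= 0:
            raise ValueError(
                "loglinear correction needs positive n_signal and n_noise counts"
            )
        h = (h * rates.n_signal + 0.5) / (rates.n_signal + 1)
        f = (f * rates.n_noise + 0.5) / (rates.n_noise + 1)
    elif correction == "none":
        if h in (0.0, 1.0):
            raise ValueError(
                f"degenerate hit_rate={h} with correction='none'; "
                "use correction='loglinear'"
            )
        if f in (0.0, 1.0):
            raise ValueError(
                f"degenerate fa_rate={f} with correction='none'; "
                "use correction='loglinear'"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(ndtri(h)), float(ndtri(f))


def dprime_from_rates(rates: RatePair, correction: Correction = "loglinear") -> float:
    """Sensitivity ``d' = z(H) - z(FA)``.

    With ``correction='loglinear'`` the rates are first replaced by
    ``(hits + 0.5) / (n_signal + 1)`` and ``(fa + 0.5) / (n_noise + 1)``,
    which keeps extreme rates finite.
    """
    zh, zf = _z_rates(rates, correction)
    return zh - zf


def criterion_c_from_rates(rates: RatePair, correction: Correction = "loglinear") -> float:
    """Criterion ``c = -(z(H) + z(FA)) / 2``.

    Positive values are conservative (fewer "present" responses),
    negative values liberal.
    """
    zh, zf = _z_rates(rates, correction)
    return -(zh + zf) / 2.0


def rates_from_model(d_prime: float, c: float) -> tuple[float, float]:
    """Forward mapping ``(H, FA) = (Phi(d'/2 - c), Phi(-d'/2 - c))``.

    Exact inverse of :func:`dprime_from_rates` /
    :func:`criterion_c_from_rates` on non-degenerate rates.
    """
    return float(ndtr(d_prime / 2.0 - c)), float(ndtr(-d_prime / 2.0 - c))


def auc_from_dprime(d: float) -> float:
    """Analytic area under the ROC curve, ``Phi(d / sqrt(2))``."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return float(ndtr(d / math.sqrt(2.0)))


def _log_gauss_mass(a: float, b: float) -> float:
    """log(Phi(b) - Phi(a)) for standardised bounds a < b, tail-stable."""
    if a >= 0:  # right tail: work with survival functions
        la, lb = log_ndtr(-a), log_ndtr(-b)
        return la + math.log1p(-math.exp(min(lb - la, 0.0)))
    if b <= 0:  # left tail, mirror
        return _log_gauss_mass(-b, -a)
    # interval straddles zero; mass is large, no cancellation issue
    return math.log(ndtr(b) - ndtr(a))


def truncated_normal_mean(
    mu: float, sigma: float, lower: float = -np.inf, upper: float = np.inf
) -> float:
    """``E[X | lower < X <= upper]`` for ``X ~ Normal(mu, sigma**2)``.

    Evaluated through the phi/Phi closed form with log-space Mills-ratio
    handling in the tails, so intervals many standard deviations from
    ``mu`` stay accurate.

    Raises
    ------
    ValueError
        If the interval is empty or carries probability mass below
        1e-300.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not lower < upper:
        raise ValueError(f"empty interval: lower={lower}, upper={upper}")
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    if np.isinf(a) and np.isinf(b):
        return float(mu)
    log_mass = _log_gauss_mass(a, b)
    if log_mass < _LOG_MIN_MASS:
        raise ValueError(
            f"interval ({lower}, {upper}] has probability mass < 1e-300 "
            f"under Normal({mu}, {sigma}**2)"
        )
    # scipy's truncnorm uses the same log-space machinery; one-sided and
    # two-sided cases are both tail-stable there.
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sigma))


def hedges_g_paired(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: Literal["classic_diff", "average_sd"] = "classic_diff",
) -> float:
    """Small-sample-corrected paired standardised mean difference.

    ``classic_diff`` standardises the mean of the paired differences by
    the SD of the differences; ``average_sd`` uses
    ``sqrt((var_a + var_b) / 2)`` instead.  Both apply the correction
    factor ``1 - 3 / (4 * df - 1)`` with ``df = n - 1``.

    Identical inputs return exactly 0.  A constant non-zero difference
    (zero denominator) raises.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D and the same length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    if np.all(diffs == 0.0):
        return 0.0
    if variant == "classic_diff":
        denom = float(np.std(diffs, ddof=1))
    elif variant == "average_sd":
        denom = math.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0.0:
        raise ValueError(f"zero variance denominator for variant={variant!r}")
    df = n - 1
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(np.mean(diffs) / denom * correction)


def _category_bounds(model: SDTModel, index: int) -> tuple[float, float]:
    edges = (-np.inf, *model.criteria, np.inf)
    if not 0 <= index < model.n_categories:
        raise ValueError(
            f"category index {index} outside 0..{model.n_categories - 1}"
        )
    return edges[index], edges[index + 1]


def expected_sorted_d(
    model: SDTModel,
    criterion_index: int = 0,
    visibility: Literal["seen", "unseen"] = "seen",
    baseline: Baseline = "cell",
    p_signal: float = 0.5,
) -> float:
    """Analytic post-hoc-sorted mean difference ``d_sorted``.

    The response cell is the half-axis defined by
    ``model.criteria[criterion_index]``: strengths strictly above it are
    "seen", at or below it "unseen".

    ``baseline`` selects the construct the cell mean is referenced to:

    ``"cell"``
        signal-trial mean minus noise-trial mean, both restricted to the
        cell (within-cell contrast).
    ``"signal_vs_noise"``
        signal-trial mean in the cell minus the untruncated noise mean.
    ``"pooled_vs_noise"``
        pooled (signal + noise, weighted by ``p_signal`` and the cell
        occupancies) cell mean minus the untruncated noise mean.

    The within-cell contrast is the symmetric textbook reading, but note
    that it *decreases* in the seen cell as the criterion becomes more
    conservative; only the ``*_vs_noise`` constructs reproduce the
    joint inflation of seen and unseen measures under a conservative
    criterion.
    """
    if not 0 <= criterion_index < len(model.criteria):
        raise ValueError(f"criterion index {criterion_index} not in model")
    c = model.criteria[criterion_index]
    if visibility == "seen":
        lower, upper = c, np.inf
    elif visibility == "unseen":
        lower, upper = -np.inf, c
    else:
        raise ValueError(f"unknown visibility {visibility!r}")
    mu_n, mu_s, sig = model.noise_mean, model.signal_mean, model.sigma
    try:
        m_signal = truncated_normal_mean(mu_s, sig, lower, upper)
        if baseline == "cell":
            return m_signal - truncated_normal_mean(mu_n, sig, lower, upper)
        if baseline == "signal_vs_noise":
            return m_signal - mu_n
        if baseline == "pooled_vs_noise":
            m_noise = truncated_normal_mean(mu_n, sig, lower, upper)
            a, b = (lower - mu_s) / sig, (upper - mu_s) / sig
            w_s = p_signal * math.exp(_log_gauss_mass(a, b))
            a, b = (lower - mu_n) / sig, (upper - mu_n) / sig
            w_n = (1.0 - p_signal) * math.exp(_log_gauss_mass(a, b))
            return (w_s * m_signal + w_n * m_noise) / (w_s + w_n) - mu_n
    except ValueError as err:
        raise ValueError(
            f"response category {visibility!r} at criterion {c} has "
            f"(near-)zero probability mass"
        ) from err
    raise ValueError(f"unknown baseline {baseline!r}")


def expected_sorted_auc(
    model: SDTModel,
    criterion_index: int = 0,
    visibility: Literal["seen", "unseen"] = "seen",
    baseline: Baseline = "cell",
    p_signal: float = 0.5,
) -> float:
    """``Phi(d_sorted / sqrt(2))`` for the analytic ``d_sorted``.

    See :func:`expected_sorted_d` for the cell and baseline semantics.
    """
    d = expected_sorted_d(model, criterion_index, visibility, baseline, p_signal)
    return auc_from_dprime(d)
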