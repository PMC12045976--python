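"""Circular hypothesis tests: Rayleigh, V-test, Watson-Williams.

These are the classical tests for directional data (Batschelet / Zar
formulations). The Rayleigh test asks whether phases are uniformly
distributed (rejection = entrainment); the V-test asks the same against
the sharper alternative of clustering around a *specified* mean angle
(rejection = synchronization to that angle); the Watson-Williams test is
the circular one-way ANOVA for equality of mean directions across groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

from .exceptions import DomainError
from .phase_metrics import circular_mean, mean_resultant, vector_length

__all__ = [
    "CircTestResult",
    "rayleigh_test",
    "v_test",
    "watson_williams",
    "fit_kappa",
    "vonmises_mean_resultant",
]

#: Weighted mean resultant length below which the Watson-Williams
#: concentration assumption is considered violated (warning attached).
WW_CONCENTRATION_WARNING = 0.45

KAPPA_CAP = 1e6


@dataclass(frozen=True)
class CircTestResult:
    """Outcome of a circular (or cohort z-) hypothesis test.

    ``df`` is ``(k - 1, N - k)`` for the Watson-Williams F test and None
    otherwise. ``mean_angle_deg`` carries the sample mean direction where
    one is defined (for the within-trial halves comparison it carries the
    signed second-minus-first circular mean difference; see
    :mod:`beatsync.comparisons`).
    """

    test_name: str
    statistic: float
    p_value: float
    n: int
    df: tuple | None = None
    mean_angle_deg: float | None = None
    warnings: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p_value out of [0, 1]: {self.p_value}")


def _check_min_n(phases: np.ndarray, n_min: int, name: str) -> None:
    if phases.size < n_min:
        raise DomainError(f"{name} requires at least {n_min} phases, got {phases.size}")


def rayleigh_test(phases_deg) -> CircTestResult:
    """Rayleigh test of uniformity.

    Statistic ``z = N * R-bar**2``; the p-value uses the higher-order
    series approximation

        p = exp(-z) * [1 + (2z - z^2)/(4N) - (24z - 132 z^2 + 76 z^3 - 9 z^4)/(288 N^2)]

    clamped to [0, 1].
    """
    phases = np.asarray(phases_deg, dtype=float)
    _check_min_n(phases, 3, "rayleigh_test")
    n = phases.size
    r_bar = vector_length(phases)
    z = n * r_bar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = min(max(p, 0.0), 1.0)
    mean_angle = circular_mean(phases) if r_bar > 1e-12 else None
    return CircTestResult("rayleigh", float(z), p, n, mean_angle_deg=mean_angle)


def v_test(phases_deg, mu0_deg: float) -> CircTestResult:
    """V-test (modified Rayleigh) against a specified mean angle ``mu0``.

    ``V = R-bar * cos(theta_bar - mu0)``; ``u = V * sqrt(2N)`` is referred
    to the upper tail of the standard normal (one-tailed).
    """
    phases = np.asarray(phases_deg, dtype=float)
    _check_min_n(phases, 3, "v_test")
    n = phases.size
    rad = np.deg2rad(phases - mu0_deg)
    v = float(np.mean(np.cos(rad)))  # = R-bar * cos(theta_bar - mu0)
    u = v * math.sqrt(2.0 * n)
    p = float(stats.norm.sf(u))
    r = mean_resultant(phases)
    mean_angle = (
        math.degrees(math.atan2(r.imag, r.real)) if abs(r) > 1e-12 else None
    )
    return CircTestResult("v_test", u, p, n, mean_angle_deg=mean_angle)


def vonmises_mean_resultant(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), the von Mises mean resultant length."""
    if kappa < 0:
        raise DomainError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def fit_kappa(r_bar: float, n: int | None = None) -> float:
    """Maximum-likelihood von Mises concentration from a mean resultant length.

    Inverts ``A(kappa) = I1/I0`` with the standard piecewise initial
    approximation (Fisher 1993) followed by Newton refinement; monotone
    nondecreasing in ``r_bar``. ``n`` is accepted for interface symmetry
    but no small-sample bias correction is applied.
    """
    if not (0.0 <= r_bar < 1.0):
        raise DomainError(f"r_bar must lie in [0, 1), got {r_bar}")
    if r_bar == 0.0:
        return 0.0
    if r_bar < 0.53:
        kappa = 2.0 * r_bar + r_bar**3 + 5.0 * r_bar**5 / 6.0
    elif r_bar < 0.85:
        kappa = -0.4 + 1.39 * r_bar + 0.43 / (1.0 - r_bar)
    else:
        kappa = 1.0 / (r_bar**3 - 4.0 * r_bar**2 + 3.0 * r_bar)
    for _ in range(50):
        a = vonmises_mean_resultant(kappa)
        # d A / d kappa = 1 - A^2 - A / kappa
        deriv = 1.0 - a * a - a / kappa
        if deriv <= 0:
            break
        step = (a - r_bar) / deriv
        kappa -= step
        if kappa <= 0:
            kappa = 1e-8
        if abs(step) < 1e-13 * max(1.0, kappa):
            break
    return min(max(kappa, 0.0), KAPPA_CAP)


def watson_williams(groups: Sequence) -> CircTestResult:
    """Watson-Williams test of homogeneity of mean directions.

    With group resultant lengths ``R_j = n_j * Rbar_j`` and pooled
    resultant ``R``,

        F = K * (N - k) * (sum_j R_j - R) / ((k - 1) * (N - sum_j R_j))

    where ``K = 1 + 3/(8 kappa-hat)`` and kappa-hat is the ML concentration
    at the weighted mean of the group mean resultant lengths. The p-value
    comes from the upper tail of F(k-1, N-k). A warning is attached when
    the weighted mean resultant length falls below 0.45 (low concentration:
    the test's assumptions are strained, as with highly dispersed phases).
    """
    if len(groups) < 2:
        raise DomainError("watson_williams needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for j, g in enumerate(arrays):
        if g.size < 2:
            raise DomainError(f"group {j + 1} has fewer than 2 phases")
    k = len(arrays)
    sizes = np.array([g.size for g in arrays])
    n_total = int(sizes.sum())
    resultants = [mean_resultant(g) for g in arrays]
    r_j = np.array([abs(r) * n for r, n in zip(resultants, sizes)])  # unnormalized
    pooled = np.concatenate(arrays)
    r_pooled = abs(mean_resultant(pooled)) * n_total
    sum_rj = float(r_j.sum())
    r_w = sum_rj / n_total  # weighted mean of group R-bars
    warnings = []
    if r_w < WW_CONCENTRATION_WARNING:
        warnings.append(
            f"weighted mean resultant length {r_w:.3f} < "
            f"{WW_CONCENTRATION_WARNING}: concentration assumption violated; "
            "interpret with caution"
        )
    kappa_hat = fit_kappa(min(r_w, 1.0 - 1e-12))
    correction = 1.0 + 3.0 / (8.0 * kappa_hat) if kappa_hat > 0 else float("inf")
    denom = (k - 1) * (n_total - sum_rj)
    between = sum_rj - r_pooled
    if denom <= 1e-12 * n_total:
        # zero within-group dispersion: means either coincide exactly or differ
        if between <= 1e-9 * n_total:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = correction * (n_total - k) * (sum_rj - r_pooled) / denom
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, k - 1, n_total - k))
    mean_angle = None
    if abs(mean_resultant(pooled)) > 1e-12:
        mean_angle = circular_mean(pooled)
    return CircTestResult(
        "watson_williams",
        float(f_stat),
        p,
        n_total,
        df=(k - 1, n_total - k),
        mean_angle_deg=mean_angle,
        warnings=tuple(warnings),
    )
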