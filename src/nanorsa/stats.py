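"""Blocking functions, jamming limits and curvature trends from raw deposition runs.

The blocking function ``B(theta)`` is the probability that a placement
attempt succeeds at coverage ``theta``; in the Monte Carlo it is estimated
as the ratio of successful to total attempts, ``B = N_succ / N_att``.  For
hard disks on a flat surface the low-density expansion

    B(theta) = 1 - 4 theta + (6 sqrt(3)/pi) theta^2
               + (40/(pi sqrt(3)) - 176/(3 pi^2)) theta^3 + O(theta^4)

is the analytic reference.  Jamming limits are across-repeat means of the
final coverage, and the structured-to-flat comparison uses

    delta  = (theta_s - theta_f) / theta_f
    Ns/Nf  = A_s theta_s / (A_f theta_f)

i.e. the relative change of occupancy and of the adsorbed particle count
on an equal footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import RsaRunResult

__all__ = [
    "FLAT_BLOCKING_COEFFS",
    "BlockingCurve",
    "BlockingFit",
    "JammingEstimate",
    "CurvatureFit",
    "estimate_blocking",
    "theoretical_flat_blocking",
    "fit_blocking_poly",
    "jamming_limit",
    "curvature_regression",
]

#: coefficients of the flat hard-disk expansion, ascending powers of theta
FLAT_BLOCKING_COEFFS = (
    1.0,
    -4.0,
    6.0 * math.sqrt(3.0) / math.pi,
    40.0 / (math.pi * math.sqrt(3.0)) - 176.0 / (3.0 * math.pi ** 2),
)


def theoretical_flat_blocking(theta):
    """Evaluate the flat-surface cubic expansion of ``B(theta)``, clamped at 0.

    Valid for ``0 <= theta < 1``; raises on values outside that domain.
    The cubic is a low-density expansion and is only quantitatively
    reliable up to ``theta ~ 0.3``.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0.0) or np.any(th >= 1.0):
        raise ValueError("theta must lie in [0, 1)")
    c0, c1, c2, c3 = FLAT_BLOCKING_COEFFS
    val = c0 + c1 * th + c2 * th ** 2 + c3 * th ** 3
    out = np.maximum(val, 0.0)
    return float(out) if np.isscalar(theta) else out


@dataclass(frozen=True)
class BlockingCurve:
    """Binned estimate of ``B(theta)`` with across-repeat standard errors."""

    theta: np.ndarray
    B: np.ndarray
    se: np.ndarray
    estimator: str
    bin_width: float
    n_runs: int


def _check_same_system(runs: Sequence[RsaRunResult]) -> None:
    if not runs:
        raise ValueError("need at least one run")
    a0, s0 = runs[0].A_s, runs[0].sigma
    for r in runs[1:]:
        if abs(r.A_s - a0) > 1e-9 * a0 or abs(r.sigma - s0) > 1e-12 * s0:
            raise ValueError("all runs must share the same surface and protein")


def _per_run_bins(run: RsaRunResult, bin_width: float, nbins: int):
    """(successes, attempts) per theta bin for one run.

    Coverage is piecewise constant between successes, so every attempt in
    the stretch ending with deposit ``i`` happens at exactly
    ``theta = i sigma / A_s`` (coverage before that success); the trailing
    failure streak happens at the final coverage.
    """
    succ = np.zeros(nbins)
    att = np.zeros(nbins)
    n = run.n_deposits
    theta_before = np.arange(n) * run.sigma / run.A_s
    idx = np.minimum((theta_before / bin_width).astype(int), nbins - 1)
    np.add.at(succ, idx, 1.0)
    np.add.at(att, idx, run.attempts_used.astype(float))
    if run.trailing_failures > 0:
        tidx = min(int(run.theta_end / bin_width), nbins - 1)
        att[tidx] += run.trailing_failures
    return succ, att


def estimate_blocking(runs: Sequence[RsaRunResult], bin_width: float = 0.01,
                      estimator: str = "binned-ratio") -> BlockingCurve:
    """Estimate ``B(theta)`` from one or more runs on the same system.

    ``binned-ratio`` pools successes over attempts per coverage bin across
    runs (the ``N_succ / N_att`` definition).  ``inverse-attempts``
    reciprocates the across-run mean of the attempts needed for the i-th
    deposit and then averages within bins.  Standard errors come from
    across-run variation where at least two runs populate a bin, else from
    the binomial approximation.  Empty bins are dropped.
    """
    _check_same_system(runs)
    nbins = int(math.ceil(1.0 / bin_width))
    centers = (np.arange(nbins) + 0.5) * bin_width

    if estimator == "binned-ratio":
        succ_all = np.zeros((len(runs), nbins))
        att_all = np.zeros((len(runs), nbins))
        for k, run in enumerate(runs):
            succ_all[k], att_all[k] = _per_run_bins(run, bin_width, nbins)
        att_tot = att_all.sum(axis=0)
        keep = att_tot > 0
        B = succ_all.sum(axis=0)[keep] / att_tot[keep]
        se = np.empty(B.size)
        for j, b in enumerate(np.nonzero(keep)[0]):
            mask = att_all[:, b] > 0
            if mask.sum() >= 2:
                per_run = succ_all[mask, b] / att_all[mask, b]
                se[j] = per_run.std(ddof=1) / math.sqrt(mask.sum())
            else:
                se[j] = math.sqrt(max(B[j] * (1.0 - B[j]), 1e-12) / att_tot[b])
        return BlockingCurve(centers[keep], B, se, estimator, bin_width, len(runs))

    if estimator == "inverse-attempts":
        nmin = min(r.n_deposits for r in runs)
        if nmin == 0:
            raise ValueError("runs contain no deposits")
        used = np.array([r.attempts_used[:nmin] for r in runs], dtype=float)
        mean_att = used.mean(axis=0)
        B_i = 1.0 / mean_att
        if len(runs) >= 2:
            se_att = used.std(axis=0, ddof=1) / math.sqrt(len(runs))
        else:
            se_att = np.sqrt(np.maximum(mean_att - 1.0, 0.0))
        se_i = se_att / mean_att ** 2  # delta method for 1/x
        theta_before = np.arange(nmin) * runs[0].sigma / runs[0].A_s
        idx = np.minimum((theta_before / bin_width).astype(int), nbins - 1)
        B = np.zeros(nbins)
        var = np.zeros(nbins)
        cnt = np.zeros(nbins)
        np.add.at(B, idx, B_i)
        np.add.at(var, idx, se_i ** 2)
        np.add.at(cnt, idx, 1.0)
        keep = cnt > 0
        B = B[keep] / cnt[keep]
        se = np.sqrt(var[keep]) / cnt[keep]
        return BlockingCurve(centers[keep], B, se, estimator, bin_width, len(runs))

    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass(frozen=True)
class BlockingFit:
    """Cubic fit of a blocking curve with the intercept pinned at ``B(0) = 1``.

    ``coeffs`` are the ascending polynomial coefficients ``(1, c1, c2, c3)``
    and ``coeff_se`` their standard errors (0 for the pinned intercept).
    ``unconstrained``/``unconstrained_se`` repeat the fit with a free
    intercept as a diagnostic: a healthy curve has an intercept
    statistically compatible with 1.

    Note the model-range caveat: fitted over the full coverage range the
    cubic is an effective parameterisation whose leading coefficient is
    steeper than the low-density expansion's -4; only a fit restricted to
    the expansion's validity range (``theta_max ~ 0.3``) recovers the
    analytic coefficients.
    """

    coeffs: tuple
    coeff_se: tuple
    residual_rms: float
    unconstrained: tuple
    unconstrained_se: tuple

    @property
    def c(self) -> tuple:
        """The free coefficients ``(c1, .., c_order)``."""
        return self.coeffs[1:]


def _weighted_fit(X: np.ndarray, y: np.ndarray, wts: np.ndarray):
    Xw = X * wts[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(Xw, y * wts, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    return coef, np.sqrt(np.diag(cov))


def fit_blocking_poly(curve: BlockingCurve, order: int = 3,
                      theta_max: float | None = None) -> BlockingFit:
    """Weighted least-squares polynomial fit of ``B(theta)`` with ``B(0) = 1``.

    ``theta_max`` restricts the fitted coverage range (``None`` fits all
    populated bins, which is what the kinetics ODE wants).
    """
    sel = slice(None) if theta_max is None else curve.theta <= theta_max
    th = curve.theta[sel]
    B = curve.B[sel]
    se = curve.se[sel]
    if th.size < 8:
        raise ValueError(f"need at least 8 populated bins, got {th.size}")
    wts = 1.0 / np.maximum(se, 1e-6)
    X = np.stack([th ** k for k in range(1, order + 1)], axis=1)
    c, c_se = _weighted_fit(X, B - 1.0, wts)
    rms = float(np.sqrt(np.mean((B - 1.0 - X @ c) ** 2)))
    Xu = np.concatenate([np.ones((th.size, 1)), X], axis=1)
    cu, cu_se = _weighted_fit(Xu, B, wts)
    return BlockingFit((1.0, *map(float, c)), (0.0, *map(float, c_se)), rms,
                       tuple(map(float, cu)), tuple(map(float, cu_se)))


@dataclass(frozen=True)
class JammingEstimate:
    """Jamming limit: across-repeat mean/sd, plus flat-referenced comparisons.

    ``delta`` is the relative coverage change versus the flat reference and
    ``ns_over_nf`` the adsorbed-count ratio on an equal footprint; both are
    ``None`` when no flat reference was supplied.
    """

    theta_inf: float
    sd: float
    n_runs: int
    area_ratio: float
    delta: float | None = None
    ns_over_nf: float | None = None


def jamming_limit(runs: Sequence[RsaRunResult],
                  flat_reference: "JammingEstimate | float | None" = None) -> JammingEstimate:
    """Across-repeat jamming statistics; budget-limited runs are excluded."""
    _check_same_system(runs)
    jammed = [r for r in runs if r.jammed]
    if len(jammed) < 2:
        raise ValueError("need at least 2 jammed runs for jamming statistics")
    finals = np.array([r.theta_end for r in jammed])
    theta = float(finals.mean())
    sd = float(finals.std(ddof=1))
    ratio = jammed[0].A_s / jammed[0].A_f
    delta = ns_nf = None
    if flat_reference is not None:
        theta_f = (flat_reference.theta_inf
                   if isinstance(flat_reference, JammingEstimate) else float(flat_reference))
        delta = (theta - theta_f) / theta_f
        ns_nf = ratio * theta / theta_f
    return JammingEstimate(theta, sd, len(jammed), ratio, delta, ns_nf)


@dataclass(frozen=True)
class CurvatureFit:
    """OLS fit of ``theta_inf`` against the half-height curvature ``1/W``."""

    slope: float
    intercept: float
    r_squared: float


def curvature_regression(estimates: Sequence[tuple]) -> CurvatureFit:
    """Regress jamming limits on ``1/W`` for a family of widths at fixed height.

    ``estimates`` is a sequence of ``(W, theta_inf)`` pairs; a positive
    slope means sharper features (larger curvature) jam at higher coverage.
    """
    from scipy.stats import linregress

    if len(estimates) < 3:
        raise ValueError("need at least 3 (W, theta_inf) points")
    W = np.array([e[0] for e in estimates], float)
    th = np.array([e[1] for e in estimates], float)
    res = linregress(1.0 / W, th)
    return CurvatureFit(float(res.slope), float(res.intercept), float(res.rvalue ** 2))
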