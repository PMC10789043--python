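"""Three-component skew-normal mixture on log UMI counts.

Pooled UMI counts of one barcode class (all gRNAs together, say) form a
mixture of an ambient-background mode and up to two signal modes; the
signal is allowed to be bimodal.  The mixture is fitted by EM on the
natural log of counts above a minimum threshold, and the ambient component
is identified as the one with the smallest location.

From the fitted posterior P(ambient | count), two integer count thresholds
are derived:

* ``t_lo`` — counts at or below it have >= ``p_lo`` (default 0.9)
  probability of being ambient;
* ``t_hi`` — counts above it have <= ``p_hi`` (default 0.1) probability of
  being ambient.

A feature is called in a cell only if its count clears ``t_hi`` while every
other feature of the class stays at or below ``t_lo``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, owens_t

logger = logging.getLogger(__name__)

N_COMPONENTS = 3


class InsufficientDataError(ValueError):
    """Too few counts above the minimum threshold to fit a mixture."""


class DegenerateFitError(ValueError):
    """The ambient posterior never reaches the signal level."""


@dataclass
class MixtureFit:
    """Fitted 3-component skew-normal mixture on log counts."""

    weights: np.ndarray      # pi_k, sum to 1
    locations: np.ndarray    # xi_k on the log-count scale
    scales: np.ndarray       # omega_k > 0
    skews: np.ndarray        # alpha_k
    log_likelihood: float
    n_observations: int
    converged: bool
    min_count: int
    max_observed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.locations = np.asarray(self.locations, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.skews = np.asarray(self.skews, dtype=float)
        if len(self.weights) != N_COMPONENTS:
            raise ValueError("mixture must have exactly 3 components")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("component weights must sum to 1")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")

    @property
    def ambient_component_index(self) -> int:
        """Ambient background = component with the smallest location."""
        return int(np.argmin(self.locations))

    def component_logprob(self, counts: np.ndarray) -> np.ndarray:
        """log pi_k + log P_k(count), shape (n, 3).

        Component probabilities are interval probabilities of the integer
        count under the log-scale skew-normal: P_k(c) =
        F_k(log(c + 1/2)) - F_k(log(c - 1/2)).
        """
        counts = np.atleast_1d(np.asarray(counts, dtype=float))
        out = np.empty((counts.size, N_COMPONENTS))
        for k in range(N_COMPONENTS):
            out[:, k] = np.log(self.weights[k] + 1e-300) + _bin_logprob(
                counts, self.skews[k], self.locations[k], self.scales[k]
            )
        return out

    def posterior_ambient(self, counts: np.ndarray) -> np.ndarray:
        """P(ambient component | count) for integer counts."""
        lp = self.component_logprob(counts)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p[:, self.ambient_component_index] / p.sum(axis=1)


@dataclass
class ThresholdPair:
    """Dual ambient-posterior count thresholds (t_lo <= t_hi)."""

    t_lo: int
    t_hi: int
    p_lo: float = 0.9
    p_hi: float = 0.1

    def __post_init__(self) -> None:
        if self.t_lo > self.t_hi:
            raise ValueError(f"t_lo {self.t_lo} > t_hi {self.t_hi}")


def _sn_cdf(x, alpha, xi, omega):
    """Skew-normal CDF via Owen's T: F(z) = Phi(z) - 2 T(z, alpha)."""
    z = (np.asarray(x, dtype=float) - xi) / omega
    return np.clip(ndtr(z) - 2.0 * owens_t(z, alpha), 0.0, 1.0)


def _edge_logprob(log_lo, log_hi, alpha, xi, omega):
    """log of the interval probability between log-scale bin edges."""
    with np.errstate(all="ignore"):
        hi = _sn_cdf(log_hi, alpha, xi, omega)
        lo = _sn_cdf(log_lo, alpha, xi, omega)
    return np.log(np.maximum(hi - lo, 1e-300))


def _bin_logprob(counts, alpha, xi, omega):
    """log P(count) under a rounded log-scale skew-normal.

    Interval likelihood F(log(c + 1/2)) - F(log(c - 1/2)): integer counts
    are treated as rounded draws, which removes the unbounded-density
    pathology of fitting a continuous density to discrete low counts.
    """
    counts = np.asarray(counts, dtype=float)
    return _edge_logprob(
        np.log(np.maximum(counts - 0.5, 1e-9)), np.log(counts + 0.5),
        alpha, xi, omega,
    )


#: counts above this are pooled into geometric bins during fitting
_EXACT_BIN_MAX = 64
_GEOM_RATIO = 1.1


def _build_bins(values, mult):
    """Fitting bins: exact integer bins for small counts, geometric above.

    Returns ``(log_lo, log_hi, weights, mid)`` with empty bins dropped.
    The interval likelihood is exact for every bin, and pooling the sparse
    high-count tail keeps the EM cost independent of the count range.
    """
    log_lo, log_hi, weights, mid = [], [], [], []
    small = values <= _EXACT_BIN_MAX
    for v, m in zip(values[small], mult[small]):
        log_lo.append(np.log(max(v - 0.5, 1e-9)))
        log_hi.append(np.log(v + 0.5))
        weights.append(m)
        mid.append(np.log(float(v)))
    if (~small).any():
        big_v, big_m = values[~small], mult[~small]
        edge = float(_EXACT_BIN_MAX) + 0.5
        top = big_v.max() + 0.5
        while edge < top:
            nxt = min(edge * _GEOM_RATIO, top)
            in_bin = (big_v > edge) & (big_v <= nxt)
            if in_bin.any():
                log_lo.append(np.log(edge))
                log_hi.append(np.log(nxt))
                weights.append(big_m[in_bin].sum())
                mid.append(
                    float(np.average(np.log(big_v[in_bin]), weights=big_m[in_bin]))
                )
            edge = nxt
    return (
        np.asarray(log_lo), np.asarray(log_hi),
        np.asarray(weights, dtype=float), np.asarray(mid),
    )


def _mixture_loglik(
    log_lo, log_hi, w: np.ndarray, weights, locs, scales, skews
) -> float:
    lp = np.empty((log_lo.size, N_COMPONENTS))
    for k in range(N_COMPONENTS):
        lp[:, k] = np.log(weights[k] + 1e-300) + _edge_logprob(
            log_lo, log_hi, skews[k], locs[k], scales[k]
        )
    m = lp.max(axis=1)
    return float(np.dot(w, m + np.log(np.exp(lp - m[:, None]).sum(axis=1))))


#: |alpha| cap — beyond this the skew-normal is numerically a half-normal
MAX_SKEW = 25.0


def _weighted_skewnorm_mle(log_lo, log_hi, w, xi0, omega0, alpha0, omega_max):
    """Maximise one component's weighted rounded-skew-normal likelihood.

    Numerical optimisation over (xi, log omega, alpha) with the skewness
    capped at +-MAX_SKEW and the scale bounded away from 0 and from
    swallowing the whole pooled distribution; guarded so the returned
    parameters are never worse than the starting point.
    """
    wsum = w.sum()
    log_omega_lo, log_omega_hi = np.log(0.05), np.log(omega_max)

    def clip_theta(theta):
        xi, log_omega, alpha = theta
        return (
            xi,
            float(np.clip(log_omega, log_omega_lo, log_omega_hi)),
            float(np.clip(alpha, -MAX_SKEW, MAX_SKEW)),
        )

    def nll(theta):
        xi, log_omega, alpha = clip_theta(theta)
        ll = _edge_logprob(log_lo, log_hi, alpha, xi, np.exp(log_omega))
        ll = np.where(np.isfinite(ll), ll, -1e6)
        return -float(np.dot(w, ll)) / wsum

    start = np.array(clip_theta((xi0, np.log(omega0), alpha0)))
    # explicit simplex: Nelder-Mead's default step for a zero coordinate is
    # tiny, which would freeze the skewness at its alpha=0 initialisation
    steps = np.array([0.15, 0.2, 1.0])
    simplex = np.vstack([start, start + np.diag(steps)])
    res = optimize.minimize(
        nll, start, method="Nelder-Mead",
        options={"maxiter": 60, "xatol": 1e-3, "fatol": 1e-6,
                 "initial_simplex": simplex},
    )
    if res.fun <= nll(start):
        xi, log_omega, alpha = clip_theta(res.x)
        return float(xi), float(np.exp(log_omega)), float(alpha)
    return float(xi0), float(omega0), float(alpha0)


def fit_count_mixture(
    counts,
    min_count: int = 2,
    min_observations: int = 100,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit the 3-component skew-normal mixture to pooled UMI counts.

    Parameters
    ----------
    counts
        Non-negative integer UMI counts pooled over cells and features of a
        single class.  Counts at or below ``min_count`` are discarded before
        fitting.
    min_count
        Minimum UMI count (exclusive) for a count to enter the fit.
    min_observations
        Fitting floor: fewer retained counts raise
        :class:`InsufficientDataError`.

    Notes
    -----
    The likelihood is the interval (rounded) form of the log-scale
    skew-normal — P(c) = F(log(c+1/2)) - F(log(c-1/2)) — which avoids the
    unbounded-density pathology of fitting a continuous density to
    discrete low counts.  Counts are collapsed to bins (exact integer bins
    up to 64, geometric above), so the cost is governed by the count range,
    not the number of cells.  Initialisation is by count terciles with zero
    skewness plus jittered restarts, keeping the best likelihood; the
    M-step is guarded so the observed log-likelihood is non-decreasing
    across iterations.
    """
    counts = np.asarray(counts)
    counts = counts[counts > min_count]
    if counts.size < min_observations:
        raise InsufficientDataError(
            f"only {counts.size} counts above min_count={min_count} "
            f"(need >= {min_observations})"
        )
    values, mult = np.unique(counts, return_counts=True)
    x = np.log(values.astype(float))
    log_lo, log_hi, w_obs, x_mid = _build_bins(values, mult)
    n = int(counts.size)

    rng = np.random.default_rng(seed)
    x_full = np.repeat(x, mult)
    q33, q66 = np.quantile(x_full, [1 / 3, 2 / 3])
    spread = max(x_full.std(), 0.1)
    # tercile moment-matching: centers and spreads of the count terciles
    terciles = [
        x_full[x_full <= q33],
        x_full[(x_full > q33) & (x_full <= q66)],
        x_full[x_full > q66],
    ]
    terc_locs = np.array([t.mean() for t in terciles])
    terc_scales = np.array([max(t.std(), 0.05) for t in terciles])

    best = None
    for restart in range(n_restarts):
        if restart == 0:
            locs, scales = terc_locs.copy(), terc_scales.copy()
        elif restart == 1:
            locs = np.array([x.min() + 0.25 * spread, q33, q66], dtype=float)
            scales = np.full(N_COMPONENTS, max(spread / 2, 0.05))
        else:
            locs = np.sort(
                rng.uniform(x.min(), x.max(), size=N_COMPONENTS)
            ).astype(float)
            scales = np.full(N_COMPONENTS, max(spread / 2, 0.05))
        skews = np.zeros(N_COMPONENTS)
        weights = np.full(N_COMPONENTS, 1 / 3)

        ll_prev = _mixture_loglik(
            log_lo, log_hi, w_obs, weights, locs, scales, skews
        )
        ll_history = [ll_prev]
        converged = False
        for _ in range(max_iter):
            # E-step: responsibilities on the bin grid
            lp = np.empty((log_lo.size, N_COMPONENTS))
            for k in range(N_COMPONENTS):
                lp[:, k] = np.log(weights[k] + 1e-300) + _edge_logprob(
                    log_lo, log_hi, skews[k], locs[k], scales[k]
                )
            lp -= lp.max(axis=1, keepdims=True)
            resp = np.exp(lp)
            resp /= resp.sum(axis=1, keepdims=True)

            # M-step (generalized: each component update only ever improves)
            new_weights = (resp * w_obs[:, None]).sum(axis=0)
            new_weights /= new_weights.sum()
            new_locs, new_scales, new_skews = locs.copy(), scales.copy(), skews.copy()
            for k in range(N_COMPONENTS):
                wk = resp[:, k] * w_obs
                if wk.sum() < 1e-8:
                    continue
                new_locs[k], new_scales[k], new_skews[k] = _weighted_skewnorm_mle(
                    log_lo, log_hi, wk, locs[k], scales[k], skews[k],
                    omega_max=2.0 * spread,
                )
            ll_new = _mixture_loglik(
                log_lo, log_hi, w_obs, new_weights, new_locs, new_scales, new_skews
            )
            if ll_new >= ll_prev - 1e-9:  # guard: never accept a worse step
                weights, locs, scales, skews = (
                    new_weights, new_locs, new_scales, new_skews,
                )
                if ll_new - ll_prev < tol * max(1.0, abs(ll_prev)):
                    converged = True
                ll_prev = ll_new
            else:
                converged = True
            ll_history.append(ll_prev)
            if converged:
                break

        fit = MixtureFit(
            weights=weights, locations=locs, scales=scales, skews=skews,
            log_likelihood=ll_prev, n_observations=n,
            converged=converged, min_count=min_count,
            max_observed=int(values.max()),
        )
        fit.ll_history = ll_history
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit

    if not best.converged:
        warnings.warn("mixture EM did not converge; fit flagged", RuntimeWarning)
        logger.warning("mixture EM failed to converge after %d iterations", max_iter)
    return best


def assignment_thresholds(
    fit: MixtureFit, p_lo: float = 0.9, p_hi: float = 0.1,
    max_count: int | None = None,
) -> ThresholdPair:
    """Derive the dual count thresholds from the ambient posterior.

    The posterior P(ambient | count) is evaluated on the integer count grid
    from ``min_count + 1`` to the largest observed scale (``max_count``,
    default ``exp(max location + 6 max scale)``).  ``t_lo`` is the last
    count before the posterior first drops below ``p_lo``; ``t_hi`` is the
    largest count whose posterior exceeds ``p_hi`` (the most conservative
    crossing if the posterior is non-monotone).  Both collapse to
    ``min_count`` when there is no ambient mass.
    """
    if max_count is None:
        if fit.max_observed is not None:
            max_count = int(fit.max_observed)
        else:
            max_count = int(
                np.ceil(np.exp(fit.locations.max() + 6 * fit.scales.max()))
            )
    lo_grid = fit.min_count + 1
    grid = np.arange(lo_grid, max(max_count, lo_grid) + 1)
    post = fit.posterior_ambient(grid)

    if post[-1] > p_hi:
        raise DegenerateFitError(
            "ambient posterior never reaches the signal level "
            f"(P(ambient) = {post[-1]:.3f} at count {grid[-1]}); "
            "inspect the fit before assigning barcodes"
        )

    above_hi = np.nonzero(post > p_hi)[0]
    t_hi = int(grid[above_hi[-1]]) if above_hi.size else fit.min_count

    below_lo = np.nonzero(post < p_lo)[0]
    if below_lo.size == 0:
        t_lo = t_hi
    elif below_lo[0] == 0:
        t_lo = fit.min_count
    else:
        t_lo = int(grid[below_lo[0] - 1])
    t_lo = min(t_lo, t_hi)
    return ThresholdPair(t_lo=t_lo, t_hi=t_hi, p_lo=p_lo, p_hi=p_hi)
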