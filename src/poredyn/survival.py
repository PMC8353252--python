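"""Survival probability P(τ) and residence half-life τ1/2.

P(τ) averages, over all time origins t with at least one particle inside,
the fraction N(t, t+τ)/N(t) of particles inside at t that are still inside
after a lag τ.  Under the default *continuous* convention a particle counts
as surviving only if it is inside at every stored frame in [t, t+τ], which
makes P non-increasing with P(0) = 1; the *intermittent* convention only
requires presence at the two endpoints.  The residence half-life is the lag
at which P crosses 0.5, linearly interpolated between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import ResidencyMatrix

__all__ = ["SurvivalCurve", "survival_probability", "residence_half_life"]


@dataclass
class SurvivalCurve:
    """P(τ) on a τ grid (ps) with the residence half-life."""

    tau: np.ndarray
    P: np.ndarray
    convention: str
    tau_half: float | None = None


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Per (particle, frame): length of the run of consecutive True flags
    starting at that frame (0 where the flag is False)."""
    n_p, n_f = flags.shape
    runs = np.zeros((n_p, n_f), dtype=np.intp)
    runs[:, -1] = flags[:, -1]
    for f in range(n_f - 2, -1, -1):
        runs[:, f] = np.where(flags[:, f], runs[:, f + 1] + 1, 0)
    return runs


def survival_probability(res: ResidencyMatrix, tau_max: float,
                         convention: str = "continuous") -> SurvivalCurve:
    """Compute P(τ) for τ = 0, Δt, 2Δt, … up to tau_max.

    A common origin set is used for the whole curve: origins t with
    t + tau_max ≤ T and N(t) > 0.  Holding the origins fixed across lags
    makes every per-origin ratio non-increasing in τ under the continuous
    convention, so the averaged curve is guaranteed monotone with P(0) = 1
    (a per-τ origin set can produce spurious upticks when late origins drop
    out of the average).
    """
    if convention not in ("continuous", "intermittent"):
        raise ValueError(f"unknown convention {convention!r}")
    flags = res.inside
    if not flags.any():
        raise ValueError("empty residency: no particle is ever inside")
    dt = res.dt
    if dt <= 0:
        raise ValueError("residency needs at least two frames")
    k_max = int(round(tau_max / dt))
    if abs(k_max * dt - tau_max) > 1e-6 * dt:
        raise ValueError("tau_max must be a multiple of the frame spacing")
    if k_max > res.n_frames - 1:
        raise ValueError("tau_max exceeds the trajectory span")

    n_frames = res.n_frames
    counts = flags.sum(axis=0)            # N(t)
    if convention == "continuous":
        runs = _run_lengths(flags)

    tau = dt * np.arange(k_max + 1)
    origins = np.arange(n_frames - k_max)
    origins = origins[counts[origins] > 0]
    if origins.size == 0:
        raise ValueError(
            "empty residency: no occupied origin with t + tau_max ≤ T")
    P = np.empty(k_max + 1)
    for k in range(k_max + 1):
        if convention == "continuous":
            surv = (runs[:, origins] >= k + 1).sum(axis=0)
        else:
            surv = (flags[:, origins] & flags[:, origins + k]).sum(axis=0)
        P[k] = float(np.mean(surv / counts[origins]))

    curve = SurvivalCurve(tau=tau, P=P, convention=convention)
    curve.tau_half = residence_half_life(curve)
    return curve


def residence_half_life(curve: SurvivalCurve) -> float | None:
    """τ at P(τ) = 0.5 by linear interpolation; None if never reached."""
    tau, P = curve.tau, curve.P
    if tau.size == 0:
        raise ValueError("empty survival curve")
    ok = ~np.isnan(P)
    tau, P = tau[ok], P[ok]
    for i in range(P.size):
        if P[i] <= 0.5:
            if P[i] == 0.5 or i == 0:
                return float(tau[i])
            p0, p1 = P[i - 1], P[i]
            t0, t1 = tau[i - 1], tau[i]
            return float(t0 + (p0 - 0.5) * (t1 - t0) / (p0 - p1))
    return None
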