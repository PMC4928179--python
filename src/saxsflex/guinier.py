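"""Guinier analysis: radius of gyration and zero-angle intensity.

At small angles the scattering of any compact particle follows
I(q) ≈ I(0)·exp(−q²Rg²/3), so ln I is linear in q² with slope −Rg²/3.
The approximation holds for q·Rg up to ≈ 1.3; because the window bound
depends on the Rg being estimated, the fit iterates (fit → Rg → window)
to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, NoGuinierRegionError
from .profiles import ScatteringProfile

_MIN_POINTS = 5
_MAX_ITER = 50
_RG_TOL = 1e-6


@dataclass(frozen=True)
class GuinierResult:
    """Result of a Guinier fit.

    Attributes
    ----------
    rg : float
        Radius of gyration, Å.
    i0 : float
        Extrapolated zero-angle intensity, arbitrary units.
    q_window : tuple[float, float]
        (q_lo, q_hi) actually used, Å⁻¹.
    r2 : float
        Coefficient of determination of the ln I vs q² regression.
    """

    rg: float
    i0: float
    q_window: tuple[float, float]
    r2: float


def _linfit(q2: np.ndarray, ln_i: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(q2, ln_i, 1)
    resid = ln_i - (slope * q2 + intercept)
    ss_tot = np.sum((ln_i - ln_i.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def guinier_fit(profile: ScatteringProfile, qrg_max: float = 1.3) -> GuinierResult:
    """Estimate Rg and I(0) from the low-q limit of a profile.

    The window is the largest low-q prefix satisfying q·Rg ≤ ``qrg_max``,
    found by fixed-point iteration on Rg (max 50 iterations, tolerance
    1e-6 Å).  Raises :class:`NoGuinierRegionError` when the low-q data do
    not decay, :class:`InsufficientDataError` with fewer than 5 usable
    points.
    """
    q, inten = profile.q, profile.intensity
    if q.size < _MIN_POINTS:
        raise InsufficientDataError(
            f"need ≥ {_MIN_POINTS} points for a Guinier fit, have {q.size}"
        )
    q2 = q**2
    ln_i = np.log(inten)

    # seed with the whole curve; the fixed-point iteration shrinks the
    # window to q·Rg ≤ qrg_max (a short seed is too noise-sensitive)
    slope, intercept, _ = _linfit(q2, ln_i)
    if slope >= 0:
        raise NoGuinierRegionError("no low-q decay: Guinier slope is non-negative")
    rg = float(np.sqrt(-3.0 * slope))

    mask = None
    for _ in range(_MAX_ITER):
        mask = q * rg <= qrg_max
        if mask.sum() < _MIN_POINTS:
            mask = np.zeros_like(mask)
            mask[:_MIN_POINTS] = True
        slope, intercept, r2 = _linfit(q2[mask], ln_i[mask])
        if slope >= 0:
            raise NoGuinierRegionError("no low-q decay inside the Guinier window")
        rg_new = float(np.sqrt(-3.0 * slope))
        done = abs(rg_new - rg) < _RG_TOL
        rg = rg_new
        if done:
            break

    qw = (float(q[mask][0]), float(q[mask][-1]))
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)), q_window=qw, r2=r2)
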