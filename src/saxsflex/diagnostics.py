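"""Classical SAXS shape diagnostics and the entropy-quartile classifier.

Transforms
----------
kratky                y = q²·I(q)            vs  x = q
dimensionless_kratky  y = (qRg)²·I(q)/I(0)   vs  x = q·Rg
porod                 y = q⁴·I(q)/I(0)       vs  x = q
porod_debye           y = q⁴·I(q)/I(0)       vs  x = q⁴
q3_debye              y = q³·I(q)/I(0)       vs  x = q³

A compact particle decays as q⁻⁴ at moderate q, so its Porod-Debye plot
plateaus; flexible chains decay as q⁻² … q⁻³ and do not.  An ideal compact
particle's dimensionless Kratky plot peaks at (√3, 3e⁻¹ ≈ 1.104).  All
transforms are pointwise and never smooth the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InsufficientDataError
from .profiles import ScatteringProfile

#: dimensionless Kratky landmark of an ideal compact particle
KRATKY_PEAK_X = float(np.sqrt(3.0))
KRATKY_PEAK_Y = float(3.0 / np.e)  # = 1.104

#: entropy quartile cut-points, nats (from a broad survey of deposited data)
ENTROPY_CUTPOINTS = (3.37, 3.86, 4.26)

_LABELS = ("Q1_compact", "Q2_intermediate", "Q3_flexible", "Q4_disordered")


@dataclass(frozen=True)
class TransformedCurve:
    x: np.ndarray
    y: np.ndarray
    kind: str


@dataclass(frozen=True)
class FlexibilityClass:
    """Quartile flexibility label derived from the RgD entropy S."""

    label: str
    cutpoints: tuple[float, float, float] = ENTROPY_CUTPOINTS


@dataclass(frozen=True)
class PlateauReport:
    present: bool
    x_range: tuple[float, float] | None
    level: float | None


def _require_profile(profile: ScatteringProfile):
    if len(profile) == 0:
        raise InsufficientDataError("empty profile")


def kratky(profile: ScatteringProfile) -> TransformedCurve:
    """q²·I(q) versus q."""
    _require_profile(profile)
    return TransformedCurve(profile.q.copy(), profile.q**2 * profile.intensity, "kratky")


def dimensionless_kratky(profile: ScatteringProfile, rg: float, i0: float) -> TransformedCurve:
    """(qRg)²·I(q)/I(0) versus qRg — size-free; folded particles peak at
    (√3, 3e⁻¹)."""
    _require_profile(profile)
    if rg <= 0 or i0 <= 0:
        raise ValueError("rg and i0 must be positive")
    x = profile.q * rg
    return TransformedCurve(x, x**2 * profile.intensity / i0, "dimensionless_kratky")


def porod(profile: ScatteringProfile, i0: float) -> TransformedCurve:
    """q⁴·I(q)/I(0) versus q (used to locate the Porod-Debye region)."""
    _require_profile(profile)
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    return TransformedCurve(profile.q.copy(), profile.q**4 * profile.intensity / i0, "porod")


def porod_debye(profile: ScatteringProfile, i0: float, exponent: int = 4) -> TransformedCurve:
    """qⁿ·I(q)/I(0) versus qⁿ with n = 4 (Porod-Debye) or n = 3 (q³-Debye)."""
    _require_profile(profile)
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if exponent not in (3, 4):
        raise ValueError("exponent must be 3 or 4")
    kind = "porod_debye" if exponent == 4 else "q3_debye"
    qn = profile.q**exponent
    return TransformedCurve(qn, qn * profile.intensity / i0, kind)


def detect_plateau(
    curve: TransformedCurve,
    window_fraction: float = 0.25,
    slope_tol: float = 0.1,
) -> PlateauReport:
    """Heuristic plateau test on a Porod-Debye (or q³-Debye) curve.

    Locates the first local maximum of the corresponding Porod plot
    (y vs q — the ordinate is shared and x is monotone in q), then tests
    the flatness of y over a window covering ``window_fraction`` of the
    x-range beyond that peak.  Flatness is measured on the cumulative
    integral Y(x) = ∫y dx, whose quadratic coefficient is immune to
    point noise and to form-factor oscillations about a constant level:
    the statistic |2c₂|·Δx / slopē is the relative drift of the trend of
    y across the window, and the plateau is declared present when it
    stays within ``slope_tol``.  Mirrors the visual judgement
    practitioners make on these plots; thresholds are tunable heuristics.
    """
    if curve.kind not in ("porod_debye", "q3_debye"):
        raise ValueError(f"plateau detection applies to Porod-Debye curves, got {curve.kind!r}")
    n = curve.x.size
    if n < 20:
        raise InsufficientDataError(f"need ≥ 20 points for plateau detection, have {n}")

    y = curve.y
    # light smoothing for peak finding only; the flatness test uses raw y
    width = max(3, n // 50)
    kernel = np.ones(width) / width
    ys = np.convolve(y, kernel, mode="same")

    peak = None
    for i in range(1, n - 1):
        if ys[i] >= ys[i - 1] and ys[i] >= ys[i + 1]:
            peak = i
            break
    if peak is None or peak >= n - 5:
        return PlateauReport(False, None, None)

    x0 = curve.x[peak]
    span = window_fraction * (curve.x[-1] - curve.x[0])
    m = (curve.x >= x0) & (curve.x <= x0 + span)
    if m.sum() < 5:
        return PlateauReport(False, None, None)
    xw, yw = curve.x[m], y[m]
    big_y = cumulative_trapezoid(yw, xw, initial=0.0)
    c2 = float(np.polyfit(xw, big_y, 2)[0])
    dx = float(xw[-1] - xw[0])
    mean_slope = float((big_y[-1] - big_y[0]) / dx)  # = mean level of y
    if mean_slope <= 0:
        return PlateauReport(False, None, None)
    drift = abs(2.0 * c2) * dx / mean_slope
    present = bool(drift <= slope_tol)
    return PlateauReport(present, (float(xw[0]), float(xw[-1])), mean_slope)


def classify_entropy(s: float) -> FlexibilityClass:
    """Quartile flexibility class of an entropy value (nats).

    Q1 for S ≤ 3.37, Q2 for 3.37 < S ≤ 3.86, Q3 for 3.86 < S ≤ 4.26,
    Q4 for S > 4.26; boundaries belong to the lower class.
    """
    if not np.isfinite(s):
        raise ValueError(f"entropy must be finite, got {s}")
    c1, c2, c3 = ENTROPY_CUTPOINTS
    if s <= c1:
        label = _LABELS[0]
    elif s <= c2:
        label = _LABELS[1]
    elif s <= c3:
        label = _LABELS[2]
    else:
        label = _LABELS[3]
    return FlexibilityClass(label)
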