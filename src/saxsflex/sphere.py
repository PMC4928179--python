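"""Scattering of a homogeneous sphere, parameterized by radius of gyration.

This is the forward model for a single conformation: a particle with
radius of gyration Rg is represented by a uniform solid sphere of radius
R = sqrt(5/3)·Rg (the hard-sphere relation R² = (5/3)Rg²).  Its normalized
scattering intensity is

    I_S(q, Rg) = [3 (sin x − x cos x) / x³]²,   x = q R,

with I_S(0, Rg) = 1.  Any experimental scale or contrast factor is handled
outside this kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# x below this uses the Taylor series of the amplitude; the direct formula
# suffers catastrophic cancellation as x -> 0 (relative error ~1e-20/x^3,
# already ~1e-8 at x = 1e-4), while the 4th-order series truncation error
# x^6/15120 stays below machine epsilon up to x = 1e-2.
_SERIES_X = 1e-2
# sqrt(5/3): sphere radius per unit radius of gyration
_R_OVER_RG = np.sqrt(5.0 / 3.0)


def _amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere scattering amplitude 3(sin x − x cos x)/x³."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_X
    xs = x[small]
    # 3(sin x - x cos x)/x^3 = 1 - x^2/10 + x^4/280 - ...
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def sphere_intensity(q, rg: float):
    """Normalized intensity I_S(q, Rg) of a homogeneous sphere.

    Parameters
    ----------
    q
        Scalar or array of momentum transfer magnitudes, Å⁻¹, q ≥ 0.
    rg
        Radius of gyration, Å, must be positive.

    Returns
    -------
    Intensity in [0, 1]; exactly 1 at q = 0.
    """
    if not np.isfinite(rg) or rg <= 0:
        raise ValueError(f"rg must be positive and finite, got {rg}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    x = q * (_R_OVER_RG * rg)
    out = _amplitude(x) ** 2
    return out if out.ndim else float(out)


def _intensity_matrix(q: np.ndarray, rg_grid: np.ndarray) -> np.ndarray:
    """I_S on the outer product of a q grid and an Rg grid; shape (nq, nrg)."""
    x = np.multiply.outer(np.asarray(q, dtype=float), _R_OVER_RG * np.asarray(rg_grid, dtype=float))
    return _amplitude(x) ** 2


@dataclass(frozen=True)
class SphereIntensityGrid:
    """Precomputed I_S(q, Rg) on a rectangular grid; values in [0, 1]."""

    q: np.ndarray
    rg_grid: np.ndarray
    values: np.ndarray  # shape (len(q), len(rg_grid))


def precompute_grid(q, rg_grid) -> SphereIntensityGrid:
    """Tabulate the sphere intensity on a (q, Rg) grid.

    Bit-identical to elementwise :func:`sphere_intensity` calls; exists so
    the ensemble-average quadrature can be vectorized inside optimizers.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    rg_grid = np.atleast_1d(np.asarray(rg_grid, dtype=float))
    if q.size == 0 or rg_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(q < 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be non-negative and strictly increasing")
    if np.any(rg_grid <= 0) or (rg_grid.size > 1 and np.any(np.diff(rg_grid) <= 0)):
        raise ValueError("rg grid must be positive and strictly increasing")
    return SphereIntensityGrid(q=q, rg_grid=rg_grid, values=_intensity_matrix(q, rg_grid))
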