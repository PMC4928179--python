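"""The in-memory SAXS curve container and elementary profile operations.

A solution scattering experiment yields a rotationally averaged intensity
I(q) on a grid of momentum-transfer magnitudes q (Å⁻¹), usually with a
per-point standard error column.  :class:`ScatteringProfile` is the validated
container every other module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MalformedProfileError


@dataclass(frozen=True)
class ScatteringProfile:
    """A measured or synthetic SAXS curve.

    Parameters
    ----------
    q
        Momentum-transfer magnitudes in Å⁻¹, strictly increasing, all > 0.
    intensity
        I(q) in arbitrary units, finite and strictly positive.
    sigma
        Optional per-point standard errors of I(q), same units as the
        intensity, finite and non-negative.
    label
        Free-text identifier carried through file round-trips.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.ndim != 1 or q.size != i.size:
            raise MalformedProfileError("q and intensity must be 1-D and equal length")
        if q.size and not np.all(np.isfinite(q)):
            raise MalformedProfileError("q contains non-finite values")
        if q.size and (np.any(q <= 0) or np.any(np.diff(q) <= 0)):
            raise MalformedProfileError("q must be strictly increasing and positive")
        if q.size and (not np.all(np.isfinite(i)) or np.any(i <= 0)):
            raise MalformedProfileError("intensity must be finite and positive")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise MalformedProfileError("sigma must match q in length")
            if s.size and (not np.all(np.isfinite(s)) or np.any(s < 0)):
                raise MalformedProfileError("sigma must be finite and non-negative")

    def __len__(self) -> int:
        return self.q.size

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def window(self, q_lo: float, q_hi: float) -> "ScatteringProfile":
        """Restrict the profile to q ∈ [q_lo, q_hi]."""
        m = (self.q >= q_lo) & (self.q <= q_hi)
        return ScatteringProfile(
            self.q[m],
            self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            self.label,
        )

    def with_label(self, label: str) -> "ScatteringProfile":
        return replace(self, label=label)


def normalize(profile: ScatteringProfile, i0: float) -> ScatteringProfile:
    """Divide the intensity (and sigma) by the zero-angle intensity I(0).

    The q grid is unchanged.  Homogeneous: normalizing by ``a*b`` equals
    normalizing by ``a`` then ``b``.
    """
    if not np.isfinite(i0) or i0 <= 0:
        raise ValueError(f"i0 must be a positive finite scalar, got {i0}")
    return ScatteringProfile(
        profile.q,
        profile.intensity / i0,
        None if profile.sigma is None else profile.sigma / i0,
        profile.label,
    )
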