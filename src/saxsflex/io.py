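"""Reading and writing 3-column SAXS ``.dat`` text files.

The dialect is the permissive one used by ATSAS / BIOISIS / SASBDB deposits:
whitespace-delimited columns ``q  I(q)  [sigma_I]``, with comment lines
starting with ``#`` and arbitrary non-numeric header/footer lines skipped.
Columns beyond the third are ignored.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import MalformedProfileError
from .profiles import ScatteringProfile

logger = logging.getLogger(__name__)

_MIN_POINTS = 5


def _try_row(tokens: list[str]) -> tuple[float, ...] | None:
    """Parse up to three leading numeric tokens; None if fewer than two."""
    vals = []
    for tok in tokens[:3]:
        try:
            vals.append(float(tok))
        except ValueError:
            break
    return tuple(vals) if len(vals) >= 2 else None


def read_dat(path, units: str = "angstrom", label: str | None = None) -> ScatteringProfile:
    """Read a SAXS profile from a ``.dat`` text file.

    Parameters
    ----------
    path
        Input file.  Must contain at least two numeric columns after
        skipping comment ('#') and non-numeric lines.
    units
        ``"angstrom"`` (default) leaves q as-is; ``"nm"`` converts q from
        nm⁻¹ to Å⁻¹ (q × 0.1).
    label
        Overrides the label; default is the file stem.

    Rows with non-positive or non-finite q or I are dropped (the count is
    logged).  A numeric third column becomes the sigma column.
    """
    if units not in ("angstrom", "nm"):
        raise ValueError(f"units must be 'angstrom' or 'nm', got {units!r}")
    path = Path(path)
    text = path.read_text()

    rows = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parsed = _try_row(stripped.split())
        if parsed is not None:
            rows.append(parsed)

    if not rows:
        raise MalformedProfileError(f"{path}: no numeric data rows found")

    has_sigma = all(len(r) == 3 for r in rows)
    q = np.array([r[0] for r in rows])
    i = np.array([r[1] for r in rows])
    s = np.array([r[2] for r in rows]) if has_sigma else None

    if units == "nm":
        q = q * 0.1

    good = np.isfinite(q) & np.isfinite(i) & (q > 0) & (i > 0)
    if s is not None:
        good &= np.isfinite(s) & (s >= 0)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid rows", path, n_dropped)

    q, i = q[good], i[good]
    s = s[good] if s is not None else None
    if q.size < _MIN_POINTS:
        raise MalformedProfileError(
            f"{path}: only {q.size} valid points after filtering (need ≥ {_MIN_POINTS})"
        )

    order = np.argsort(q)
    q, i = q[order], i[order]
    s = s[order] if s is not None else None
    # collapse exact q duplicates (rare in deposits; keep first occurrence)
    keep = np.concatenate(([True], np.diff(q) > 0))
    q, i = q[keep], i[keep]
    s = s[keep] if s is not None else None

    return ScatteringProfile(q, i, s, label if label is not None else path.stem)


def write_dat(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column (or 2-column, if no sigma) text.

    A '#'-prefixed header carries the label; values round-trip through
    :func:`read_dat` to better than 6 significant digits.
    """
    path = Path(path)
    lines = [f"# {profile.label}", "# q(1/angstrom)  I(q)" + ("  sigma_I" if profile.has_sigma else "")]
    for k in range(len(profile)):
        cols = [f"{profile.q[k]:.9e}", f"{profile.intensity[k]:.9e}"]
        if profile.has_sigma:
            cols.append(f"{profile.sigma[k]:.9e}")
        lines.append("  ".join(cols))
    path.write_text("\n".join(lines) + "\n")
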