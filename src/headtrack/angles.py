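"""Circular arithmetic on heading angles, in degrees.

Headings live on [0, 360), with 180 denoting "forwards" at the start of a
trajectory (360 and 0 are the same direction).  Every angular difference in
the package is routed through :func:`signed_diff_deg` / :func:`abs_diff_deg`
so that wraparound across 0/360 is handled in exactly one place.

All functions accept scalars or numpy arrays and return the matching shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "signed_diff_deg", "abs_diff_deg"]


def _check_finite(*xs) -> None:
    for x in xs:
        if not np.all(np.isfinite(x)):
            raise ValueError("heading angles must be finite")


def wrap_deg(x):
    """Wrap an unbounded angle (degrees) onto [0, 360).

    Idempotent; ``wrap_deg(x) ≡ x (mod 360)``.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    out = np.mod(x, 360.0)
    # np.mod can return 360.0 for tiny negative inputs due to rounding
    out = np.where(out >= 360.0, out - 360.0, out)
    return out if out.ndim else float(out)


def signed_diff_deg(a, b):
    """Signed minimal rotation from heading ``b`` to heading ``a``, in (-180, 180].

    Antisymmetric except for exactly opposite headings, which return +180
    (a fixed tie-break so the function is deterministic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, b)
    d = np.mod(a - b, 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    out = np.asarray(d)
    return out if out.ndim else float(out)


def abs_diff_deg(a, b):
    """Smaller of the two angles between headings ``a`` and ``b``, in [0, 180]."""
    d = np.abs(signed_diff_deg(a, b))
    return d if np.ndim(d) else float(d)
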