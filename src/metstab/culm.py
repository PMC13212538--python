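"""Culm-mechanics derived traits.

The rice culm's basal internode is modelled as a hollow oval tube.  From
its outer/inner oval diameters and a prostrate-tester reading, three
mechanical traits are derived:

* section modulus ``SM`` — geometric resistance of the cross-section,
* bending stress ``BS`` — pushing resistance normalised per tiller,
* bending moment at breaking ``M = SM × BS``.

The section-modulus expression used by the source methodology is

    SM = (pi/32) * (a1**3 * b1 - a2**3 * b2)

where ``a1, b1`` are the outer minor/major oval diameters (mm) and ``a2,
b2`` the inner ones.  The textbook section modulus of a hollow oval would
additionally divide by the outer major radius; both conventions are
offered (``convention="as_printed"`` is the default, ``"standard"``
divides by ``b1``).

Bending stress follows ``BS = (TR/40) * (1000/TN)`` with ``TR`` the
prostrate-tester reading and ``TN`` the tiller number; the calibration
constant 40 is exposed as an argument because instrument conventions vary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["section_modulus", "bending_stress", "bending_moment", "derive_culm_traits"]


def section_modulus(a1, b1, a2, b2, convention: str = "as_printed"):
    """Section modulus (mm^3) of a hollow-oval culm cross-section.

    Vectorized over array-like inputs.  Raises DomainError when an inner
    diameter exceeds its outer counterpart (the hollow cannot be larger
    than the wall).
    """
    a1, b1, a2, b2 = (np.asarray(x, dtype=float) for x in (a1, b1, a2, b2))
    if np.any(a2 > a1) or np.any(b2 > b1):
        raise DomainError("inner diameter exceeds outer diameter (a2 > a1 or b2 > b1)")
    if np.any(a1 < 0) or np.any(b1 < 0) or np.any(a2 < 0) or np.any(b2 < 0):
        raise DomainError("diameters must be non-negative")
    sm = (np.pi / 32.0) * (a1**3 * b1 - a2**3 * b2)
    if convention == "standard":
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = np.where(b1 > 0, sm / b1, 0.0)
    elif convention != "as_printed":
        raise ValueError(f"unknown section-modulus convention {convention!r}")
    return sm if sm.ndim else float(sm)


def bending_stress(tr, tn, calibration: float = 40.0):
    """Bending stress (g/mm^2) from prostrate-tester reading TR and tiller number TN."""
    tr = np.asarray(tr, dtype=float)
    tn = np.asarray(tn, dtype=float)
    if np.any(tn < 1):
        raise DomainError("tiller number must be >= 1")
    bs = (tr / calibration) * (1000.0 / tn)
    return bs if bs.ndim else float(bs)


def bending_moment(sm, bs):
    """Bending moment at breaking, M = SM * BS (native SM·BS units)."""
    sm = np.asarray(sm, dtype=float)
    bs = np.asarray(bs, dtype=float)
    m = sm * bs
    return m if m.ndim else float(m)


def derive_culm_traits(
    df: pd.DataFrame,
    convention: str = "as_printed",
    calibration: float = 40.0,
) -> pd.DataFrame:
    """Append SM, BS, M columns to a measurements table.

    ``df`` must carry columns ``a1, b1, a2, b2, TR, TN`` (per-culm
    measurements).  Returns a copy with the three derived columns added.
    """
    required = ["a1", "b1", "a2", "b2", "TR", "TN"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"measurement columns missing: {missing}")
    out = df.copy()
    out["SM"] = section_modulus(df["a1"], df["b1"], df["a2"], df["b2"], convention)
    out["BS"] = bending_stress(df["TR"], df["TN"], calibration)
    out["M"] = bending_moment(out["SM"], out["BS"])
    return out
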