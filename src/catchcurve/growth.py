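"""von Bertalanffy length-age transforms.

Every length record entering a catch curve is aged deterministically through
the von Bertalanffy growth model

    L(a) = L_inf * (1 - exp(-k * (a - t0)))

and its inverse.  The growth coefficient ``k`` is taxon-specific; ``L_inf``
(asymptotic length, mm) and ``t0`` (theoretical age at length zero, yr) must
be supplied by configuration for each species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GrowthParams", "age_to_length", "length_to_age", "ages_from_lengths"]

#: fraction of L_inf used when clamping over-asymptote lengths
CLAMP_FRACTION = 0.999


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy parameter triple for one species.

    Parameters
    ----------
    linf : float
        Asymptotic length L_inf in mm.  Must be positive.
    k : float
        Growth coefficient in 1/yr.  Must be positive.
    t0 : float
        Theoretical age at length zero, yr.
    """

    linf: float
    k: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.linf > 0:
            raise ValueError(f"linf must be positive, got {self.linf}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")


def age_to_length(a, p: GrowthParams):
    """Mean length at age ``a`` (yr) under the von Bertalanffy model.

    Accepts scalars or arrays.  Raises ``ValueError`` for any age below
    ``t0`` (the model is undefined there).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < p.t0):
        raise ValueError(f"age below t0={p.t0} is outside the model domain")
    out = p.linf * -np.expm1(-p.k * (a - p.t0))
    return out if out.ndim else float(out)


def length_to_age(length, p: GrowthParams):
    """Invert the growth curve: age (yr) at mean length ``length`` (mm).

    Valid for 0 <= length < linf; lengths at or above the asymptote have no
    finite age (see :func:`ages_from_lengths` for the record-level policy).
    """
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("negative length")
    if np.any(length >= p.linf):
        raise ValueError(f"length at or above linf={p.linf} has no finite age")
    out = p.t0 - np.log1p(-length / p.linf) / p.k
    return out if out.ndim else float(out)


def ages_from_lengths(lengths, p: GrowthParams, over_linf: str = "drop"):
    """Age a vector of measured lengths, handling over-asymptote records.

    Measured lengths can exceed L_inf through individual growth variability;
    those records have no finite model age.  Policy:

    ``"drop"`` (default)
        Exclude them, log a warning, and report the count.  Conservative and
        auditable.
    ``"clamp"``
        Assign the age at ``0.999 * linf``.

    Returns
    -------
    ages : ndarray
        Ages of the retained records, in input order.
    n_dropped : int
        Number of records excluded (0 under ``"clamp"``).
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("negative length")
    over = lengths >= p.linf
    n_over = int(over.sum())
    if over_linf == "drop":
        if n_over:
            logger.warning(
                "dropped %d of %d records with length >= linf=%.1f mm",
                n_over, lengths.size, p.linf,
            )
        return length_to_age(lengths[~over], p), n_over
    if over_linf == "clamp":
        clamped = np.where(over, CLAMP_FRACTION * p.linf, lengths)
        if n_over:
            logger.warning(
                "clamped %d records with length >= linf=%.1f mm to age at %.1f%% of linf",
                n_over, p.linf, 100 * CLAMP_FRACTION,
            )
        return length_to_age(clamped, p), 0
    raise ValueError(f"unknown over_linf policy {over_linf!r}")
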