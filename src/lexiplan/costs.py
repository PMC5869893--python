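"""Wishlist cost functions: LTCP, EUD, max dose, mean dose.

All four are convex in the voxel doses, which is what makes the
prioritized epsilon-constraint method globally valid:

* ``LTCP(d) = (1/m) * sum_j exp(-alpha * (d_j - D_p))`` — the logarithmic
  tumor-control surrogate: 1 for a uniform dose at prescription ``D_p``,
  exploding for underdose, -> 0 as doses rise.  ``alpha`` (1/Gy) is the
  cell-sensitivity parameter.
* ``EUD(d; k) = ((1/m) * sum_j d_j**k) ** (1/k)`` — generalized power
  mean with volume-effect exponent ``k >= 1``; k=1 is the mean dose,
  large k approaches the maximum.
* max / mean dose over the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .errors import StructureError

COST_KINDS = ("LTCP", "EUD", "MAX", "MEAN")


@dataclass(frozen=True)
class CostSpec:
    """A cost-function kind plus its parameters, as used in wishlist rows."""

    kind: str
    d_p: Optional[float] = None    # LTCP prescription dose (Gy)
    alpha: Optional[float] = None  # LTCP cell sensitivity (1/Gy)
    k: Optional[float] = None      # EUD volume-effect exponent

    def __post_init__(self):
        if self.kind not in COST_KINDS:
            raise ValueError(f"unknown cost kind {self.kind!r}; expected one of {COST_KINDS}")
        if self.kind == "LTCP":
            if self.d_p is None or self.d_p <= 0:
                raise ValueError("LTCP requires a prescription dose D_p > 0")
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("LTCP requires cell sensitivity alpha > 0")
        if self.kind == "EUD":
            if self.k is None or self.k < 1:
                raise ValueError("EUD requires volume-effect exponent k >= 1")

    def evaluate(self, doses: np.ndarray) -> float:
        return evaluate(self, doses)


def _require_nonempty(doses: np.ndarray) -> np.ndarray:
    d = np.asarray(doses, float).ravel()
    if d.size == 0:
        raise StructureError("cost function evaluated on an empty structure")
    return d


def ltcp(doses: np.ndarray, d_p: float, alpha: float) -> float:
    """LTCP over a structure; equals 1 iff the dose is uniform at ``d_p``."""
    if d_p <= 0 or alpha <= 0:
        raise ValueError("LTCP requires D_p > 0 and alpha > 0")
    return float(np.exp(log_ltcp(doses, d_p, alpha)))


def log_ltcp(doses: np.ndarray, d_p: float, alpha: float) -> float:
    """log(LTCP) via log-sum-exp; safe for alpha * D_p of order 50."""
    d = _require_nonempty(doses)
    return float(logsumexp(-alpha * (d - d_p)) - np.log(d.size))


def eud(doses: np.ndarray, k: float) -> float:
    """Equivalent uniform dose, the power mean of exponent ``k >= 1``.

    Computed in a max-scaled form so large exponents (k = 64) do not
    overflow; zero-dose voxels are legal (0**k = 0).
    """
    if k < 1:
        raise ValueError(f"EUD volume-effect exponent must be >= 1, got {k}")
    d = _require_nonempty(doses)
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    if k == 1:
        return float(d.mean())
    top = d.max()
    if top == 0:
        return 0.0
    return float(top * np.mean((d / top) ** k) ** (1.0 / k))


def max_dose(doses: np.ndarray) -> float:
    return float(_require_nonempty(doses).max())


def mean_dose(doses: np.ndarray) -> float:
    return float(_require_nonempty(doses).mean())


def evaluate(spec: CostSpec, doses: np.ndarray) -> float:
    """Evaluate any cost spec on the masked dose values."""
    if spec.kind == "LTCP":
        return ltcp(doses, spec.d_p, spec.alpha)
    if spec.kind == "EUD":
        return eud(doses, spec.k)
    if spec.kind == "MAX":
        return max_dose(doses)
    return mean_dose(doses)
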