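"""Closed-form mechanics of an entropic-plus-Hookean protein tether.

The end-to-end distance ``x`` of the tethered molecule under an applied
force ``F`` is modelled as a saturating entropic term plus a linear
(enthalpic) spring::

    x(F) = x_E / (1 + F_half / F) + F / K

``x_E`` is the maximal entropic extension (nm): the length gained by
straightening thermal undulations, interdomain linkers and any unfolded
polypeptide.  ``F_half`` (pN) is the force at which the entropic extension
is half complete, and ``K`` (pN/nm) is the enthalpic stiffness that
dominates above ~30 pN.

Unit convention used throughout the package: forces in pN, lengths in nm,
stiffnesses in pN/nm.  Numerically 1 pN/nm == 1 mN/m, so stiffness values
can be read directly in the mN/m units conventional for gating springs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FitParams",
    "StiffnessValue",
    "extension_at_force",
    "invert_extension",
    "series_stiffness",
    "scaled_stiffness",
    "contour_gain",
    "NM_PER_RESIDUE",
    "FOLDED_DOMAIN_LENGTH_NM",
    "KBT_PN_NM",
]

#: Contour length contributed per amino acid of unfolded polypeptide (nm).
NM_PER_RESIDUE = 0.40

#: End-to-end length of a folded cadherin domain, lost when it unfolds (nm).
FOLDED_DOMAIN_LENGTH_NM = 4.5

#: Thermal energy at room temperature (pN nm).
KBT_PN_NM = 4.11


@dataclass(frozen=True)
class FitParams:
    """Parameters of the saturation-plus-spring force-extension model.

    Attributes
    ----------
    x_e : float
        Maximal entropic extension, nm.  Must be positive.
    f_half : float
        Half-saturation force, pN.  Must be positive.
    k : float
        Enthalpic (Hookean) stiffness, pN/nm (== mN/m).  Must be positive.
    resid_rms : float, optional
        Root-mean-square residual of the fit that produced these
        parameters, nm.
    n_points : int, optional
        Number of samples in that fit.
    """

    x_e: float
    f_half: float
    k: float
    resid_rms: Optional[float] = None
    n_points: Optional[int] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_e) and self.x_e > 0):
            raise ValueError(f"x_e must be positive and finite, got {self.x_e}")
        if not (np.isfinite(self.f_half) and self.f_half > 0):
            raise ValueError(f"f_half must be positive and finite, got {self.f_half}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be positive and finite, got {self.k}")
        if self.resid_rms is not None and self.resid_rms < 0:
            raise ValueError("resid_rms must be non-negative")
        if self.n_points is not None and self.n_points < 0:
            raise ValueError("n_points must be non-negative")

    def with_extra_contour(self, gain_nm: float) -> "FitParams":
        """Return parameters with ``gain_nm`` added to the entropic extension.

        Used by the simulator: unfolding a structural unit releases contour
        length that enlarges ``x_E`` while leaving ``F_half`` and ``K``
        unchanged.
        """
        return FitParams(self.x_e + gain_nm, self.f_half, self.k)


@dataclass(frozen=True)
class StiffnessValue:
    """A stiffness estimate in pN/nm (== mN/m) with optional uncertainty.

    ``sem`` is the standard error of the mean over ``n`` independent
    determinations.
    """

    value: float
    sem: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value) and self.value > 0):
            raise ValueError(f"stiffness must be positive and finite, got {self.value}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be non-negative")


def _as_stiffness(k: "StiffnessValue | float") -> float:
    value = k.value if isinstance(k, StiffnessValue) else float(k)
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"stiffness must be positive and finite, got {value}")
    return value


def extension_at_force(params: FitParams, force):
    """End-to-end extension (nm) at applied force ``force`` (pN).

    Evaluates ``x_E / (1 + F_half/F) + F/K``.  At ``F == 0`` the continuous
    limit 0 is returned rather than raising on the division.  Accepts a
    scalar or array of forces; forces must be finite and non-negative.
    """
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("force must be finite")
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    # x_E/(1 + F_half/F) rewritten as x_E*F/(F + F_half): continuous at F=0.
    x = params.x_e * f / (f + params.f_half) + f / params.k
    return x if x.ndim else float(x)


def invert_extension(params: FitParams, x: float, f_max: float = 1e4) -> float:
    """Force (pN) at which the model extension equals ``x`` (nm).

    The model is strictly increasing in force, so the root is unique; it is
    found by bracketed root-finding on [0, ``f_max``] with a tolerance of
    1e-9 nm in extension.
    """
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"extension must be non-negative and finite, got {x}")
    if x == 0.0:
        return 0.0
    x_hi = extension_at_force(params, f_max)
    if x >= x_hi:
        raise ValueError(f"extension {x} nm outside invertible range (< {x_hi:.3g} nm)")
    return float(brentq(lambda f: extension_at_force(params, f) - x, 0.0, f_max, xtol=1e-12, rtol=1e-14))


def series_stiffness(*springs: "StiffnessValue | float") -> StiffnessValue:
    """Combined stiffness of springs in series: 1/K_total = sum(1/K_i).

    The tip link is a PCDH15 dimer in series with a CDH23 dimer, so its
    stiffness is the series combination of the two.  Symmetric in its
    arguments and never exceeds the softest spring.
    """
    if len(springs) < 2:
        raise ValueError("series_stiffness needs at least two springs")
    compliance = sum(1.0 / _as_stiffness(k) for k in springs)
    return StiffnessValue(1.0 / compliance)


def scaled_stiffness(k: "StiffnessValue | float", length_ratio: float) -> StiffnessValue:
    """Stiffness of a mechanically similar molecule ``length_ratio`` times longer.

    For identical material, stiffness is inversely proportional to contour
    length: a filament 2.3 times as long is 2.3 times as compliant.
    """
    if not (np.isfinite(length_ratio) and length_ratio > 0):
        raise ValueError(f"length_ratio must be positive, got {length_ratio}")
    return StiffnessValue(_as_stiffness(k) / length_ratio)


def contour_gain(n_residues: int, folded_length: float = FOLDED_DOMAIN_LENGTH_NM) -> float:
    """Contour length (nm) released by unfolding ``n_residues`` amino acids.

    Computed as 0.40 nm per residue, less the end-to-end length of the
    folded structure that is lost (4.5 nm for a complete cadherin domain;
    pass 0 for an unstructured linker), floored at zero.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    if folded_length < 0:
        raise ValueError("folded_length must be non-negative")
    return max(NM_PER_RESIDUE * n_residues - folded_length, 0.0)
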