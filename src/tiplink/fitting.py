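"""Fitting the saturation-plus-spring model to force-extension data.

The central object is :class:`SaturationSpring`, a model in the
statsmodels mould: it is constructed from observed (force, extension)
samples together with a fixed enthalpic stiffness K, and its
:meth:`~SaturationSpring.fit` returns a :class:`SaturationSpringResults`
carrying the estimates of the two free parameters (the maximal entropic
extension x_E and the half-saturation force F_half), their standard
errors, residual diagnostics and a ``summary()`` table.

K is not fitted jointly: it is estimated once per experimental condition
from the high-force slope of all cycles (:func:`enthalpic_stiffness`) and
then held fixed for every per-segment and per-phase fit of that
condition.  The joint three-parameter fit is poorly identified because
within a single segment the linear term is nearly collinear with the
tail of the saturation term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.signal import savgol_filter

from .containers import PHASE_EXTENSION, ForceRampCycle
from .events import Segment
from .mechanics import FitParams, StiffnessValue, extension_at_force
from .trajectory_io import split_phases

__all__ = [
    "SaturationSpring",
    "SaturationSpringResults",
    "FitError",
    "fit_segment",
    "fit_phase",
    "fit_segments_shared_fhalf",
    "enthalpic_stiffness",
]

MIN_SAMPLES = 10
MIN_FORCE_SPAN = 2.0  # pN


class FitError(RuntimeError):
    """Raised when a segment cannot support a fit (degenerate data or
    non-convergence)."""


class SaturationSpring:
    """Saturation-plus-spring force-extension model for one data span.

    Parameters
    ----------
    force, extension : array-like
        Observed samples, pN and nm.  At least 10 samples spanning at
        least 2 pN of force are required; narrower spans cannot separate
        x_E from F_half and are rejected rather than reported.
    k_enthalpic : float
        Fixed enthalpic stiffness K, pN/nm.
    """

    def __init__(self, force, extension, k_enthalpic: float, name: str = ""):
        force = np.asarray(force, dtype=float)
        extension = np.asarray(extension, dtype=float)
        if force.shape != extension.shape or force.ndim != 1:
            raise ValueError("force and extension must be 1-D arrays of equal length")
        if not (np.isfinite(force).all() and np.isfinite(extension).all()):
            raise ValueError("force and extension must be finite")
        if len(force) < MIN_SAMPLES:
            raise FitError(f"need at least {MIN_SAMPLES} samples, got {len(force)}")
        if np.ptp(force) < MIN_FORCE_SPAN:
            raise FitError(
                f"force span {np.ptp(force):.3g} pN below the {MIN_FORCE_SPAN} pN identifiability floor"
            )
        if k_enthalpic <= 0:
            raise ValueError("k_enthalpic must be positive")
        self.force = force
        self.extension = extension
        self.k = float(k_enthalpic)
        self.name = name

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        k_enthalpic: float,
        force_col: str = "force_pN",
        extension_col: str = "extension_nm",
        name: str = "",
    ) -> "SaturationSpring":
        return cls(df[force_col].to_numpy(), df[extension_col].to_numpy(), k_enthalpic, name=name)

    def predict(self, params: Sequence[float], force=None):
        x_e, f_half = params
        f = self.force if force is None else np.asarray(force, dtype=float)
        return x_e * f / (f + f_half) + f / self.k

    def fit(self, x0: Optional[Tuple[float, float]] = None, f_half_fixed: Optional[float] = None) -> "SaturationSpringResults":
        """Least-squares fit of (x_E, F_half) with K held fixed.

        ``f_half_fixed`` restricts the fit to x_E alone (used by the
        shared-F_half per-phase mode).
        """
        f, x = self.force, self.extension
        # A tether must lengthen with force; a flat or inverted span cannot
        # come from this model and the optimizer would pin x_E at its bound.
        if np.ptp(x) <= 0 or np.corrcoef(f, x)[0, 1] <= 0:
            raise FitError("degenerate segment: extension does not increase with force")
        resid_linear = x - f / self.k
        if x0 is None:
            x0 = (max(float(np.max(resid_linear)), 0.5), 2.0)
        try:
            if f_half_fixed is None:
                popt, pcov = curve_fit(
                    lambda ff, x_e, f_half: x_e * ff / (ff + f_half) + ff / self.k,
                    f,
                    x,
                    p0=x0,
                    bounds=([1e-6, 1e-6], [np.inf, np.inf]),
                    maxfev=10000,
                )
            else:
                popt1, pcov1 = curve_fit(
                    lambda ff, x_e: x_e * ff / (ff + f_half_fixed) + ff / self.k,
                    f,
                    x,
                    p0=(x0[0],),
                    bounds=([1e-6], [np.inf]),
                    maxfev=10000,
                )
                popt = np.array([popt1[0], f_half_fixed])
                pcov = np.array([[pcov1[0, 0], 0.0], [0.0, 0.0]])
        except RuntimeError as err:
            raise FitError(f"fit did not converge: {err}") from err
        resid = x - self.predict(popt)
        return SaturationSpringResults(model=self, params=popt, cov=pcov, resid=resid)


@dataclass
class SaturationSpringResults:
    """Estimates and diagnostics from a :class:`SaturationSpring` fit."""

    model: SaturationSpring
    params: np.ndarray  # (x_E, F_half)
    cov: np.ndarray
    resid: np.ndarray

    @property
    def x_e(self) -> float:
        return float(self.params[0])

    @property
    def f_half(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (x_E, F_half) from the fit covariance."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def resid_rms(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def nobs(self) -> int:
        return len(self.model.force)

    @property
    def rsquared(self) -> float:
        ss_tot = float(np.sum((self.model.extension - self.model.extension.mean()) ** 2))
        if ss_tot == 0:
            return np.nan
        return 1.0 - float(np.sum(self.resid**2)) / ss_tot

    def to_fit_params(self) -> FitParams:
        return FitParams(
            x_e=self.x_e,
            f_half=self.f_half,
            k=self.model.k,
            resid_rms=self.resid_rms,
            n_points=self.nobs,
        )

    def predict(self, force=None):
        return self.model.predict(self.params, force)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Saturation-spring model fit" + (f" [{self.model.name}]" if self.model.name else ""),
            "=" * 44,
            f"{'n samples':<22}{self.nobs:>22}",
            f"{'force span (pN)':<22}{np.ptp(self.model.force):>22.3f}",
            f"{'K fixed (pN/nm)':<22}{self.model.k:>22.3f}",
            "-" * 44,
            f"{'x_E (nm)':<14}{self.x_e:>14.4f}{se[0]:>14.4f}  (SE)",
            f"{'F_half (pN)':<14}{self.f_half:>14.4f}{se[1]:>14.4f}  (SE)",
            "-" * 44,
            f"{'resid RMS (nm)':<22}{self.resid_rms:>22.4f}",
            f"{'R^2':<22}{self.rsquared:>22.5f}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.model.force)
        ax.plot(self.model.force[order], self.model.extension[order], ".", ms=2, alpha=0.4, label="data")
        ax.plot(self.model.force[order], self.predict()[order], "k--", label="fit")
        ax.set_xlabel("Force (pN)")
        ax.set_ylabel("Extension (nm)")
        ax.legend()
        return ax


def fit_segment(cycle: ForceRampCycle, segment: Segment, k_fixed: float) -> FitParams:
    """Fit the model to one between-events segment of a cycle."""
    sl = slice(segment.start, segment.stop)
    model = SaturationSpring(
        cycle.force[sl],
        cycle.extension[sl],
        k_fixed,
        name=f"cycle {cycle.cycle_index} {segment.phase} seg {segment.ordinal}",
    )
    return model.fit().to_fit_params()


def fit_phase(cycle: ForceRampCycle, phase: str, k_fixed: float) -> FitParams:
    """Fit the model to a whole phase, ignoring any internal steps."""
    ext_idx, rel_idx = split_phases(cycle)
    idx = ext_idx if phase == PHASE_EXTENSION else rel_idx
    model = SaturationSpring(
        cycle.force[idx], cycle.extension[idx], k_fixed, name=f"cycle {cycle.cycle_index} {phase}"
    )
    return model.fit().to_fit_params()


def fit_segments_shared_fhalf(
    cycle: ForceRampCycle, segments: Sequence[Segment], k_fixed: float
) -> Tuple[List[Optional[FitParams]], float]:
    """Joint fit of one phase's segments with a single shared F_half.

    One F_half and one x_E per segment are estimated jointly by least
    squares, mirroring the convention of reporting a single F_half for
    the successive segments of a phase.  Sharing F_half is what keeps
    high-force-only segments identifiable: a span that starts above
    ~30 pN cannot separate x_E from F_half on its own, but inherits the
    F_half pinned down by the low-force segment of the same phase.

    Returns a list aligned with ``segments`` (None for segments too short
    or too narrow in force to fit) and the shared F_half.
    """
    if not segments:
        raise ValueError("no segments to fit")
    spans = []
    for pos, seg in enumerate(segments):
        f = cycle.force[seg.start : seg.stop]
        x = cycle.extension[seg.start : seg.stop]
        if len(f) >= MIN_SAMPLES and np.ptp(f) >= MIN_FORCE_SPAN and np.ptp(x) > 0:
            spans.append((pos, f, x))
    if not spans:
        raise FitError("no segment has enough samples/force span for a joint fit")

    def residuals(theta):
        f_half = theta[0]
        out = []
        for (pos, f, x), x_e in zip(spans, theta[1:]):
            out.append(x_e * f / (f + f_half) + f / k_fixed - x)
        return np.concatenate(out)

    theta0 = np.concatenate(([2.0], [max(np.max(x - f / k_fixed), 0.5) for _, f, x in spans]))
    sol = least_squares(residuals, theta0, bounds=(1e-6, np.inf))
    if not sol.success:
        raise FitError(f"joint fit did not converge: {sol.message}")
    f_half = float(sol.x[0])
    params: List[Optional[FitParams]] = [None] * len(segments)
    for (pos, f, x), x_e in zip(spans, sol.x[1:]):
        resid = x_e * f / (f + f_half) + f / k_fixed - x
        params[pos] = FitParams(
            x_e=float(x_e),
            f_half=f_half,
            k=k_fixed,
            resid_rms=float(np.sqrt(np.mean(resid**2))),
            n_points=len(f),
        )
    return params, f_half


def _phase_determinations(
    force: np.ndarray,
    extension: np.ndarray,
    force_threshold: float,
    grid_spacing: float,
    sg_window: int,
) -> Optional[float]:
    """One stiffness determination: mean inverse slope above the threshold."""
    mask = force > force_threshold
    if mask.sum() < MIN_SAMPLES:
        return None
    f = force[mask]
    x = extension[mask]
    order = np.argsort(f)
    f, x = f[order], x[order]
    # collapse duplicate forces so np.interp sees a strictly monotone grid
    grid = np.arange(f[0], f[-1] + grid_spacing / 2, grid_spacing)
    if len(grid) < 5:
        return None
    xg = np.interp(grid, f, x)
    window = min(sg_window, len(grid) if len(grid) % 2 else len(grid) - 1)
    if window < 5:
        return None
    deriv = savgol_filter(xg, window_length=window, polyorder=2, deriv=1, delta=grid_spacing)
    valid = deriv > 1e-6
    if valid.sum() < 3:
        return None
    # Median over the grid: robust both to near-zero derivatives (which
    # would explode the inverse) and to unfolding steps inside the
    # high-force span (which inflate the derivative locally).
    return float(np.median(1.0 / deriv[valid]))


def enthalpic_stiffness(
    cycles: Iterable[ForceRampCycle],
    force_threshold: float = 30.0,
    grid_spacing: float = 0.5,
    sg_window: int = 21,
) -> StiffnessValue:
    """High-force (Hookean) stiffness averaged over cycles.

    For every phase of every cycle, the extension is resampled onto a
    uniform force grid above ``force_threshold`` (default 30 pN, where the
    force-extension relation is essentially linear), smoothed and
    differentiated with a Savitzky-Golay filter (quadratic, default
    window 21 grid points), and the inverse derivative is pooled (median)
    over the grid.  Each phase of each cycle contributes one
    determination; the result is the mean with its SEM and the
    determination count.
    """
    values: List[float] = []
    any_cycle = False
    for cycle in cycles:
        any_cycle = True
        ext_idx, rel_idx = split_phases(cycle)
        for idx in (ext_idx, rel_idx):
            det = _phase_determinations(
                cycle.force[idx], cycle.extension[idx], force_threshold, grid_spacing, sg_window
            )
            if det is not None and det > 0:
                values.append(det)
    if not any_cycle:
        raise ValueError("no cycles supplied")
    if not values:
        raise ValueError(f"no phase has enough samples above {force_threshold} pN")
    arr = np.asarray(values)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return StiffnessValue(value=float(arr.mean()), sem=sem, n=len(arr))


def folded_state_stiffness(
    cycles: Iterable[ForceRampCycle],
    quantile: float = 0.9,
    force_threshold: float = 30.0,
    grid_spacing: float = 0.5,
    sg_window: int = 21,
) -> StiffnessValue:
    """Enthalpic stiffness of the folded molecule, from the stiffest cycles.

    Every per-phase inverse-slope determination (as in
    :func:`enthalpic_stiffness`) is softened by the entropic residual of
    whatever material is unfolded during that cycle, so the average over
    all cycles under-reads the folded molecule's spring constant whenever
    unfolding is common.  The cycles with the *least* unfolded material
    give the stiffest determinations, so an upper quantile (default 0.9)
    of the pooled determinations approximates the folded-state K.  This is
    the value held fixed in the saturation-spring fits.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    values: List[float] = []
    for cycle in cycles:
        for idx in split_phases(cycle):
            det = _phase_determinations(
                cycle.force[idx], cycle.extension[idx], force_threshold, grid_spacing, sg_window
            )
            if det is not None and det > 0:
                values.append(det)
    if not values:
        raise ValueError(f"no phase has enough samples above {force_threshold} pN")
    return StiffnessValue(value=float(np.quantile(values, quantile)), n=len(values))
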