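"""Pressure–strain (P–S) loop assembly and elastic-modulus estimation.

Over a cardiac/respiratory cycle the intraluminal pressure p and the
circumferential strain eps of the wall trace a closed loop in the (eps, p)
plane; its mean slope is the pressure–strain elastic modulus E (mmHg per unit
strain), the stiffness measure used to follow graft remodeling. Two
estimators are provided:

``extrema``
    E = (p_max - p_min) / (eps_max - eps_min): the slope through the loop's
    bounding box, the classic two-point pulse-pressure over pulse-strain form.

``loop-fit`` (default)
    A least-squares fit of the whole loop with a first-order viscoelastic
    response: strain is regressed on the centered pressure and on its
    quadrature component (the time derivative of pressure, rescaled to the
    pressure's standard deviation), eps = a + b1*p + b2*q. The reported
    modulus is the dynamic magnitude E = sign(b1) / sqrt(b1^2 + b2^2) — the
    pressure-to-strain amplitude ratio of the loop. Because pressure is the
    accurately measured catheter signal and strain the noisy image-derived
    one, regressing strain on pressure keeps the estimate unbiased under
    strain noise, and the quadrature term absorbs hysteresis so a pure phase
    lag does not bias E. On a noiseless linear zero-lag loop both estimators
    return the exact slope; both scale as E -> cE under p -> cp and
    E -> E/c under eps -> c*eps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateLoopError, ValidationError
from .kinematics import StrainSeries

__all__ = [
    "PressureTrace",
    "PSLoop",
    "ModulusRecord",
    "build_ps_loop",
    "elastic_modulus",
    "modulus_ratio",
]


@dataclass
class PressureTrace:
    """Sampled intraluminal pressure versus time (mmHg; seconds)."""

    timestamps: np.ndarray
    pressures: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) < 2:
            raise ValidationError("timestamps: need at least 2 samples")
        if len(self.timestamps) != len(self.pressures):
            raise ValidationError("pressures: length must match timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps: must be strictly increasing")
        if not np.all(np.isfinite(self.pressures)):
            raise ValidationError("pressures: non-finite values")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class PSLoop:
    """Paired (strain, pressure) samples on a common timebase.

    Multi-cycle acquisitions are pooled into one point cloud; ``cycle_count``
    is bookkeeping metadata when known.
    """

    timestamps: np.ndarray
    strains: np.ndarray
    pressures: np.ndarray
    cycle_count: int | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if not (len(self.timestamps) == len(self.strains) == len(self.pressures)):
            raise ValidationError("ps loop: mismatched array lengths")
        if len(self.strains) < 4:
            raise ValidationError("ps loop: need >= 4 samples")
        if not (np.all(np.isfinite(self.strains)) and np.all(np.isfinite(self.pressures))):
            raise ValidationError("ps loop: non-finite values")

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def strain_range(self) -> float:
        return float(np.ptp(self.strains))

    def enclosed_area(self) -> float:
        """Unsigned shoelace area of the loop in the (strain, pressure) plane.

        Nonzero area is the signature of hysteresis (a phase lag between
        pressure and wall motion); a purely elastic response collapses the
        loop onto a line with zero area.
        """
        x, y = self.strains, self.pressures
        return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


@dataclass
class ModulusRecord:
    """Elastic modulus with its estimation method and subject labels.

    ``E`` is in mmHg per unit strain. ``tissue`` distinguishes the native
    vessel ('native'), the engineered vessel ('itev') and the bare scaffold
    ('scaffold'); ``timepoint`` is months after implantation.
    """

    E: float
    method: str = "loop-fit"
    subject_id: str | None = None
    tissue: str | None = None
    timepoint: float | None = None


def build_ps_loop(strain: StrainSeries, pressure: PressureTrace) -> PSLoop:
    """Synchronize a strain series with a pressure trace into a P–S loop.

    The pressure (the densely sampled signal) is linearly interpolated onto
    the strain timestamps, restricted to the overlapping time window. Strain
    frames outside the pressure record are dropped, never extrapolated.
    """
    t_lo = max(strain.timestamps[0], pressure.timestamps[0])
    t_hi = min(strain.timestamps[-1], pressure.timestamps[-1])
    if t_lo > t_hi:
        raise ValidationError("no temporal overlap between strain and pressure")
    mask = (strain.timestamps >= t_lo) & (strain.timestamps <= t_hi)
    t = strain.timestamps[mask]
    eps = strain.strains[mask]
    p = np.interp(t, pressure.timestamps, pressure.pressures)
    return PSLoop(timestamps=t, strains=eps, pressures=p)


def _loop_fit_slope(t: np.ndarray, eps: np.ndarray, p: np.ndarray) -> float:
    """In-phase + quadrature regression of the loop; returns the modulus.

    The quadrature regressor dp/dt is rescaled to the pressure's standard
    deviation so the fitted (b1, b2) pair lives on a common scale and the
    dynamic magnitude sqrt(b1^2 + b2^2) is the inverse modulus regardless of
    the cycle frequency.
    """
    pc = p - p.mean()
    sd_p = float(np.std(pc))
    if sd_p == 0.0:
        raise DegenerateLoopError("zero pressure variance: degenerate loop")
    q = np.gradient(p, t)
    sd_q = float(np.std(q))
    cols = [np.ones_like(eps), pc]
    if sd_q > 0:
        cols.append(q * (sd_p / sd_q))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, eps, rcond=None)
    b1 = float(beta[1])
    b2 = float(beta[2]) if X.shape[1] == 3 else 0.0
    mag = float(np.hypot(b1, b2))
    if mag == 0.0:
        raise DegenerateLoopError("strain uncorrelated with pressure: degenerate loop")
    sign = 1.0 if b1 >= 0 else -1.0
    return sign / mag


def elastic_modulus(
    loop: PSLoop,
    method: str = "loop-fit",
    subject_id: str | None = None,
    tissue: str | None = None,
    timepoint: float | None = None,
) -> ModulusRecord:
    """Estimate the pressure–strain elastic modulus from a P–S loop.

    Raises DegenerateLoopError when the loop has no strain excursion.
    """
    if method not in ("extrema", "loop-fit"):
        raise ValidationError(f"method: unknown estimator '{method}'")
    eps, p = loop.strains, loop.pressures
    if np.ptp(eps) <= 0:
        raise DegenerateLoopError("zero strain range: degenerate loop")
    if method == "extrema":
        e = float(np.ptp(p) / np.ptp(eps))
    else:
        e = _loop_fit_slope(loop.timestamps, eps, p)
    return ModulusRecord(E=e, method=method, subject_id=subject_id,
                         tissue=tissue, timepoint=timepoint)


def modulus_ratio(e_itev: ModulusRecord, e_native: ModulusRecord) -> float:
    """Stiffness ratio E_T / E_N of the engineered vessel to the native one.

    Both records must be positive and refer to the same timepoint.
    """
    if e_itev.E <= 0 or e_native.E <= 0:
        raise ValidationError("modulus_ratio: both moduli must be positive")
    if e_itev.timepoint != e_native.timepoint:
        raise ValidationError(
            "modulus_ratio: mismatched timepoints "
            f"({e_itev.timepoint} vs {e_native.timepoint})"
        )
    return e_itev.E / e_native.E
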