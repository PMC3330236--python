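"""Ground-truth-known synthetic inputs for every downstream stage.

Three generators and one packaged fixture:

* ``generate_phantom`` — a pulsating thin-walled vessel cross section. The
  intraluminal pressure is sinusoidal, p(t) = mean + A sin(2 pi t / T), and
  the lumen radius follows a first-order (linear) compliance law

      r(t) = r0 * (1 + (p(t - tau) - p_min) / E_true),

  where E_true is the pressure–strain elastic modulus being planted and
  tau = lag / omega a pure phase delay that opens the pressure–strain loop
  into the hysteresis ellipse seen in real acquisitions. With the diastolic
  frame as strain reference the loop slope equals E_true exactly, so the
  whole kinematics → loop → modulus chain can be checked against a closed
  form. Contours are regular polygons on r(t) plus i.i.d. radial noise.

* ``generate_cohort`` — per-animal paired native / engineered-vessel moduli
  across follow-up timepoints, drawn lognormally (moduli are positive)
  around configurable ratio means, with separate between-animal and
  measurement coefficients of variation.

* ``rasterize_frames`` — optional B-mode-like grayscale frames (dark lumen,
  bright wall band, multiplicative speckle) rendered from a contour series.

* ``load_printed_degradation`` — the in-vitro scaffold degradation series
  (tensile strength, weeks 0–9; molecular weight, weeks 0–25), packaged as
  fixed reference data.

All stochastic generators take a mandatory integer seed in their spec and
never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradation import DecaySeries
from .errors import ValidationError
from .frames import FrameStack
from .kinematics import ContourSeries
from .psloop import PressureTrace

__all__ = [
    "VesselPhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "rasterize_frames",
    "generate_cohort",
    "load_printed_degradation",
    "PRINTED_STRENGTH_WEEKS",
    "PRINTED_STRENGTH_N",
    "PRINTED_MW_WEEKS",
    "PRINTED_MW_DA",
]

# In-vitro scaffold degradation reference series (PBS, 37 degrees C):
# tensile strength per cm width (N) and weight-average molecular weight (Da).
PRINTED_STRENGTH_WEEKS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 9.0)
PRINTED_STRENGTH_N = (9.3, 6.9, 5.3, 2.1, 1.2, 0.4, 0.1)
PRINTED_MW_WEEKS = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 13.0, 20.0, 25.0)
PRINTED_MW_DA = (194267.0, 163566.0, 124383.0, 82709.0, 51737.0, 32867.0,
                 8655.0, 6190.0, 4387.0)


@dataclass
class VesselPhantomSpec:
    """Parameters of the pulsating-vessel phantom.

    Defaults describe a caval-vein-like vessel: 8 mm diameter, low venous
    pressure with a small respiratory/cardiac swing, imaged for two cycles.
    Frame rate and acquisition length are free choices of the acquisition,
    not tissue properties, and are fully configurable.
    """

    baseline_radius: float = 4.0          # mm, diastolic lumen radius
    elastic_modulus_true: float = 50.0    # mmHg per unit strain
    pressure_mean: float = 8.0            # mmHg
    pressure_amplitude: float = 2.0       # mmHg, half peak-to-peak
    cycle_period: float = 1.0             # s
    n_frames: int = 60
    frame_rate: float = 30.0              # Hz
    contour_points: int = 64
    noise_sd_contour: float = 0.0         # mm, radial i.i.d. per vertex
    noise_sd_pressure: float = 0.0        # mmHg, i.i.d. per sample
    hysteresis_phase_lag: float = 0.0     # radians, radius lags pressure
    seed: int = 0
    pressure_oversampling: int = 10       # pressure samples per frame interval

    def validate(self) -> None:
        if not self.baseline_radius > 0:
            raise ValidationError("baseline_radius: must be > 0")
        if not self.elastic_modulus_true > 0:
            raise ValidationError("elastic_modulus_true: must be > 0")
        if self.pressure_amplitude < 0:
            raise ValidationError("pressure_amplitude: must be >= 0")
        if self.n_frames < 4:
            raise ValidationError("n_frames: must be >= 4")
        if self.contour_points < 8:
            raise ValidationError("contour_points: must be >= 8")
        if not self.cycle_period > 0:
            raise ValidationError("cycle_period: must be > 0")
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate: must be > 0")
        if self.noise_sd_contour < 0:
            raise ValidationError("noise_sd_contour: must be >= 0")
        if self.noise_sd_pressure < 0:
            raise ValidationError("noise_sd_pressure: must be >= 0")
        if self.pressure_oversampling < 1:
            raise ValidationError("pressure_oversampling: must be >= 1")


@dataclass
class CohortSpec:
    """Parameters of the per-animal paired-modulus cohort.

    Defaults reproduce the published follow-up design: 7 animals, ratio
    means 7.3 (scaffold control at implantation) decaying to ~1 by 2.5
    months. ``between_animal_cv`` scatters both an animal's native modulus
    level and its ratio trajectory; ``measurement_cv`` is per-measurement.
    """

    n_animals: int = 7
    timepoints: tuple = (0.0, 1.0, 2.5, 6.0, 12.0, 24.0)   # months
    modulus_ratio_means: tuple = (7.3, 2.3, 1.1, 1.0, 1.4, 1.1)
    native_modulus_mean: float = 50.0     # mmHg per unit strain
    between_animal_cv: float = 0.10
    measurement_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals: must be >= 1")
        tps = np.asarray(self.timepoints, dtype=float)
        if len(tps) < 1 or np.any(np.diff(tps) <= 0):
            raise ValidationError("timepoints: must be strictly increasing")
        if 0.0 not in tps:
            raise ValidationError("timepoints: must include 0 (implantation baseline)")
        means = np.asarray(self.modulus_ratio_means, dtype=float)
        if len(means) != len(tps):
            raise ValidationError("modulus_ratio_means: one mean per timepoint required")
        if np.any(means <= 0):
            raise ValidationError("modulus_ratio_means: all means must be > 0")
        if not self.native_modulus_mean > 0:
            raise ValidationError("native_modulus_mean: must be > 0")
        for name in ("between_animal_cv", "measurement_cv"):
            cv = getattr(self, name)
            if not 0.0 <= cv < 1.0:
                raise ValidationError(f"{name}: must be in [0, 1)")


def generate_phantom(spec: VesselPhantomSpec) -> tuple[ContourSeries, PressureTrace, dict]:
    """Simulate one pulsating-vessel acquisition.

    Returns (contours, pressure, ground_truth). The pressure trace is sampled
    ``pressure_oversampling`` times per frame interval, so the frame times are
    an exact subset of the pressure times — as with a real pressure catheter,
    pressure is the densely sampled signal. ``ground_truth`` echoes the
    planted modulus and the analytic strain extrema (peak strain relative to
    the diastolic radius is 2 A / E_true).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    omega = 2.0 * np.pi / spec.cycle_period

    t_frames = np.arange(spec.n_frames) / spec.frame_rate
    n_p = (spec.n_frames - 1) * spec.pressure_oversampling + 1
    t_press = np.arange(n_p) / (spec.frame_rate * spec.pressure_oversampling)

    p_min = spec.pressure_mean - spec.pressure_amplitude
    p_clean = spec.pressure_mean + spec.pressure_amplitude * np.sin(omega * t_press)
    p_noisy = p_clean + rng.normal(0.0, spec.noise_sd_pressure, size=n_p) \
        if spec.noise_sd_pressure > 0 else p_clean

    # radius follows the (lagged) pressure through the linear compliance law
    p_at_frames_lagged = spec.pressure_mean + spec.pressure_amplitude * np.sin(
        omega * t_frames - spec.hysteresis_phase_lag
    )
    radii = spec.baseline_radius * (
        1.0 + (p_at_frames_lagged - p_min) / spec.elastic_modulus_true
    )

    angles = 2.0 * np.pi * np.arange(spec.contour_points) / spec.contour_points
    unit = np.column_stack([np.cos(angles), np.sin(angles)])
    contours = []
    for r in radii:
        radial = np.full(spec.contour_points, r)
        if spec.noise_sd_contour > 0:
            radial = radial + rng.normal(0.0, spec.noise_sd_contour,
                                         size=spec.contour_points)
        contours.append(unit * radial[:, None])

    strain_peak = 2.0 * spec.pressure_amplitude / spec.elastic_modulus_true
    ground_truth = {
        "elastic_modulus_true": spec.elastic_modulus_true,
        "baseline_radius": spec.baseline_radius,
        "pressure_min": p_min,
        "pressure_max": spec.pressure_mean + spec.pressure_amplitude,
        "strain_min": 0.0,
        "strain_max": strain_peak,
        "radii": radii,
        "n_cycles": spec.n_frames / spec.frame_rate / spec.cycle_period,
    }
    return (
        ContourSeries(timestamps=t_frames, contours=contours),
        PressureTrace(timestamps=t_press, pressures=p_noisy),
        ground_truth,
    )


def rasterize_frames(
    contours: ContourSeries,
    image_size: int = 128,
    speckle_sd: float = 0.0,
    mm_per_px: float | None = None,
    wall_thickness_mm: float = 1.0,
    seed: int = 0,
) -> FrameStack:
    """Render B-mode-like frames: dark lumen, bright wall band, speckle.

    Intensity at a pixel is a function of its signed distance to the lumen
    contour (negative inside): lumen level inside, wall level within
    ``wall_thickness_mm`` outside, background beyond, with one-pixel linear
    ramps at both edges so the inner wall edge has a well-defined sub-pixel
    gradient maximum. Speckle is multiplicative Gaussian noise of relative
    standard deviation ``speckle_sd``.

    When ``mm_per_px`` is omitted it is chosen so the widest contour plus
    wall band fits with a 10% margin. An explicit ``mm_per_px`` that would
    push any contour (plus wall) outside the image raises ValidationError.
    """
    import shapely

    if image_size < 16:
        raise ValidationError("image_size: must be >= 16")
    if speckle_sd < 0:
        raise ValidationError("speckle_sd: must be >= 0")
    if wall_thickness_mm <= 0:
        raise ValidationError("wall_thickness_mm: must be > 0")

    all_pts = np.vstack(contours.contours)
    lo = all_pts.min(axis=0) - wall_thickness_mm
    hi = all_pts.max(axis=0) + wall_thickness_mm
    span = float(np.max(hi - lo))
    if mm_per_px is None:
        mm_per_px = span * 1.1 / (image_size - 1)
    extent = (image_size - 1) * mm_per_px
    center = (lo + hi) / 2.0
    x0 = float(center[0] - extent / 2.0)
    y0 = float(center[1] - extent / 2.0)
    if (lo[0] < x0 or lo[1] < y0 or hi[0] > x0 + extent or hi[1] > y0 + extent):
        raise ValidationError(
            "mm_per_px: contours (plus wall band) exceed the image bounds"
        )

    lumen_level, wall_level, bg_level = 20.0, 200.0, 60.0
    edge = mm_per_px  # one-pixel transition ramps

    cols, rows = np.meshgrid(np.arange(image_size), np.arange(image_size))
    px = x0 + cols * mm_per_px
    py = y0 + (image_size - 1 - rows) * mm_per_px
    points = shapely.points(px.ravel(), py.ravel())

    rng = np.random.default_rng(seed)
    frames = np.empty((len(contours), image_size, image_size), dtype=np.uint8)
    for i, verts in enumerate(contours.contours):
        poly = shapely.Polygon(verts)
        d = shapely.distance(shapely.get_exterior_ring(poly), points)
        inside = shapely.contains(poly, points)
        signed = np.where(inside, -d, d)

        ramp_in = np.clip(signed / edge + 0.5, 0.0, 1.0)
        ramp_out = np.clip((signed - wall_thickness_mm) / edge + 0.5, 0.0, 1.0)
        img = (lumen_level
               + (wall_level - lumen_level) * ramp_in
               - (wall_level - bg_level) * ramp_out)
        if speckle_sd > 0:
            img = img * (1.0 + rng.normal(0.0, speckle_sd, size=img.shape))
        frames[i] = np.clip(img, 0, 255).reshape(image_size, image_size)

    manifest = {
        "mm_per_px": float(mm_per_px),
        "x0_mm": x0,
        "y0_mm": y0,
        "image_size": int(image_size),
        "wall_thickness_mm": float(wall_thickness_mm),
        "intensity_levels": {"lumen": lumen_level, "wall": wall_level,
                             "background": bg_level},
        "speckle_sd": float(speckle_sd),
        "seed": int(seed),
        "frame_sources": list(range(len(contours))),
    }
    return FrameStack(frames=frames, timestamps=contours.timestamps.copy(),
                      manifest=manifest)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format cohort table of paired native / engineered moduli.

    One row per animal x timepoint x tissue with columns ``animal_id``,
    ``timepoint_months``, ``tissue`` ('native' | 'itev') and ``modulus``
    (mmHg per unit strain). Per animal, a lognormal level factor (its native
    stiffness) and a lognormal ratio factor (its trajectory offset) are drawn
    once with ``between_animal_cv``; every individual measurement then gets
    an independent lognormal factor with ``measurement_cv``. Month-0 rows are
    always present so regeneration scores are computable per animal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tps = np.asarray(spec.timepoints, dtype=float)
    ratios = np.asarray(spec.modulus_ratio_means, dtype=float)

    level = _lognormal_factors(rng, spec.between_animal_cv, spec.n_animals)
    ratio_offset = _lognormal_factors(rng, spec.between_animal_cv, spec.n_animals)

    rows = []
    for a in range(spec.n_animals):
        animal = f"animal_{a + 1:02d}"
        for tp, ratio in zip(tps, ratios):
            m_native, m_itev = _lognormal_factors(rng, spec.measurement_cv, 2)
            e_n = spec.native_modulus_mean * level[a] * m_native
            e_t = spec.native_modulus_mean * level[a] * ratio * ratio_offset[a] * m_itev
            rows.append({"animal_id": animal, "timepoint_months": tp,
                         "tissue": "native", "modulus": e_n})
            rows.append({"animal_id": animal, "timepoint_months": tp,
                         "tissue": "itev", "modulus": e_t})
    return pd.DataFrame(rows)


def load_printed_degradation() -> tuple[DecaySeries, DecaySeries]:
    """The packaged in-vitro degradation reference series.

    Returns ``(strength, mw)``: tensile strength (N) at weeks 0–9 and
    weight-average molecular weight (Da) at weeks 0–25, exactly as reported.
    """
    strength = DecaySeries(times=np.array(PRINTED_STRENGTH_WEEKS),
                           values=np.array(PRINTED_STRENGTH_N),
                           quantity="strength_N")
    mw = DecaySeries(times=np.array(PRINTED_MW_WEEKS),
                     values=np.array(PRINTED_MW_DA),
                     quantity="mw_da")
    return strength, mw
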