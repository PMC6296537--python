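"""Forward OCT phantom generation.

Frames are built from the same single-scattering physics the estimators
assume: per A-line,

    I(z) = intensity_scale * beta(z) * mu(z) * exp(-2 * integral_0^z mu du)

plus a noise floor, with optional fully developed speckle as unit-mean
exponential multiplicative noise. Red thrombus is realised purely through a
high attenuation coefficient — its signal-free shadow must *emerge* from the
physics (deep pixels decay to the noise floor) rather than being painted in,
so that downstream estimator behaviour on shadows is meaningful. White
thrombus attenuates mildly and leaves the abluminal wall visible.

With speckle enabled the noise floor is exponentially distributed (the
multiplicative speckle acts on signal + background); with speckle disabled
frames are fully deterministic and match the analytic decay exactly.

Cohorts draw per-patient attenuation/backscatter from class-conditional
normal distributions and derive a ground-truth six-stage grade from the
class and the patient's attenuation tertile. Synthetic observer readings
perturb the true grade by +/-1 step with a configurable confusion
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .oct_io import ObserverReading, PolarFrame, RegionMask

__all__ = [
    "PhantomSpec",
    "ClassEffects",
    "CohortSpec",
    "Cohort",
    "PatientData",
    "simulate_frame",
    "simulate_cohort",
    "simulate_observers",
]

# spec-level defaults for class attenuation (mm^-1) and relative backscatter
MU_DEFAULTS = {"white": 1.2, "red": 4.5}
BETA_DEFAULTS = {"white": 0.20, "red": 0.12}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optical properties and noise model for one phantom frame."""

    thrombus_class: str = "white"  # 'white' | 'red'
    n_alines: int = 96
    n_depth: int = 768
    axial_pitch_mm: float = 0.005
    catheter_offset: int = 20
    lumen_radius_samples: int = 60
    aline_span: tuple[int, int] = (24, 72)  # [start, stop) rows with thrombus
    depth_span: tuple[int, int] = (80, 380)  # [start, stop) thrombus depth
    mu_thrombus: float | None = None  # default by class
    beta_thrombus: float | None = None  # default by class
    mu_wall: float = 0.8
    beta_wall: float = 0.15
    noise_floor: float = 2.0
    speckle: bool = True
    intensity_scale: float = 1023.0
    guidewire: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thrombus_class not in ("white", "red"):
            raise ConfigurationError(f"thrombus_class must be white/red, got {self.thrombus_class}")
        a0, a1 = self.aline_span
        d0, d1 = self.depth_span
        if not (0 <= a0 < a1 <= self.n_alines):
            raise ConfigurationError(f"aline_span {self.aline_span} outside [0, {self.n_alines}]")
        if not (self.catheter_offset <= d0 < d1 <= self.n_depth):
            raise ConfigurationError(
                f"depth_span {self.depth_span} outside "
                f"[{self.catheter_offset}, {self.n_depth}]"
            )
        if not 0 <= self.catheter_offset < self.n_depth:
            raise ConfigurationError("catheter_offset outside depth range")
        if not self.catheter_offset <= self.lumen_radius_samples <= self.n_depth:
            raise ConfigurationError("lumen_radius_samples outside depth range")
        for name in ("mu_thrombus", "beta_thrombus"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mu_wall < 0 or self.beta_wall < 0 or self.noise_floor < 0:
            raise ConfigurationError("mu_wall, beta_wall, noise_floor must be >= 0")

    @property
    def mu(self) -> float:
        return MU_DEFAULTS[self.thrombus_class] if self.mu_thrombus is None else self.mu_thrombus

    @property
    def beta(self) -> float:
        return (
            BETA_DEFAULTS[self.thrombus_class]
            if self.beta_thrombus is None
            else self.beta_thrombus
        )


def analytic_intensity(spec: PhantomSpec) -> np.ndarray:
    """Noise-free forward model: signal component of every pixel.

    Uses the left-Riemann discretisation of the accumulated attenuation,
    exp(-2 * dz * sum_{k<j} mu[k]).
    """
    mu_map = np.zeros((spec.n_alines, spec.n_depth))
    beta_map = np.zeros_like(mu_map)
    a0, a1 = spec.aline_span
    d0, d1 = spec.depth_span
    rows = np.arange(spec.n_alines)
    in_thrombus_rows = (rows >= a0) & (rows < a1)

    # wall everywhere beyond the lumen; thrombus A-lines get the thrombus
    # body first, with wall behind it
    wall_start = np.where(in_thrombus_rows, d1, spec.lumen_radius_samples)
    cols = np.arange(spec.n_depth)
    wall = cols[None, :] >= wall_start[:, None]
    mu_map[wall] = spec.mu_wall
    beta_map[wall] = spec.beta_wall
    thrombus = in_thrombus_rows[:, None] & (cols[None, :] >= d0) & (cols[None, :] < d1)
    mu_map[thrombus] = spec.mu
    beta_map[thrombus] = spec.beta
    # catheter interior carries no tissue signal
    mu_map[:, : spec.catheter_offset] = 0.0
    beta_map[:, : spec.catheter_offset] = 0.0

    if spec.guidewire:
        mid = (a0 + a1) // 2
        mu_map[mid - 1 : mid + 2, :] = 0.0
        beta_map[mid - 1 : mid + 2, :] = 0.0

    dz = spec.axial_pitch_mm
    cum = np.cumsum(mu_map, axis=1) * dz
    cum_exclusive = np.concatenate([np.zeros((spec.n_alines, 1)), cum[:, :-1]], axis=1)
    return spec.intensity_scale * beta_map * mu_map * np.exp(-2.0 * cum_exclusive)


def thrombus_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros((spec.n_alines, spec.n_depth), dtype=bool)
    mask[spec.aline_span[0] : spec.aline_span[1], spec.depth_span[0] : spec.depth_span[1]] = True
    return mask


def simulate_frame(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    frame_id: str = "frame_000",
    patient_id: str = "",
) -> tuple[PolarFrame, RegionMask]:
    """Simulate one polar frame and its ground-truth thrombus mask.

    Deterministic for a fixed spec (seed included); the same seed yields
    bit-identical frames.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    signal = analytic_intensity(spec)
    intensity = signal + spec.noise_floor
    if spec.speckle:
        intensity = intensity * rng.exponential(1.0, size=intensity.shape)
    frame = PolarFrame(
        intensity=intensity,
        axial_pitch_mm=spec.axial_pitch_mm,
        catheter_offset=spec.catheter_offset,
        frame_id=frame_id,
        patient_id=patient_id,
    )
    mask = RegionMask.from_array(thrombus_mask(spec), frame_id=frame_id)
    return frame, mask


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ClassEffects:
    """Class-conditional (mean, sd) for per-patient optical properties."""

    mu_white: tuple[float, float] = (1.2, 0.15)
    mu_red: tuple[float, float] = (4.5, 0.5)
    beta_white: tuple[float, float] = (0.20, 0.02)
    beta_red: tuple[float, float] = (0.12, 0.012)

    @classmethod
    def null(cls) -> "ClassEffects":
        """Zero between-class effect: red drawn from the white distributions."""
        return cls(mu_red=cls.mu_white, beta_red=cls.beta_white)

    def params(self, cls_name: str) -> tuple[tuple[float, float], tuple[float, float]]:
        if cls_name == "white":
            return self.mu_white, self.beta_white
        return self.mu_red, self.beta_red


@dataclass(frozen=True)
class CohortSpec:
    """Shape and effect sizes of a simulated patient cohort."""

    n_white: int = 13
    n_red: int = 17
    frames_per_patient: int = 3
    effects: ClassEffects = field(default_factory=ClassEffects)
    confusion_prob: float = 0.1
    frame_template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_white < 0 or self.n_red < 0 or self.n_white + self.n_red == 0:
            raise ConfigurationError("cohort needs at least one patient")
        if not 0 <= self.confusion_prob <= 1:
            raise ConfigurationError("confusion_prob must be in [0, 1]")
        if self.frames_per_patient < 1:
            raise ConfigurationError("frames_per_patient must be >= 1")

    @property
    def n_patients(self) -> int:
        return self.n_white + self.n_red


@dataclass(frozen=True)
class PatientData:
    patient_id: str
    label: str  # 'white' | 'red'
    tas: int
    mu: float
    beta: float
    frames: tuple[PolarFrame, ...]
    masks: tuple[RegionMask, ...]


@dataclass(frozen=True)
class Cohort:
    patients: tuple[PatientData, ...]

    @property
    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.label for p in self.patients}

    @property
    def true_tas(self) -> dict[str, int]:
        return {p.patient_id: p.tas for p in self.patients}


def _true_tas(cls_name: str, mu: float, params: tuple[float, float]) -> int:
    """Class base (1 white / 4 red) plus the attenuation tertile within the
    class distribution, clamped to three levels."""
    mean, sd = params
    q = 0.5 if sd == 0 else 0.5 * (1.0 + math.erf((mu - mean) / (sd * math.sqrt(2.0))))
    step = min(2, int(3.0 * q))
    return (1 if cls_name == "white" else 4) + step


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full cohort of pullbacks with ground truth.

    Patients are interleaved (white/red alternating until one class is
    exhausted) so patient index does not encode the class.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ["white"] * spec.n_white + ["red"] * spec.n_red
    order = rng.permutation(len(classes))
    patients = []
    for idx, pos in enumerate(order):
        cls_name = classes[pos]
        mu_params, beta_params = spec.effects.params(cls_name)
        mu = max(0.05, rng.normal(*mu_params))
        beta = max(0.005, rng.normal(*beta_params))
        pid = f"P{idx:03d}"
        frames, masks = [], []
        for f in range(spec.frames_per_patient):
            frame_spec = replace(
                spec.frame_template,
                thrombus_class=cls_name,
                mu_thrombus=mu,
                beta_thrombus=beta,
            )
            frame, mask = simulate_frame(
                frame_spec, rng=rng, frame_id=f"frame_{f:03d}", patient_id=pid
            )
            frames.append(frame)
            masks.append(mask)
        patients.append(
            PatientData(
                patient_id=pid,
                label=cls_name,
                tas=_true_tas(cls_name, mu, mu_params),
                mu=float(mu),
                beta=float(beta),
                frames=tuple(frames),
                masks=tuple(masks),
            )
        )
    return Cohort(patients=tuple(patients))


def simulate_observers(
    true_tas: Mapping[str, int],
    confusion_prob: float,
    n_observers: int = 2,
    n_sessions: int = 2,
    seed: int = 0,
) -> list[ObserverReading]:
    """Generate observer readings: each reading perturbs the true grade by
    one step (direction uniform) with probability ``confusion_prob``,
    clamped to 1..6."""
    if not 0 <= confusion_prob <= 1:
        raise ConfigurationError("confusion_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    readings = []
    for obs in range(1, n_observers + 1):
        for session in range(1, n_sessions + 1):
            for pid in true_tas:
                tas = int(true_tas[pid])
                if rng.random() < confusion_prob:
                    tas += int(rng.choice([-1, 1]))
                tas = min(6, max(1, tas))
                readings.append(
                    ObserverReading(
                        patient_id=pid,
                        observer_id=f"observer_{obs}",
                        session=session,
                        tas=tas,
                    )
                )
    return readings
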