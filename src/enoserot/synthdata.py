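"""Synthetic MOS sensor-array records for rot-grade classification.

The simulator emulates a 12-sensor metal-oxide array sampling potato
headspace at 1 Hz: a 60 s clean-air pre-clean window, 90 s of sample-gas
injection and 90 s of clean-air recovery (180 recorded points per sensor).
Sensor kinetics follow a double-exponential adsorption/desorption model in
conductivity-ratio space; records are emitted as resistances so that
baseline correction is genuinely exercised downstream.

Two environment modes are provided. ``laboratory`` is near-ideal;
``storage`` adds a class-independent ambient-gas offset (lognormal,
partially shared across sensors) and more measurement noise, which widens
the inter-class overlap of downstream feature ranges — the regime the
class-overlap discretizer is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "SensorSpec",
    "ClassProfile",
    "EnvironmentConfig",
    "RawRecord",
    "default_sensor_specs",
    "default_class_profiles",
    "default_environment",
    "simulate_record",
    "simulate_dataset",
]

CLASS_LABELS = ("normal", "slight", "total")

N_SENSORS = 12
PRECLEAN_SECONDS = 60
INJECTION_SECONDS = 90
CLEANING_SECONDS = 90
RECORD_SECONDS = INJECTION_SECONDS + CLEANING_SECONDS  # 1 Hz sampling

# background-gas adsorption is slower than the analyte's (larger, stickier
# molecules accumulated in the box headspace)
AMBIENT_RISE_TAU = 25.0
AMBIENT_DECAY_TAU = 40.0


@dataclass(frozen=True)
class SensorSpec:
    """One MOS sensor of the array: identity plus clean-air resistance."""

    sensor_id: int  # 1..12
    name: str
    target_note: str
    base_resistance: float  # ohms, clean air

    def __post_init__(self) -> None:
        if not 1 <= self.sensor_id <= N_SENSORS:
            raise ValueError(f"sensor_id must be 1..{N_SENSORS}, got {self.sensor_id}")
        if self.base_resistance <= 0:
            raise ValueError("base_resistance must be > 0")


@dataclass(frozen=True)
class ClassProfile:
    """Response profile of one rot grade.

    ``peak_amplitude[s]`` is the asymptotic conductivity ratio G/G0 the
    sensor with index ``s`` (0-based) approaches during injection; 1 means
    no response. ``rise_tau``/``decay_tau`` are the adsorption and
    desorption time constants in seconds.
    """

    class_label: str
    peak_amplitude: np.ndarray  # shape (12,), dimensionless >= 1
    rise_tau: float = 15.0
    decay_tau: float = 25.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        amp = np.asarray(self.peak_amplitude, dtype=float)
        if amp.shape != (N_SENSORS,):
            raise ValueError(f"peak_amplitude must have shape ({N_SENSORS},)")
        if np.any(amp < 1.0):
            raise ValueError("peak amplitudes must be >= 1 (no negative responses)")
        object.__setattr__(self, "peak_amplitude", amp)


@dataclass(frozen=True)
class EnvironmentConfig:
    """Acquisition environment: ambient interference and noise levels.

    ``ambient_offset_scale`` sets the magnitude of the additive,
    class-independent conductivity offset produced by background odours;
    ``amplitude_spread`` is the lognormal sigma of per-sample variation of
    the class peak amplitudes (sample-to-sample biological variability).
    """

    environment: str = "laboratory"  # or "storage"
    ambient_offset_scale: float = 0.02
    ambient_shared_sigma: float = 0.15  # lognormal sigma of the shared plume factor
    ambient_sensor_sigma: float = 0.15  # lognormal sigma of the per-sensor factor
    noise_sd: float = 0.01
    drift_rate: float = 0.0  # per-second linear conductivity drift
    amplitude_spread: float = 0.08  # per-sensor lognormal sigma of the response magnitude
    concentration_spread: float = 0.05  # shared lognormal sigma: headspace intensity per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.environment not in ("laboratory", "storage"):
            raise ValueError(f"unknown environment {self.environment!r}")
        for name in ("ambient_offset_scale", "noise_sd", "amplitude_spread",
                     "concentration_spread"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class RawRecord:
    """One sample's acquisition: clean-air window plus recorded resistances."""

    sample_id: str
    class_label: str
    environment: str
    preclean_resistance: np.ndarray  # (12, 60) ohms
    resistance: np.ndarray  # (12, 180) ohms

    def __post_init__(self) -> None:
        self.preclean_resistance = np.asarray(self.preclean_resistance, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.preclean_resistance.shape != (N_SENSORS, PRECLEAN_SECONDS):
            raise ValueError(
                f"preclean_resistance must be ({N_SENSORS}, {PRECLEAN_SECONDS}), "
                f"got {self.preclean_resistance.shape}"
            )
        if self.resistance.shape != (N_SENSORS, RECORD_SECONDS):
            raise ValueError(
                f"resistance must be ({N_SENSORS}, {RECORD_SECONDS}), "
                f"got {self.resistance.shape}"
            )
        if np.any(self.preclean_resistance <= 0) or np.any(self.resistance <= 0):
            raise ValueError(f"record {self.sample_id}: non-positive resistance")


# --- default sensor array ---------------------------------------------------
# Clean-air resistances are order-of-magnitude values typical of the series.

_SENSOR_TABLE = [
    (1, "MQ8", "hydrogen", 10_000.0),
    (2, "TGS2600", "hydrogen, ethanol, methane, isobutane", 45_000.0),
    (3, "TGS2602", "ammonia, hydrogen sulfide", 30_000.0),
    (4, "MQ135", "ammonia, hydrogen sulfide, benzene", 22_000.0),
    (5, "TGS2603", "ethanol, trimethylamine, hydrogen sulfide", 35_000.0),
    (6, "TGS2609", "hydrogen, carbon monoxide", 25_000.0),
    (7, "MQ136", "hydrogen sulfide", 18_000.0),
    (8, "TGS2611", "methane", 40_000.0),
    (9, "TGS2620", "organic solvents, alcohol, methanol", 28_000.0),
    (10, "MQ138", "methylbenzene, acetone, ethanol, methanal", 15_000.0),
    (11, "TGS2610", "propane, butane", 50_000.0),
    (12, "TGS2612", "methane, propane, butane", 55_000.0),
]


def default_sensor_specs() -> list[SensorSpec]:
    """The 12-sensor array used by the default simulator."""
    return [SensorSpec(i, n, t, r) for i, n, t, r in _SENSOR_TABLE]


# Per-class asymptotic conductivity ratios for the 12 sensors (S1..S12).
# Laboratory anchors: S4 = (1.11, 1.27, 2.05) and S5 = (1.39, 1.73, 2.67);
# storage anchor: S8 = (1.71, 2.01, 3.03). Sensors without a quantitative
# anchor follow the qualitative selectivity pattern: alcohol-sensitive
# sensors (S2, S5, S9) respond to every grade with a rising trend;
# hydrogen/ketone sensors (S1, S4, S8, S10) respond weakly to normal
# samples and strongly to rot; the sulfide sensor S3 and the high-detection-
# limit alkane sensors S11/S12 respond mainly to total rot.
_LAB_PEAKS = {
    #        normal slight total
    1: (1.08, 1.22, 1.95),
    2: (1.30, 1.60, 2.40),
    3: (1.02, 1.04, 1.80),
    4: (1.11, 1.27, 2.05),
    5: (1.39, 1.73, 2.67),
    6: (1.10, 1.20, 1.70),
    7: (1.08, 1.18, 1.85),
    8: (1.12, 1.30, 2.10),
    9: (1.35, 1.65, 2.50),
    10: (1.10, 1.25, 2.00),
    11: (1.03, 1.06, 1.60),
    12: (1.02, 1.05, 1.50),
}

# In storage the responses of S1-S10 to normal and slightly rotten samples
# are clearly elevated by ambient gases while totally rotten samples change
# little, compressing the inter-class gaps (but never inverting the class
# ordering); weakly responding sensors are elevated proportionally less.
# S8 is placed exactly at its storage anchor.
_STORAGE_ELEVATION = {s: (0.45, 0.35, 0.10) for s in (1, 2, 4, 5, 9, 10)}
_STORAGE_ELEVATION[3] = (0.10, 0.09, 0.05)
_STORAGE_ELEVATION[6] = (0.30, 0.25, 0.08)
_STORAGE_ELEVATION[7] = (0.30, 0.25, 0.08)
_STORAGE_ELEVATION[8] = (0.45, 0.35, 0.10)  # replaced by the anchor below
_STORAGE_ELEVATION[11] = (0.05, 0.04, 0.02)
_STORAGE_ELEVATION[12] = (0.05, 0.04, 0.02)
_STORAGE_S8 = (1.71, 2.01, 3.03)


def default_class_profiles(environment: str = "laboratory") -> dict[str, ClassProfile]:
    """Default per-class response profiles for an environment mode."""
    peaks = np.zeros((3, N_SENSORS))
    for s in range(1, N_SENSORS + 1):
        lab = np.array(_LAB_PEAKS[s])
        if environment == "storage":
            if s == 8:
                vals = np.array(_STORAGE_S8)
            else:
                vals = lab + np.array(_STORAGE_ELEVATION[s])
        elif environment == "laboratory":
            vals = lab
        else:
            raise ValueError(f"unknown environment {environment!r}")
        peaks[:, s - 1] = vals
    return {
        label: ClassProfile(label, peaks[k]) for k, label in enumerate(CLASS_LABELS)
    }


def default_environment(environment: str = "laboratory", seed: int = 0) -> EnvironmentConfig:
    """Default acquisition settings per mode.

    Storage mode carries a substantially larger ambient offset (background
    odours of surrounding produce) and doubled noise.
    """
    if environment == "laboratory":
        return EnvironmentConfig("laboratory", ambient_offset_scale=0.02,
                                 noise_sd=0.01, drift_rate=0.0,
                                 concentration_spread=0.05, seed=seed)
    if environment == "storage":
        return EnvironmentConfig("storage", ambient_offset_scale=0.45,
                                 noise_sd=0.02, drift_rate=5e-5,
                                 concentration_spread=0.25, seed=seed)
    raise ValueError(f"unknown environment {environment!r}")


def _response_curve(amplitude: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Noise-free conductivity-ratio curves, shape (12, 180).

    Saturating-exponential rise toward ``amplitude`` over the 90 s injection,
    exponential decay back toward 1 over the 90 s cleaning phase.
    """
    t = np.arange(RECORD_SECONDS, dtype=float)
    rise = 1.0 + (amplitude[:, None] - 1.0) * (1.0 - np.exp(-t[None, :] / rise_tau))
    x_end = 1.0 + (amplitude - 1.0) * (1.0 - np.exp(-INJECTION_SECONDS / rise_tau))
    decay = 1.0 + (x_end[:, None] - 1.0) * np.exp(
        -(t[None, :] - INJECTION_SECONDS) / decay_tau
    )
    return np.where(t[None, :] < INJECTION_SECONDS, rise, decay)


def simulate_record(
    class_label: str,
    env: EnvironmentConfig,
    profiles: dict[str, ClassProfile] | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample-0",
    sensors: list[SensorSpec] | None = None,
) -> RawRecord:
    """Simulate one acquisition of a sample of the given rot grade.

    The conductivity-ratio curve x(t) is built from the class profile,
    scaled by a per-sample lognormal amplitude factor, offset by the
    class-independent ambient interference, perturbed by Gaussian noise and
    optional linear drift, then converted to resistance via each sensor's
    clean-air base resistance. The 60 s pre-clean window records clean-air
    resistance with the same noise level.
    """
    if profiles is None:
        profiles = default_class_profiles(env.environment)
    if class_label not in profiles:
        raise ValueError(f"unknown class label {class_label!r}")
    if rng is None:
        rng = np.random.default_rng(env.seed)
    if sensors is None:
        sensors = default_sensor_specs()
    prof = profiles[class_label]

    # per-sample spread of the response magnitude: a shared concentration
    # factor (how much headspace gas actually reaches the chamber — tightly
    # controlled in the laboratory protocol, highly variable in storage)
    # times an independent per-sensor biological factor
    conc = rng.normal() if env.concentration_spread > 0 else 0.0
    per = rng.normal(size=N_SENSORS) if env.amplitude_spread > 0 else np.zeros(N_SENSORS)
    spread = np.exp(env.concentration_spread * conc + env.amplitude_spread * per)
    amplitude = 1.0 + (prof.peak_amplitude - 1.0) * spread

    x = _response_curve(amplitude, prof.rise_tau, prof.decay_tau)

    # ambient interference: background gases are pumped in with the sample
    # stream, so the class-independent offset follows adsorption/desorption
    # kinetics of its own (slower than the analyte's) instead of being a
    # constant shift; its amplitude is lognormal per sample and per sensor
    # with a shared component (one background plume reaches all sensors)
    shared = rng.normal()
    per_sensor = rng.normal(size=N_SENSORS)
    amb = env.ambient_offset_scale * np.exp(
        env.ambient_shared_sigma * shared + env.ambient_sensor_sigma * per_sensor)
    x = x + (_response_curve(1.0 + amb, AMBIENT_RISE_TAU, AMBIENT_DECAY_TAU) - 1.0)

    t = np.arange(RECORD_SECONDS, dtype=float)
    if env.drift_rate:
        x = x + env.drift_rate * t[None, :]
    if env.noise_sd > 0:
        x = x + rng.normal(scale=env.noise_sd, size=x.shape)
    # keep the implied response physical (conductivity must stay positive)
    np.clip(x, max(1e-3, 1.0 - 3.0 * env.noise_sd - 0.05), None, out=x)

    base = np.array([s.base_resistance for s in sensors])
    # clean-air window: x ~ 1 plus noise
    pre = np.ones((N_SENSORS, PRECLEAN_SECONDS))
    if env.noise_sd > 0:
        pre = pre + rng.normal(scale=env.noise_sd, size=pre.shape)
    pre = np.clip(pre, 1e-3, None)

    return RawRecord(
        sample_id=sample_id,
        class_label=class_label,
        environment=env.environment,
        preclean_resistance=base[:, None] / pre,
        resistance=base[:, None] / x,
    )


def simulate_dataset(
    n_per_class: int = 100,
    env: EnvironmentConfig | None = None,
    seed: int = 0,
    profiles: dict[str, ClassProfile] | None = None,
) -> list[RawRecord]:
    """Simulate a balanced dataset of ``3 * n_per_class`` records.

    Records are shuffled deterministically by ``seed``; sample ids encode
    environment, class and replicate index.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if env is None:
        env = default_environment("laboratory", seed=seed)
    rng = np.random.default_rng(seed)
    records = []
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            sid = f"{env.environment[:4]}-{label}-{i:03d}"
            records.append(
                simulate_record(label, env, profiles=profiles, rng=rng, sample_id=sid)
            )
    order = np.random.default_rng(seed + 1).permutation(len(records))
    return [records[i] for i in order]
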