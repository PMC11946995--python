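"""Synthetic vibroacoustic recordings and tracking trajectories.

No public recordings of cadaveric sweep responses exist, so this module
provides a seeded generator with the statistical structure the detection
method assumes.  The bone-implant transfer path is modeled as a small set of
damped resonant modes (per-specimen jittered); a loose screw changes the path
by (i) downshifting and under-damping the modes, (ii) adding odd-harmonic
"rattle" distortion, and (iii) adding broadband high-frequency content — the
loose condition thereby carries more high-frequency and more distributed
spectral energy, which is the empirically reported signature the classifier
must pick up.  A single ``separation`` scalar in [0, 1] scales all
loose-vs-fixed contrasts; at 0 the two conditions are distributionally
identical (a built-in null).

Flexion-extension trajectories for the tracking-based validation statistic
are synthesized as a cyclic angular motion (default 5 deg/s over 30 cycles)
with a condition-dependent relative implant-vertebra displacement plus
tracking noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.signal import butter, fftconvolve, sawtooth, sosfilt

from .excitation import (
    DatasetManifest,
    ExcitationConfig,
    Recording,
    RecordingMeta,
    generate_sweep,
    manifest_from_records,
    write_recording,
)
from .loosening import TrackedTrajectory

__all__ = [
    "Mode",
    "ModeSet",
    "SpecimenProfile",
    "ConditionEffect",
    "StudyDesign",
    "TrajectorySimConfig",
    "sample_specimen_profile",
    "impulse_response",
    "simulate_recording",
    "generate_recordings",
    "generate_dataset",
    "in_memory_dataset",
    "simulate_trajectories",
    "high_band_energy_fraction",
]


@dataclass(frozen=True)
class Mode:
    """One damped resonance of the bone-implant transfer path."""

    center_frequency: float  # Hz
    damping_ratio: float  # dimensionless, in (0.005, 0.2)
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not 20.0 < self.center_frequency < 4000.0:
            raise ValueError(
                f"mode frequency must lie in (20, 4000) Hz, got {self.center_frequency}"
            )
        if not 0.005 < self.damping_ratio < 0.2:
            raise ValueError(
                f"damping ratio must lie in (0.005, 0.2), got {self.damping_ratio}"
            )


@dataclass(frozen=True)
class ModeSet:
    """A transfer path as a sum of >= 3 damped modes."""

    modes: tuple[Mode, ...]

    def __post_init__(self) -> None:
        if len(self.modes) < 3:
            raise ValueError(f"a ModeSet needs >= 3 modes, got {len(self.modes)}")

    def __iter__(self):
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)


# Baseline modes loosely spanning the excited band and its first overtones;
# magnitudes are free parameters of the generator, not measured values.
_BASE_MODES = (
    Mode(90.0, 0.030, 1.0),
    Mode(150.0, 0.025, 0.8),
    Mode(240.0, 0.035, 0.7),
    Mode(380.0, 0.040, 0.5),
    Mode(520.0, 0.050, 0.35),
    Mode(760.0, 0.060, 0.2),
    Mode(1100.0, 0.070, 0.1),
)


@dataclass(frozen=True)
class SpecimenProfile:
    """Per-specimen transfer path: jittered modes and a bone-quality factor."""

    specimen_id: int
    modes: ModeSet
    bone_quality_factor: float
    rng_seed: int


@dataclass(frozen=True)
class ConditionEffect:
    """How loosening perturbs the transfer path.

    All contrasts scale linearly with ``separation``; 0 makes loose and fixed
    indistinguishable, 1 applies the full default contrast.
    """

    mode_shift: float = -0.12  # fractional frequency change when loose
    damping_scale: float = 0.6  # damping multiplier when loose (<1: ringier)
    rattle_gain: float = 0.15  # odd-harmonic waveshaping amplitude
    broadband_hf_gain: float = 0.08  # high-passed noise, relative to signal RMS
    separation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError(f"separation must lie in [0, 1], got {self.separation}")

    def loose_params(self) -> tuple[float, float, float, float]:
        """(freq shift, damping multiplier, rattle, hf gain) at this separation."""
        s = self.separation
        return (
            s * self.mode_shift,
            1.0 + s * (self.damping_scale - 1.0),
            s * self.rattle_gain,
            s * self.broadband_hf_gain,
        )


@dataclass(frozen=True)
class StudyDesign:
    """The measurement campaign layout; defaults match the cadaver study
    (4 specimens x 2 screws x 2 conditions x 50 sweeps = 800 recordings)."""

    n_specimens: int = 4
    screws_per_specimen: int = 2
    sweeps_per_screw: int = 50
    conditions: tuple[str, ...] = ("fixed", "loose")
    noise_snr_db: float = 30.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1 or self.screws_per_specimen < 1 or self.sweeps_per_screw < 1:
            raise ValueError("design counts must be >= 1")

    @property
    def n_recordings(self) -> int:
        return (
            self.n_specimens
            * self.screws_per_specimen
            * len(self.conditions)
            * self.sweeps_per_screw
        )


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Cyclic flexion-extension trajectory generator settings.

    The biomechanical protocol is emulated only through its kinematic
    parameters: angular speed 5 deg/s, 30-50 cycles, torque-limited endpoints
    represented by a fixed range of motion.
    """

    n_cycles: int = 30
    angular_speed: float = 5.0  # deg/s
    base_relative_amplitude: float = 0.5  # mm, fixed-condition toggling
    loosening_gain: float = 4.0  # relative-movement multiplier when loose
    tracking_noise_sd: float = 0.05  # mm per axis
    sample_rate: float = 30.0  # Hz
    range_of_motion: float = 15.0  # deg, flexion-extension endpoint
    standoff: float = 40.0  # mm, marker offset between rod and vertebra points

    def __post_init__(self) -> None:
        if self.loosening_gain <= 1.0:
            raise ValueError(
                f"loosening_gain must exceed 1 for a loose scenario, got {self.loosening_gain}"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def _rng(*tags: int) -> np.random.Generator:
    """Counter-based derivation: one master seed, integer tag path."""
    return np.random.default_rng(np.random.SeedSequence(list(tags)))


def sample_specimen_profile(specimen_id: int, master_seed: int) -> SpecimenProfile:
    """Draw a specimen's transfer path deterministically from (id, seed)."""
    rng = _rng(master_seed, 101, specimen_id)
    modes = []
    for m in _BASE_MODES:
        f = m.center_frequency * float(np.exp(rng.normal(0.0, 0.08)))
        z = m.damping_ratio * float(np.exp(rng.normal(0.0, 0.15)))
        g = m.gain * float(np.exp(rng.normal(0.0, 0.2)))
        modes.append(
            Mode(
                center_frequency=float(np.clip(f, 20.001, 3999.999)),
                damping_ratio=float(np.clip(z, 0.0051, 0.1999)),
                gain=g,
            )
        )
    bq = float(rng.uniform(0.8, 1.3))
    return SpecimenProfile(
        specimen_id=specimen_id,
        modes=ModeSet(tuple(modes)),
        bone_quality_factor=bq,
        rng_seed=master_seed,
    )


def impulse_response(
    modes: ModeSet, sample_rate: float, length: int
) -> np.ndarray:
    """Sum of exponentially damped sinusoids, one per mode."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    t = np.arange(length) / sample_rate
    h = np.zeros(length)
    for m in modes:
        w0 = 2 * np.pi * m.center_frequency
        wd = w0 * np.sqrt(1.0 - m.damping_ratio**2)
        h += m.gain * np.exp(-m.damping_ratio * w0 * t) * np.sin(wd * t)
    return h


def _condition_modes(
    profile: SpecimenProfile, condition: str, effect: ConditionEffect
) -> ModeSet:
    if condition == "fixed":
        shift, dscale = 0.0, 1.0
    else:
        shift, dscale, _, _ = effect.loose_params()
    bq = profile.bone_quality_factor
    out = []
    for m in profile.modes:
        out.append(
            Mode(
                center_frequency=float(
                    np.clip(m.center_frequency * (1.0 + shift), 20.001, 3999.999)
                ),
                damping_ratio=float(np.clip(m.damping_ratio * bq * dscale, 0.0051, 0.1999)),
                gain=m.gain,
            )
        )
    return ModeSet(tuple(out))


def _ir_length(modes: ModeSet, sample_rate: float) -> int:
    """Long enough for every mode to decay below 1% of its peak (5 tau)."""
    tau = max(1.0 / (m.damping_ratio * 2 * np.pi * m.center_frequency) for m in modes)
    return min(int(np.ceil(5 * tau * sample_rate)), int(sample_rate))


def simulate_recording(
    sweep: Recording,
    profile: SpecimenProfile | None,
    condition: Literal["fixed", "loose"],
    effect: ConditionEffect | None = None,
    snr_db: float = np.inf,
    seed: int = 0,
    gain_jitter: float = 1.0,
    delay_samples: int = 0,
) -> Recording:
    """Propagate a sweep through a (condition-adjusted) transfer path.

    The sweep is convolved with the modal impulse response; in the loose
    condition, odd-harmonic waveshaping (``rattle_gain``) and high-passed
    broadband noise (``broadband_hf_gain``) are added, each scaled by the
    effect's ``separation``.  Measurement noise is added at ``snr_db``.
    ``profile=None`` selects an identity transfer path (test hook).
    """
    effect = effect or ConditionEffect()
    if condition not in ("fixed", "loose"):
        raise ValueError(f"unknown condition {condition!r}")
    n = len(sweep)
    x = sweep.samples
    if profile is None:
        y = x.copy()
    else:
        modes = _condition_modes(profile, condition, effect)
        ir = impulse_response(modes, sweep.sample_rate, _ir_length(modes, sweep.sample_rate))
        y = fftconvolve(x, ir)[:n]
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(y**2))
        if rms_out > 0:
            y *= rms_in / rms_out
    y = y * gain_jitter

    ss = np.random.SeedSequence(seed)
    rng_hf, rng_meas = (np.random.default_rng(c) for c in ss.spawn(2))

    if condition == "loose":
        _, _, rattle, hf_gain = effect.loose_params()
    else:
        rattle, hf_gain = 0.0, 0.0
    if rattle > 0:
        peak = np.max(np.abs(y)) or 1.0
        y = y + rattle * peak * (y / peak) ** 3
    if hf_gain > 0:
        noise = rng_hf.standard_normal(n)
        sos = butter(4, 600.0, btype="highpass", fs=sweep.sample_rate, output="sos")
        noise = sosfilt(sos, noise)
        noise *= hf_gain * np.sqrt(np.mean(y**2)) / (np.sqrt(np.mean(noise**2)) or 1.0)
        y = y + noise
    if np.isfinite(snr_db):
        sigma = np.sqrt(np.mean(y**2)) * 10.0 ** (-snr_db / 20.0)
        y = y + sigma * rng_meas.standard_normal(n)
    if delay_samples:
        y = np.concatenate([np.zeros(delay_samples), y])[:n]
    peak = np.max(np.abs(y))
    if peak > 0.99:
        y = y * (0.99 / peak)
    return Recording(
        samples=y,
        sample_rate=sweep.sample_rate,
        bit_depth=sweep.bit_depth,
        meta=RecordingMeta(condition=condition),
    )


def _design_digest(design: StudyDesign, effect: ConditionEffect, excitation: ExcitationConfig) -> str:
    blob = repr((asdict(design), asdict(effect), asdict(excitation))).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def generate_recordings(
    design: StudyDesign | None = None,
    effect: ConditionEffect | None = None,
    excitation: ExcitationConfig | None = None,
):
    """Yield every recording of the study design, fully seeded.

    Per-sweep shaker replacement is emulated by a small random gain jitter
    (x U[0.9, 1.1]) and a random onset delay of up to 5 ms.  Every record's
    randomness derives from the master seed and its metadata tuple only, so
    datasets are bit-reproducible and records independent of generation
    order.
    """
    design = design or StudyDesign()
    effect = effect or ConditionEffect()
    sweep = generate_sweep(excitation or ExcitationConfig())
    max_delay = int(0.005 * sweep.sample_rate)
    for spec_id in range(design.n_specimens):
        profile = sample_specimen_profile(spec_id, design.master_seed)
        for screw in range(1, design.screws_per_specimen + 1):
            for ci, condition in enumerate(design.conditions):
                for sweep_idx in range(design.sweeps_per_screw):
                    ss = np.random.SeedSequence(
                        [design.master_seed, 202, spec_id, screw, ci, sweep_idx]
                    )
                    rng = np.random.default_rng(ss)
                    rec_seed = int(rng.integers(0, 2**31 - 1))
                    rec = simulate_recording(
                        sweep,
                        profile,
                        condition,
                        effect,
                        snr_db=design.noise_snr_db,
                        seed=rec_seed,
                        gain_jitter=float(rng.uniform(0.9, 1.1)),
                        delay_samples=int(rng.integers(0, max_delay + 1)),
                    )
                    rec.meta = RecordingMeta(
                        specimen_id=spec_id,
                        screw_id=screw,
                        sensor_id=screw,  # one contact microphone per screw head
                        condition=condition,
                        sweep_index=sweep_idx,
                    )
                    yield rec


def generate_dataset(
    design: StudyDesign | None = None,
    effect: ConditionEffect | None = None,
    out_dir: str | Path = "dataset",
    excitation: ExcitationConfig | None = None,
) -> DatasetManifest:
    """Write the full synthetic study to ``out_dir`` (WAVs + manifest.csv)."""
    design = design or StudyDesign()
    effect = effect or ConditionEffect()
    excitation = excitation or ExcitationConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    records = []
    try:
        for rec in generate_recordings(design, effect, excitation):
            m = rec.meta
            name = (
                f"spec{m.specimen_id}_screw{m.screw_id}_sensor{m.sensor_id}_"
                f"{m.condition}_sweep{m.sweep_index:03d}.wav"
            )
            path = out_dir / name
            write_recording(rec, path)
            written.append(path)
            records.append((str(path), m))
        manifest = manifest_from_records(
            records,
            seed=design.master_seed,
            config_digest=_design_digest(design, effect, excitation),
        )
        manifest.save(out_dir / "manifest.csv")
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def in_memory_dataset(
    design: StudyDesign | None = None,
    effect: ConditionEffect | None = None,
    excitation: ExcitationConfig | None = None,
) -> tuple[DatasetManifest, dict[str, Recording]]:
    """Generate the study without touching disk.

    Returns a manifest whose paths are synthetic ``mem://`` keys plus the
    matching path -> Recording mapping, accepted by the evaluation module.
    """
    design = design or StudyDesign()
    effect = effect or ConditionEffect()
    excitation = excitation or ExcitationConfig()
    records, recordings = [], {}
    for i, rec in enumerate(generate_recordings(design, effect, excitation)):
        m = rec.meta
        key = (
            f"mem://spec{m.specimen_id}_screw{m.screw_id}_{m.condition}_"
            f"sweep{m.sweep_index:03d}"
        )
        records.append((key, m))
        recordings[key] = rec
    manifest = manifest_from_records(
        records,
        seed=design.master_seed,
        config_digest=_design_digest(design, effect, excitation),
    )
    return manifest, recordings


def simulate_trajectories(
    config: TrajectorySimConfig | None = None,
    condition: Literal["fixed", "loose"] = "fixed",
    seed: int = 0,
) -> tuple[TrackedTrajectory, TrackedTrajectory, TrackedTrajectory]:
    """Synthesize (L2, rod1, rod2) reference-point trajectories.

    The construct swings through triangular flexion-extension cycles at the
    configured angular speed.  Each rod point sits at a fixed standoff from
    the L2 point along its own direction, plus a relative displacement
    proportional to the applied angle with amplitude
    ``base_relative_amplitude`` (times ``loosening_gain`` when loose),
    plus i.i.d. per-axis tracking noise on every body.
    """
    config = config or TrajectorySimConfig()
    if condition not in ("fixed", "loose"):
        raise ValueError(f"unknown condition {condition!r}")
    period = 4.0 * config.range_of_motion / config.angular_speed
    duration = config.n_cycles * period
    n = int(round(duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    # triangular angle profile: constant |angular velocity|, torque-limited
    # endpoints emulated as a fixed range of motion
    theta = config.range_of_motion * sawtooth(2 * np.pi * t / period + np.pi / 2, width=0.5)
    theta_rad = np.deg2rad(theta)

    pivot_radius = 50.0  # mm; lever arm of the L2 marker about the loading axis
    pos_l2 = np.column_stack(
        [
            pivot_radius * np.sin(theta_rad),
            pivot_radius * (1.0 - np.cos(theta_rad)),
            np.zeros(n),
        ]
    )
    amp = config.base_relative_amplitude * (
        config.loosening_gain if condition == "loose" else 1.0
    )
    rel = amp * theta / config.range_of_motion  # toggling follows the load
    dirs = {
        "rod1": np.array([0.6, 0.8, 0.0]),
        "rod2": np.array([0.0, 0.8, 0.6]),
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    noise = {
        body: config.tracking_noise_sd * rng.standard_normal((n, 3))
        if config.tracking_noise_sd > 0
        else np.zeros((n, 3))
        for body in ("L2", "rod1", "rod2")
    }
    trajs = {"L2": TrackedTrajectory(t, pos_l2 + noise["L2"], body="L2")}
    for body, u in dirs.items():
        pos = pos_l2 + (config.standoff + rel)[:, None] * u[None, :]
        trajs[body] = TrackedTrajectory(t, pos + noise[body], body=body)
    return trajs["L2"], trajs["rod1"], trajs["rod2"]


def high_band_energy_fraction(rec: Recording, above_hz: float = 600.0) -> float:
    """Fraction of periodogram power above ``above_hz`` — the loose-vs-fixed
    spectral contrast summary."""
    from scipy.signal import periodogram

    f, p = periodogram(rec.samples, fs=rec.sample_rate)
    total = float(np.sum(p))
    if total == 0:
        return 0.0
    return float(np.sum(p[f > above_hz]) / total)
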