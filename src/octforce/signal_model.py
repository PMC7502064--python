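"""Forward model of the spring-loaded piston needle and its spectral OCT signal.

The needle embeds a single-mode fiber facing a sliding brass piston across an
air gap of roughly 1 mm.  Axial tip force compresses an epoxy layer acting as a
spring, so the piston approaches the fiber end and the optical path of the gap
shrinks linearly with force until the piston saturates against its stop.  A
spectral-domain OCT system interrogates the gap: the detector records, per
acquisition, a 1024-sample interferogram whose fringe frequency in wavenumber
encodes the gap length.

The simulator in this module produces raw spectral M-scans paired with the
ground-truth force trace that produced them, emulating a stepper-motor
calibration rig that presses the needle against a flat surface in ramp/release
cycles between 0 N and 1 N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

N_SPECTRAL_SAMPLES = 1024

__all__ = [
    "N_SPECTRAL_SAMPLES",
    "ChirpMap",
    "NeedleModel",
    "RawSpectrum",
    "RawMScan",
    "ForceTrace",
    "CalibrationDataset",
    "force_to_gap",
    "gap_to_force",
    "simulate_spectrum",
    "generate_force_profile",
    "generate_dataset",
    "default_chirp",
    "default_needle",
]


@dataclass(frozen=True)
class ChirpMap:
    """Detector-pixel to wavenumber mapping (1/mm) for 1024 spectral samples.

    Real spectrometers sample the spectrum non-uniformly in wavenumber
    ("chirped"); reconstruction resamples onto the uniform grid spanning the
    same interval.  ``is_uniform`` is True when the spacing is exactly
    constant, in which case dechirping is the identity.
    """

    wavenumbers: np.ndarray
    is_uniform: bool = False

    def __post_init__(self) -> None:
        k = np.asarray(self.wavenumbers, dtype=np.float64)
        object.__setattr__(self, "wavenumbers", k)
        if k.shape != (N_SPECTRAL_SAMPLES,):
            raise ValueError(
                f"chirp map must have {N_SPECTRAL_SAMPLES} wavenumbers, got {k.shape}"
            )
        if not np.all(np.diff(k) > 0):
            raise ValueError("chirp map wavenumbers must be strictly increasing")

    @property
    def uniform_grid(self) -> np.ndarray:
        """The uniform wavenumber grid spanning [k_min, k_max], 1024 points."""
        k = self.wavenumbers
        return np.linspace(k[0], k[-1], k.size)

    @property
    def uniform_spacing(self) -> float:
        k = self.wavenumbers
        return float((k[-1] - k[0]) / (k.size - 1))

    def gap_to_bin(self, gap_mm: float | np.ndarray) -> float | np.ndarray:
        """Depth-profile bin index of a reflector at optical path ``gap_mm``.

        A reflector at single-pass path g produces the fringe cos(2 g k); on
        the uniform grid with spacing dk its DFT peak sits at bin
        N * g * dk / pi.
        """
        return np.asarray(gap_mm) * N_SPECTRAL_SAMPLES * self.uniform_spacing / np.pi

    def bin_to_gap(self, bin_index: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`gap_to_bin` (mm per depth bin)."""
        return np.asarray(bin_index) * np.pi / (N_SPECTRAL_SAMPLES * self.uniform_spacing)


def default_chirp(
    k_center: float = 4797.0,
    dk: float = 0.15,
    distortion: float = 0.15,
) -> ChirpMap:
    """Build the package's default chirp map.

    Parameters
    ----------
    k_center : float
        Central wavenumber in 1/mm.  4797/mm corresponds to a 1310 nm source.
    dk : float
        Mean pixel-to-pixel wavenumber increment (1/mm).  With the default the
        full band spans ~153/mm (~42 nm of bandwidth) and the single-sided
        imaging range is ~10.5 mm over 512 depth bins.
    distortion : float
        Strength of a monotone quadratic deviation from the uniform grid, the
        stand-in for an uncalibrated spectrometer.  0 gives a uniform map.
        Must lie in (-1, 1) to keep the map strictly increasing.
    """
    if not -1.0 < distortion < 1.0:
        raise ValueError("distortion must lie in (-1, 1)")
    n = N_SPECTRAL_SAMPLES
    span = dk * (n - 1)
    u = np.linspace(0.0, 1.0, n)
    # u + a*u*(1-u) is strictly increasing for |a| < 1 and fixes both endpoints
    warped = u + distortion * u * (1.0 - u)
    k = (k_center - span / 2.0) + span * warped
    return ChirpMap(wavenumbers=k, is_uniform=(distortion == 0.0))


def _default_source_spectrum() -> np.ndarray:
    """Gaussian broadband-source envelope over the 1024 pixels (detector counts)."""
    i = np.arange(N_SPECTRAL_SAMPLES, dtype=np.float64)
    centre = (N_SPECTRAL_SAMPLES - 1) / 2.0
    return 1000.0 * np.exp(-0.5 * ((i - centre) / 200.0) ** 2) + 10.0


@dataclass(frozen=True)
class NeedleModel:
    """Physical parameters of one force-sensing needle.

    Parameters
    ----------
    spring_constant : float
        Stiffness of the epoxy spring in N/mm.  The default sweeps 0.3 mm of
        gap over the calibrated 0-1 N range.
    rest_gap : float
        Air-gap optical path at zero force, in mm.
    max_gap_travel : float
        Piston displacement at which the mechanical stop is reached (mm);
        beyond the corresponding force the gap saturates.
    piston_reflectivity : float
        Dimensionless fringe-amplitude factor of the piston face, in (0, 1].
    source_spectrum : ndarray
        1024 non-negative samples of the DC source envelope (detector counts).
    noise_sd : float
        Standard deviation of additive i.i.d. Gaussian detector noise, in the
        same counts as the spectrum.
    coupling_length : float or None
        Characteristic length (mm) of the gap-dependent fiber-recoupling loss:
        light diverging from the fiber end is recollected less efficiently the
        farther the piston sits, so the effective fringe visibility is
        r / (1 + (gap/coupling_length)^2).  ``None`` disables the effect and
        makes the fringe amplitude independent of the gap.
    drift_amplitude, drift_period_s : float
        Optional slow multiplicative source-power drift (sinusoidal), giving
        the DC-spectrum tracker something to follow on long records.
    """

    spring_constant: float = 10.0 / 3.0
    rest_gap: float = 1.0
    max_gap_travel: float = 0.5
    piston_reflectivity: float = 0.3
    source_spectrum: np.ndarray = field(default_factory=_default_source_spectrum)
    noise_sd: float = 5.0
    coupling_length: float | None = 1.2
    drift_amplitude: float = 0.0
    drift_period_s: float = 2.0

    def __post_init__(self) -> None:
        s = np.asarray(self.source_spectrum, dtype=np.float64)
        object.__setattr__(self, "source_spectrum", s)
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.rest_gap <= 0:
            raise ValueError("rest_gap must be positive")
        if self.max_gap_travel <= 0 or self.max_gap_travel >= self.rest_gap:
            raise ValueError("max_gap_travel must lie in (0, rest_gap)")
        if not 0.0 < self.piston_reflectivity <= 1.0:
            raise ValueError("piston_reflectivity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if s.shape != (N_SPECTRAL_SAMPLES,) or np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("source_spectrum must be 1024 finite non-negative samples")
        if self.coupling_length is not None and self.coupling_length <= 0:
            raise ValueError("coupling_length must be positive or None")

    @property
    def saturation_force(self) -> float:
        """Force (N) at which the piston reaches its mechanical stop."""
        return self.spring_constant * self.max_gap_travel

    def fringe_visibility(self, gap_mm: float | np.ndarray) -> float | np.ndarray:
        """Effective fringe-amplitude factor at a given gap."""
        r = self.piston_reflectivity
        if self.coupling_length is None:
            return r * np.ones_like(np.asarray(gap_mm, dtype=np.float64))
        g = np.asarray(gap_mm, dtype=np.float64)
        return r / (1.0 + (g / self.coupling_length) ** 2)

    def to_json(self) -> str:
        d = asdict(self)
        d["source_spectrum"] = self.source_spectrum.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "NeedleModel":
        d = json.loads(text)
        d["source_spectrum"] = np.asarray(d["source_spectrum"], dtype=np.float64)
        return cls(**d)


def default_needle(**overrides) -> NeedleModel:
    """Convenience constructor for the default needle with keyword overrides."""
    return NeedleModel(**overrides)


@dataclass(frozen=True)
class RawSpectrum:
    """A single raw interferogram: 1024 detector counts plus its timestamp."""

    samples: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", s)
        if s.shape != (N_SPECTRAL_SAMPLES,):
            raise ValueError(f"raw spectrum must have {N_SPECTRAL_SAMPLES} samples")
        if not np.all(np.isfinite(s)):
            raise ValueError("raw spectrum samples must be finite")


@dataclass(frozen=True)
class RawMScan:
    """A raw spectral M-scan: 1024 x N_t detector counts over time."""

    spectra: np.ndarray  # (1024, N_t)
    timestamps: np.ndarray  # (N_t,)
    chirp: ChirpMap

    def __post_init__(self) -> None:
        sp = np.asarray(self.spectra, dtype=np.float64)
        ts = np.asarray(self.timestamps, dtype=np.float64)
        object.__setattr__(self, "spectra", sp)
        object.__setattr__(self, "timestamps", ts)
        if sp.ndim != 2 or sp.shape[0] != N_SPECTRAL_SAMPLES:
            raise ValueError(f"M-scan spectra must be {N_SPECTRAL_SAMPLES} x N_t")
        if ts.ndim != 1 or ts.size != sp.shape[1]:
            raise ValueError("timestamps must align with M-scan columns")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_t(self) -> int:
        return self.spectra.shape[1]


@dataclass(frozen=True)
class ForceTrace:
    """Axial tip forces (N) aligned one-to-one with an M-scan's columns."""

    forces: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=np.float64)
        ts = np.asarray(self.timestamps, dtype=np.float64)
        object.__setattr__(self, "forces", f)
        object.__setattr__(self, "timestamps", ts)
        if f.shape != ts.shape or f.ndim != 1:
            raise ValueError("forces and timestamps must be equal-length 1D arrays")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("simulated forces must lie in [0, 1] N")


@dataclass(frozen=True)
class CalibrationDataset:
    """Paired raw M-scan and force trace, with provenance for reproducibility."""

    mscan: RawMScan
    force_trace: ForceTrace
    needle_id: str = "synthetic-0"
    provenance: dict = field(default_factory=dict)
    recon: np.ndarray | None = None  # (512, N_t), filled by reconstruction

    def __post_init__(self) -> None:
        if self.mscan.n_t != self.force_trace.forces.size:
            raise ValueError("M-scan and force trace lengths differ")
        if not np.array_equal(self.mscan.timestamps, self.force_trace.timestamps):
            raise ValueError("M-scan and force trace timestamps differ")

    @property
    def n_t(self) -> int:
        return self.mscan.n_t


def force_to_gap(needle: NeedleModel, force: float | np.ndarray) -> float | np.ndarray:
    """Air-gap optical path (mm) under an axial tip force (N).

    Hooke's law on the epoxy spring, clamped at the piston's mechanical stop:
    g(F) = max(rest_gap - F / spring_constant, rest_gap - max_gap_travel).
    """
    f = np.asarray(force, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    gap = np.maximum(
        needle.rest_gap - f / needle.spring_constant,
        needle.rest_gap - needle.max_gap_travel,
    )
    return float(gap) if np.isscalar(force) else gap


def gap_to_force(needle: NeedleModel, gap: float | np.ndarray) -> float | np.ndarray:
    """Invert :func:`force_to_gap` on the pre-saturation branch."""
    g = np.asarray(gap, dtype=np.float64)
    force = (needle.rest_gap - g) * needle.spring_constant
    out = np.clip(force, 0.0, None)
    return float(out) if np.isscalar(gap) else out


def simulate_spectrum(
    needle: NeedleModel,
    gap: float,
    chirp: ChirpMap,
    rng: np.random.Generator,
    *,
    power_factor: float = 1.0,
    timestamp: float = 0.0,
) -> RawSpectrum:
    """Simulate one raw interferogram for a reflector at the given gap.

    Two-beam spectral-domain interferometer with a single reflector (the
    piston face); autocorrelation and multiple-reflection terms are omitted:

        I(k_i) = p * S(k_i) * (1 + 2 r_eff(g) cos(2 k_i g)) + noise_i

    where S is the source envelope, r_eff the gap-dependent fringe visibility
    (see :class:`NeedleModel`) and p a slow source-power factor.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    k = chirp.wavenumbers
    visibility = needle.fringe_visibility(gap)
    signal = power_factor * needle.source_spectrum * (
        1.0 + 2.0 * visibility * np.cos(2.0 * k * gap)
    )
    if needle.noise_sd > 0:
        signal = signal + rng.normal(0.0, needle.noise_sd, size=k.size)
    return RawSpectrum(samples=signal, timestamp=timestamp)


def generate_force_profile(
    n_samples: int,
    n_ramps: int,
    peak_force: float,
    rng: np.random.Generator,
    *,
    sample_rate_hz: float = 1000.0,
    peak_jitter: float = 0.1,
    sensor_noise_sd: float = 0.002,
) -> ForceTrace:
    """Piecewise-linear press/release force cycles, as a stepper-motor rig produces.

    Each of ``n_ramps`` cycles ramps linearly from 0 N up to a jittered peak
    near ``peak_force`` and back down.  Small Gaussian force-sensor noise is
    added and the trace is clipped to the calibrated [0, 1] N range.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < peak_force <= 1.0:
        raise ValueError("peak_force must lie in (0, 1] N")
    if n_ramps < 1:
        raise ValueError("need at least one ramp cycle")

    # triangular carrier: n_ramps up/down cycles across the record
    phase = np.linspace(0.0, n_ramps, n_samples)
    cycle = np.minimum(phase % 1.0, 1.0 - (phase % 1.0)) * 2.0  # in [0, 1]
    peaks = peak_force * (1.0 - peak_jitter * rng.random(n_ramps + 1))
    peak_per_sample = peaks[np.minimum(phase.astype(int), n_ramps)]
    forces = cycle * peak_per_sample
    if sensor_noise_sd > 0:
        forces = forces + rng.normal(0.0, sensor_noise_sd, size=n_samples)
    forces = np.clip(forces, 0.0, 1.0)
    timestamps = np.arange(n_samples, dtype=np.float64) / sample_rate_hz
    return ForceTrace(forces=forces, timestamps=timestamps)


def generate_dataset(
    needle: NeedleModel,
    chirp: ChirpMap,
    n_samples: int,
    seed: int,
    *,
    n_ramps: int | None = None,
    peak_force: float = 1.0,
    peak_jitter: float = 0.1,
    sensor_noise_sd: float = 0.002,
    sample_rate_hz: float = 1000.0,
    needle_id: str = "synthetic-0",
) -> CalibrationDataset:
    """Simulate a full calibration session: aligned raw M-scan + force trace.

    The acquisition presses the needle against a surface in ``n_ramps``
    triangular cycles (default: one cycle per 2000 samples, at least one),
    converts each instantaneous force to a gap through the spring model and
    renders one raw interferogram per time point.  Fully reproducible from
    ``seed``; all generation parameters are recorded in ``provenance``.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if n_ramps is None:
        n_ramps = max(1, n_samples // 2000)
    rng = np.random.default_rng(seed)
    trace = generate_force_profile(
        max(n_samples, 2),
        n_ramps,
        peak_force,
        rng,
        sample_rate_hz=sample_rate_hz,
        peak_jitter=peak_jitter,
        sensor_noise_sd=sensor_noise_sd,
    )
    if n_samples == 1:  # degenerate single-scan record
        trace = ForceTrace(forces=trace.forces[:1], timestamps=trace.timestamps[:1])
    gaps = force_to_gap(needle, trace.forces)
    if needle.drift_amplitude > 0:
        power = 1.0 + needle.drift_amplitude * np.sin(
            2.0 * np.pi * trace.timestamps / needle.drift_period_s
        )
    else:
        power = np.ones_like(trace.timestamps)

    k = chirp.wavenumbers
    visibility = np.asarray(needle.fringe_visibility(gaps))
    # vectorized over time: (1024, N_t)
    fringes = 1.0 + 2.0 * visibility[None, :] * np.cos(2.0 * np.outer(k, gaps))
    spectra = (power[None, :] * needle.source_spectrum[:, None]) * fringes
    if needle.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, needle.noise_sd, size=spectra.shape)

    mscan = RawMScan(spectra=spectra, timestamps=trace.timestamps, chirp=chirp)
    provenance = {
        "kind": "simulation",
        "seed": int(seed),
        "n_samples": int(n_samples),
        "n_ramps": int(n_ramps),
        "peak_force": float(peak_force),
        "peak_jitter": float(peak_jitter),
        "sensor_noise_sd": float(sensor_noise_sd),
        "sample_rate_hz": float(sample_rate_hz),
        "needle": json.loads(needle.to_json()),
        "chirp_is_uniform": bool(chirp.is_uniform),
        "chirp_k_min": float(k[0]),
        "chirp_k_max": float(k[-1]),
    }
    return CalibrationDataset(
        mscan=mscan, force_trace=trace, needle_id=needle_id, provenance=provenance
    )
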