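"""Spectral-domain OCT A-scan reconstruction.

Maps raw 1024-sample interferograms to 512-sample magnitude depth profiles
through the standard pipeline: (1) dechirp onto a uniform wavenumber grid,
(2) track the DC source spectrum with an exponential moving average,
(3) subtract the DC estimate, (4) apodize with a Hann window, (5) Fourier
transform, (6) keep the magnitude of the 512 non-redundant bins.

The EMA runs over time across successive spectra (fixed-pattern removal): the
DC estimate is a 1024-vector updated once per A-scan.  The update includes the
current scan before subtraction ("update-then-subtract"); on the very first
scan the estimate is initialized to that scan, so its residual — and hence its
A-scan — is exactly zero.  A configurable burn-in (default 200 scans) lets
downstream consumers discard the transient while the estimate converges.

One practical consequence of EMA fixed-pattern removal, faithful to real
systems: if the reflector holds perfectly still, its fringe is eventually
absorbed into the DC estimate and the reconstructed peak fades away.  The
tracker relies on the scene decorrelating faster than 1/damping scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import N_SPECTRAL_SAMPLES, ChirpMap, RawMScan, RawSpectrum

N_DEPTH_BINS = N_SPECTRAL_SAMPLES // 2

__all__ = [
    "N_DEPTH_BINS",
    "ReconAScan",
    "ReconMScan",
    "DCState",
    "dechirp",
    "update_dc",
    "subtract_dc",
    "apodize",
    "spectral_window",
    "to_depth_profile",
    "reconstruct_mscan",
    "peak_depth",
    "AScanReconstructor",
]


@dataclass(frozen=True)
class ReconAScan:
    """One reconstructed depth profile: 512 non-negative magnitudes."""

    magnitudes: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=np.float64)
        object.__setattr__(self, "magnitudes", m)
        if m.shape != (N_DEPTH_BINS,):
            raise ValueError(f"A-scan must have {N_DEPTH_BINS} bins")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("A-scan magnitudes must be finite and non-negative")


@dataclass(frozen=True)
class ReconMScan:
    """Reconstructed M-scan: 512 x N_t depth profiles over time."""

    ascans: np.ndarray  # (512, N_t)
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ascans, dtype=np.float64)
        ts = np.asarray(self.timestamps, dtype=np.float64)
        object.__setattr__(self, "ascans", a)
        object.__setattr__(self, "timestamps", ts)
        if a.ndim != 2 or a.shape[0] != N_DEPTH_BINS:
            raise ValueError(f"reconstructed M-scan must be {N_DEPTH_BINS} x N_t")
        if ts.size != a.shape[1]:
            raise ValueError("timestamps must align with A-scan columns")

    @property
    def n_t(self) -> int:
        return self.ascans.shape[1]


@dataclass
class DCState:
    """Running exponential-moving-average estimate of the DC spectrum."""

    damping: float = 0.05
    estimate: np.ndarray = field(
        default_factory=lambda: np.zeros(N_SPECTRAL_SAMPLES, dtype=np.float64)
    )
    initialized: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        self.estimate = np.asarray(self.estimate, dtype=np.float64)
        if self.estimate.shape != (N_SPECTRAL_SAMPLES,):
            raise ValueError(f"DC estimate must have {N_SPECTRAL_SAMPLES} samples")


def dechirp(spectrum: np.ndarray | RawSpectrum, chirp: ChirpMap) -> np.ndarray:
    """Resample a spectrum from the detector's chirped wavenumber grid onto
    the uniform grid spanning the same interval (linear interpolation).

    On a uniform chirp map this is the identity.  Endpoints are preserved
    exactly because the uniform grid shares them with the chirped grid.
    """
    s = spectrum.samples if isinstance(spectrum, RawSpectrum) else np.asarray(spectrum, float)
    if s.shape[-1] != N_SPECTRAL_SAMPLES:
        raise ValueError(f"spectrum must have {N_SPECTRAL_SAMPLES} samples")
    if chirp.is_uniform:
        return s.copy()
    grid = chirp.uniform_grid
    if s.ndim == 1:
        return np.interp(grid, chirp.wavenumbers, s)
    return np.stack([np.interp(grid, chirp.wavenumbers, col) for col in s])


def update_dc(state: DCState, spectrum: np.ndarray) -> tuple[DCState, np.ndarray]:
    """Advance the EMA DC estimate with one spectrum.

    First call: the estimate is initialized to the spectrum itself.
    Afterwards: estimate <- (1 - d) * estimate + d * spectrum.
    Returns the updated state and a copy of its estimate.
    """
    s = np.asarray(spectrum, dtype=np.float64)
    if s.shape != (N_SPECTRAL_SAMPLES,):
        raise ValueError(f"spectrum must have {N_SPECTRAL_SAMPLES} samples")
    if not state.initialized:
        new = DCState(damping=state.damping, estimate=s.copy(), initialized=True)
    else:
        est = (1.0 - state.damping) * state.estimate + state.damping * s
        new = DCState(damping=state.damping, estimate=est, initialized=True)
    return new, new.estimate.copy()


def subtract_dc(spectrum: np.ndarray, dc: np.ndarray) -> np.ndarray:
    """Remove the DC source envelope, leaving the interferometric fringe."""
    s = np.asarray(spectrum, dtype=np.float64)
    d = np.asarray(dc, dtype=np.float64)
    if s.shape != d.shape:
        raise ValueError("spectrum and DC estimate must have equal shapes")
    return s - d


def spectral_window(kind: str = "hann") -> np.ndarray:
    """Apodization window over the 1024 spectral samples.

    ``"hann"`` is the standard symmetric Hann window
    w[i] = 0.5*(1 - cos(2*pi*i/(N-1))).  ``"narrow"`` is a deliberately
    destructive Gaussian (sigma = 24 px) that collapses depth resolution;
    it exists to study how much force information survives an aggressive,
    information-destroying reconstruction.
    """
    n = N_SPECTRAL_SAMPLES
    if kind == "hann":
        i = np.arange(n, dtype=np.float64)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * i / (n - 1)))
    if kind == "narrow":
        i = np.arange(n, dtype=np.float64)
        centre = (n - 1) / 2.0
        return np.exp(-0.5 * ((i - centre) / 24.0) ** 2)
    raise ValueError(f"unknown window kind: {kind!r}")


def apodize(spectrum: np.ndarray, *, window: str = "hann") -> np.ndarray:
    """Apply the spectral apodization window (Hann by default)."""
    s = np.asarray(spectrum, dtype=np.float64)
    if s.shape[-1] != N_SPECTRAL_SAMPLES:
        raise ValueError(f"spectrum must have {N_SPECTRAL_SAMPLES} samples")
    return s * spectral_window(window)


def to_depth_profile(spectrum: np.ndarray, *, timestamp: float = 0.0) -> ReconAScan:
    """Fourier transform the fringe spectrum and keep 512 magnitude bins.

    Unnormalized forward DFT; bins 0..511 (the non-redundant half for a real
    input) are retained and their complex magnitude is the depth profile.
    """
    s = np.asarray(spectrum, dtype=np.float64)
    if s.shape != (N_SPECTRAL_SAMPLES,):
        raise ValueError(f"spectrum must have {N_SPECTRAL_SAMPLES} samples")
    spectrum_c = np.fft.fft(s)
    return ReconAScan(magnitudes=np.abs(spectrum_c[:N_DEPTH_BINS]), timestamp=timestamp)


def reconstruct_mscan(
    mscan: RawMScan,
    damping: float = 0.05,
    *,
    window: str = "hann",
    dc_init: np.ndarray | None = None,
) -> ReconMScan:
    """Run the full six-step reconstruction over an M-scan, column by column.

    Columns are processed in timestamp order because the DC tracker is
    stateful.  ``dc_init`` pre-seeds the EMA estimate (1024-vector); by
    default the first scan initializes it, making the first A-scan zero.
    """
    if mscan.n_t < 1:
        raise ValueError("M-scan must contain at least one scan")
    dech = dechirp(mscan.spectra.T, mscan.chirp)  # (N_t, 1024)
    if dc_init is not None:
        state = DCState(damping=damping, estimate=np.asarray(dc_init, float), initialized=True)
    else:
        state = DCState(damping=damping)
    win = spectral_window(window)
    out = np.empty((N_DEPTH_BINS, mscan.n_t), dtype=np.float64)
    for t in range(mscan.n_t):
        state, dc = update_dc(state, dech[t])
        residual = subtract_dc(dech[t], dc)
        out[:, t] = np.abs(np.fft.fft(residual * win)[:N_DEPTH_BINS])
    return ReconMScan(ascans=out, timestamps=mscan.timestamps)


def peak_depth(
    ascan: ReconAScan | np.ndarray,
    *,
    guard_band: int = 4,
) -> float | None:
    """Locate the dominant reflector in a depth profile, in fractional bins.

    Searches bins >= ``guard_band`` (excluding residual DC), takes the argmax
    (ties break toward the lower index) and refines it with a three-point
    parabolic fit.  Returns ``None`` when the profile carries no signal.
    """
    m = ascan.magnitudes if isinstance(ascan, ReconAScan) else np.asarray(ascan, float)
    if m.size == 0:
        raise ValueError("empty A-scan")
    region = m[guard_band:]
    if not np.any(region > 0):
        return None
    i = int(np.argmax(region)) + guard_band
    if 0 < i < m.size - 1:
        left, centre, right = m[i - 1], m[i], m[i + 1]
        denom = left - 2.0 * centre + right
        if denom < 0:  # strict local maximum: refine
            return i + 0.5 * (left - right) / denom
    return float(i)


class AScanReconstructor:
    """Sklearn-style transformer: raw spectra (n_scans, 1024) -> A-scans (n_scans, 512).

    Rows must be in acquisition order because the DC tracker is stateful
    across scans.  ``fit`` validates parameters and stores the chirp map;
    ``transform`` is stateless between calls (each call replays the EMA from
    its initialization).

    Parameters
    ----------
    chirp : ChirpMap or None
        Pixel-to-wavenumber map used for dechirping.  ``None`` assumes the
        input is already on a uniform grid.
    damping : float
        EMA damping coefficient d in (0, 1].
    window : str
        Apodization window, ``"hann"`` or ``"narrow"``.
    burn_in : int
        Number of leading scans whose DC estimate is considered transient.
        ``transform`` still returns them; use :meth:`valid_slice` to drop
        them for training.
    """

    def __init__(
        self,
        chirp: ChirpMap | None = None,
        damping: float = 0.05,
        window: str = "hann",
        burn_in: int = 200,
    ) -> None:
        self.chirp = chirp
        self.damping = damping
        self.window = window
        self.burn_in = burn_in

    def get_params(self, deep: bool = True) -> dict:
        return {
            "chirp": self.chirp,
            "damping": self.damping,
            "window": self.window,
            "burn_in": self.burn_in,
        }

    def set_params(self, **params) -> "AScanReconstructor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray | RawMScan, y=None) -> "AScanReconstructor":
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        spectral_window(self.window)  # validates the window kind
        self.n_features_in_ = N_SPECTRAL_SAMPLES
        return self

    def transform(self, X: np.ndarray | RawMScan) -> np.ndarray:
        if isinstance(X, RawMScan):
            mscan = X
        else:
            arr = np.asarray(X, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != N_SPECTRAL_SAMPLES:
                raise ValueError(f"expected (n_scans, {N_SPECTRAL_SAMPLES}) input")
            chirp = self.chirp
            if chirp is None:
                chirp = ChirpMap(
                    wavenumbers=np.arange(N_SPECTRAL_SAMPLES, dtype=np.float64),
                    is_uniform=True,
                )
            mscan = RawMScan(
                spectra=arr.T,
                timestamps=np.arange(arr.shape[0], dtype=np.float64),
                chirp=chirp,
            )
        recon = reconstruct_mscan(mscan, damping=self.damping, window=self.window)
        return recon.ascans.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def valid_slice(self) -> slice:
        """Row slice excluding the EMA burn-in transient."""
        return slice(self.burn_in, None)
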