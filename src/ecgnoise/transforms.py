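"""Signal-to-image transforms: SPAR attractor density and Morse CWT scalogram.

Symmetric projection attractor reconstruction (SPAR) embeds a quasi-periodic
signal in 3D with delay coordinates (x(t), x(t-tau), x(t-2*tau)), projects
onto the plane orthogonal to (1, 1, 1) — which removes any common baseline
offset exactly — and renders the 2D point density.  With tau locked to one
third of the mean cardiac cycle, the attractor captures waveform morphology
while factoring out heart rate.

The scalogram is the magnitude of a continuous wavelet transform using an
analytic generalized Morse wavelet (gamma = 3, time-bandwidth product
P^2 = beta * gamma = 60) evaluated as an FFT-domain filter bank at 16
voices per octave.  Both transforms emit 150 x 150 greyscale images with
intensities in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

from .cohort import ECGRecord

#: orthonormal basis of the plane orthogonal to (1,1,1):
#: v = (x + y - 2z)/sqrt(6), w = (x - y)/sqrt(2)
PROJECTION = np.array(
    [
        [1.0 / np.sqrt(6.0), 1.0 / np.sqrt(6.0), -2.0 / np.sqrt(6.0)],
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
    ]
)


@dataclass
class TransformImage:
    pixels: np.ndarray  # (grid, grid) float in [0, 1]
    kind: str  # "attractor" | "scalogram"
    record_id: str = ""
    variant: str = ""
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.kind not in ("attractor", "scalogram"):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("image intensities must lie in [0, 1]")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SPARConfig:
    grid: int = 150
    #: delay as a fraction of the estimated mean cycle length
    tau_cycle_fraction: float = 1.0 / 3.0
    #: fallback fixed delay (used when cycle estimation fails), seconds
    tau_fixed_s: float = 0.33
    #: cycle-length search range for the autocorrelation peak, seconds
    cycle_range_s: tuple[float, float] = (0.3, 3.0)
    density_scaling: str = "log1p"  # "log1p" | "linear"

    def validate(self) -> None:
        if self.grid < 2:
            raise ValueError("grid size must be >= 2")
        if self.density_scaling not in ("log1p", "linear"):
            raise ValueError(f"unknown density scaling {self.density_scaling!r}")


@dataclass
class ScalogramConfig:
    grid: int = 150
    gamma: float = 3.0
    time_bandwidth: float = 60.0  # P^2 = beta * gamma
    voices_per_octave: int = 16
    freq_min_hz: float = 0.5
    freq_max_hz: float = 50.0
    log_magnitude: bool = False

    @property
    def beta(self) -> float:
        return self.time_bandwidth / self.gamma


# ---------------------------------------------------------------------------
# SPAR attractor

def delay_embed(signal: np.ndarray, tau: int) -> np.ndarray:
    """Delay-coordinate embedding -> (N - 2*tau, 3) points (x(t), x(t-tau), x(t-2tau))."""
    signal = np.asarray(signal, float)
    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be >= 1 sample")
    if len(signal) <= 2 * tau:
        raise ValueError(f"signal length {len(signal)} too short for tau={tau}")
    x = signal[2 * tau :]
    y = signal[tau : -tau]
    z = signal[: -2 * tau]
    return np.column_stack([x, y, z])


def spar_project(points: np.ndarray) -> np.ndarray:
    """Project 3D delay points onto the plane orthogonal to (1, 1, 1)."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.size == 0:
        raise ValueError("empty point set")
    return points @ PROJECTION.T


def density_image(vw: np.ndarray, cfg: SPARConfig | None = None) -> TransformImage:
    """2D histogram of projected points on a symmetric square grid, in [0, 1]."""
    cfg = cfg or SPARConfig()
    cfg.validate()
    vw = np.atleast_2d(np.asarray(vw, float))
    if vw.size == 0:
        raise ValueError("empty point set")
    r = float(np.max(np.abs(vw)))
    if r == 0.0:
        r = 1.0  # all points at the origin: one central nonzero pixel
    counts, _, _ = np.histogram2d(
        vw[:, 1], vw[:, 0], bins=cfg.grid, range=[[-r, r], [-r, r]]
    )
    counts = counts[::-1]  # +w upward
    if cfg.density_scaling == "log1p":
        img = np.log1p(counts)
    else:
        img = counts
    peak = img.max()
    if peak > 0:
        img = img / peak
    return TransformImage(img, "attractor", meta={"bound": r, "n_points": int(len(vw))})


def estimate_cycle_length(signal: np.ndarray, fs: float, cfg: SPARConfig | None = None) -> int:
    """Mean cardiac cycle length in samples from the autocorrelation peak."""
    cfg = cfg or SPARConfig()
    x = np.asarray(signal, float)
    x = x - x.mean()
    if np.allclose(x, 0):
        raise ValueError("cycle estimation failed: constant signal")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    acf = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2)[:n]
    lo = int(cfg.cycle_range_s[0] * fs)
    hi = min(n - 1, int(cfg.cycle_range_s[1] * fs))
    if hi <= lo:
        raise ValueError("signal too short for cycle estimation")
    lag = lo + int(np.argmax(acf[lo : hi + 1]))
    if acf[lag] <= 0:
        raise ValueError("cycle estimation failed: no positive autocorrelation peak")
    return lag


def spar_attractor(record: ECGRecord, cfg: SPARConfig | None = None) -> TransformImage:
    """Full SPAR pipeline: cycle estimate -> tau = cycle/3 -> embed -> project -> density."""
    cfg = cfg or SPARConfig()
    try:
        cycle = estimate_cycle_length(record.signal, record.fs, cfg)
        tau = max(1, int(round(cycle * cfg.tau_cycle_fraction)))
    except ValueError as exc:
        warnings.warn(f"cycle estimation failed ({exc}); using fixed tau", stacklevel=2)
        tau = max(1, int(round(cfg.tau_fixed_s * record.fs)))
    pts = delay_embed(record.signal, tau)
    img = density_image(spar_project(pts), cfg)
    img.record_id = record.record_id
    img.variant = record.variant
    img.meta["tau_samples"] = tau
    return img


# ---------------------------------------------------------------------------
# Morse CWT scalogram

def _morse_filter(omega: np.ndarray, scale: float, beta: float, gamma: float) -> np.ndarray:
    """Analytic generalized Morse wavelet in the frequency domain, peak-normalized."""
    w = scale * omega
    psi = np.zeros_like(w)
    pos = w > 0
    # log-domain evaluation, normalized so the peak (at w_p=(beta/gamma)^(1/gamma)) is 2
    log_peak = (beta / gamma) * (np.log(beta / gamma) - 1.0)
    psi[pos] = 2.0 * np.exp(beta * np.log(w[pos]) - w[pos] ** gamma - log_peak)
    return psi


def morse_cwt(
    signal: np.ndarray, fs: float, cfg: ScalogramConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """CWT magnitude matrix (n_freqs, n_samples) and center frequencies (Hz, descending)."""
    cfg = cfg or ScalogramConfig()
    x = np.asarray(signal, float)
    if x.size == 0:
        raise ValueError("empty signal")

    # the analysed band ends at freq_max; decimate first when the sampling
    # rate is far above it (pure speed-up, the discarded band is not imaged)
    q = int(fs // (4.0 * cfg.freq_max_hz))
    if q > 1:
        x = sps.decimate(x, q, ftype="fir", zero_phase=True)
        fs = fs / q

    n = len(x)
    n_octaves = np.log2(cfg.freq_max_hz / cfg.freq_min_hz)
    n_freqs = int(np.floor(n_octaves * cfg.voices_per_octave)) + 1
    freqs = cfg.freq_max_hz * 2.0 ** (-np.arange(n_freqs) / cfg.voices_per_octave)

    nfft = int(2 ** np.ceil(np.log2(max(2, n))))
    X = np.fft.fft(x, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    w_peak = (cfg.beta / cfg.gamma) ** (1.0 / cfg.gamma)

    mag = np.empty((n_freqs, n), dtype=float)
    for i, f in enumerate(freqs):
        scale = w_peak / (2.0 * np.pi * f)
        coef = np.fft.ifft(X * _morse_filter(omega, scale, cfg.beta, cfg.gamma))[:n]
        mag[i] = np.abs(coef)
    return mag, freqs


def cwt_scalogram(record: ECGRecord, cfg: ScalogramConfig | None = None) -> TransformImage:
    """Scalogram image: |CWT| resized to grid x grid, max-normalized to [0, 1].

    Row 0 corresponds to the highest analysed frequency; frequency decreases
    monotonically down the image.
    """
    cfg = cfg or ScalogramConfig()
    mag, freqs = morse_cwt(record.signal, record.fs, cfg)
    if cfg.log_magnitude:
        mag = np.log1p(mag)
    # block-average the time axis to a few columns per output pixel before
    # the bilinear resize; equivalent low-pass, much cheaper on long records
    max_cols = 4 * cfg.grid
    n_t = mag.shape[1]
    if n_t > 2 * max_cols:
        step = n_t // max_cols
        trim = (n_t // step) * step
        mag = mag[:, :trim].reshape(mag.shape[0], -1, step).mean(axis=2)
    img = _sk_resize(mag, (cfg.grid, cfg.grid), order=1, anti_aliasing=True, preserve_range=True)
    peak = img.max()
    if peak > 0:
        img = img / peak
    img = np.clip(img, 0.0, 1.0)
    out = TransformImage(img, "scalogram", record_id=record.record_id, variant=record.variant)
    out.meta = {"freq_max_hz": float(freqs[0]), "freq_min_hz": float(freqs[-1])}
    return out


def resize_for_network(img: TransformImage, side: int) -> np.ndarray:
    """Bilinear resize of the image to the side a network input layer expects."""
    if side != img.side and side not in (224, 227):
        raise ValueError(f"unsupported network input side {side}; expected 224 or 227")
    if side == img.side:
        return img.pixels.copy()
    out = _sk_resize(img.pixels, (side, side), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


class SparAttractor:
    """Transformer: list of ECGRecord -> list of attractor TransformImage."""

    def __init__(self, cfg: SPARConfig | None = None):
        self.cfg = cfg

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [spar_attractor(r, self.cfg) for r in X]

    def get_params(self, deep=True):
        return {"cfg": self.cfg}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


class MorseScalogram:
    """Transformer: list of ECGRecord -> list of scalogram TransformImage."""

    def __init__(self, cfg: ScalogramConfig | None = None):
        self.cfg = cfg

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [cwt_scalogram(r, self.cfg) for r in X]

    def get_params(self, deep=True):
        return {"cfg": self.cfg}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
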