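"""Synthetic three-class ECG cohort and physiological noise bank.

The study design needs a labelled single-lead (lead II) ECG cohort with one
rhythm-based pathology (atrial fibrillation, AF), one morphology-based
pathology (ST depression, STD) and a healthy class (Normal), sampled at
500 Hz with record lengths between 8 and 138 s, plus 30-minute banks of the
three classic physiological noise processes: baseline wander (bw),
electrode movement (em) and motion artefact (ma), and their sum (all).

The ECG model is a sum of Gaussian P/QRS/T bumps per beat on a 0 mV
isoline.  It is deliberately simple: every fiducial is known to the
generator, so downstream contracts (RR statistics, ST-segment level,
attractor invariances) can be tested against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

CLASSES = ("AF", "Normal", "STD")
VARIANTS = ("raw", "clean", "bw", "em", "ma", "all")
NOISE_TYPES = ("bw", "em", "ma")

#: default per-class subject counts (total 2678)
DEFAULT_COUNTS = {"AF": 976, "Normal": 918, "STD": 784}


@dataclass
class ECGRecord:
    """One subject's lead-II signal with label and provenance."""

    record_id: str
    class_label: str
    fs: float
    signal: np.ndarray
    duration_s: float
    variant: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.signal = np.asarray(self.signal, dtype=float)
        n_expected = int(round(self.duration_s * self.fs))
        if len(self.signal) != n_expected:
            raise ValueError(
                f"signal length {len(self.signal)} != round(duration*fs)={n_expected}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.signal)

    def with_signal(self, signal: np.ndarray, variant: str, **meta) -> "ECGRecord":
        new_meta = {**self.meta, **meta}
        return replace(self, signal=np.asarray(signal, float), variant=variant, meta=new_meta)


@dataclass
class MorphologyParams:
    """Beat-morphology and rhythm parameters of the generator.

    Amplitudes in mV, widths/offsets in seconds, rates in bpm.
    """

    normal_hr_bpm: float = 70.0
    normal_rr_cv: float = 0.03
    af_hr_bpm: float = 110.0
    af_rr_cv: float = 0.20
    af_fwave_freq_hz: tuple[float, float] = (4.0, 9.0)
    af_fwave_amp_mv: float = 0.08
    std_depth_mv: float = 0.15
    r_amp_mv: float = 1.1
    #: white-noise floor on raw records, as signal-to-floor SNR in dB
    raw_noise_snr_db: float = 30.0
    #: ST analysis window relative to the R peak (start, end), seconds
    st_window_s: tuple[float, float] = (0.06, 0.14)


@dataclass
class CohortConfig:
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    fs: float = 500.0
    duration_range_s: tuple[float, float] = (8.0, 138.0)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    seed: int = 0

    def validate(self) -> None:
        for c, n in self.counts.items():
            if c not in CLASSES:
                raise ValueError(f"unknown class {c!r} in counts")
            if n < 0:
                raise ValueError("counts must be >= 0")
        lo, hi = self.duration_range_s
        if not (8.0 <= lo <= hi <= 138.0):
            raise ValueError("duration range must lie within [8, 138] s")


@dataclass
class NoiseBank:
    """30-minute noise series at a common sampling rate.

    ``all_`` is the elementwise sum bw + em + ma (combination weights fixed
    at 1; the study only requires a linear combination).
    """

    fs: float
    bw: np.ndarray
    em: np.ndarray
    ma: np.ndarray
    seed: int | None = None

    @property
    def all_(self) -> np.ndarray:
        return self.bw + self.em + self.ma

    @property
    def n_samples(self) -> int:
        return len(self.bw)

    def series(self, noise_type: str) -> np.ndarray:
        if noise_type == "all":
            return self.all_
        if noise_type not in NOISE_TYPES:
            raise ValueError(f"unknown noise type {noise_type!r}")
        return getattr(self, noise_type)


# ---------------------------------------------------------------------------
# beat-level synthesis

# Gaussian bump parameters per wave: (amplitude mV, center offset s from R,
# width s).  A compact ECGSYN-flavoured parameterization.
_WAVES = {
    "P": (0.12, -0.17, 0.025),
    "Q": (-0.10, -0.028, 0.010),
    "R": (1.10, 0.0, 0.013),
    "S": (-0.18, 0.030, 0.012),
    "T": (0.32, 0.26, 0.055),
}


def _beat_template(t: np.ndarray, amp_scale: float, with_p: bool) -> np.ndarray:
    y = np.zeros_like(t)
    for name, (a, mu, sigma) in _WAVES.items():
        if name == "P" and not with_p:
            continue
        s = a * amp_scale if name == "R" else a
        y += s * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return y


def _draw_rr(rng, n: int, mean_rr: float, cv: float) -> np.ndarray:
    rr = rng.normal(mean_rr, cv * mean_rr, size=n)
    return np.clip(rr, 0.30, 2.2)


def generate_record(
    class_label: str,
    duration_s: float,
    fs: float = 500.0,
    rng: np.random.Generator | None = None,
    params: MorphologyParams | None = None,
    record_id: str = "rec",
) -> ECGRecord:
    """Synthesize one raw-variant lead-II record of the given class.

    Normal: near-constant RR, isoelectric ST.  AF: i.i.d. irregular RR at an
    elevated rate, P wave replaced by a low-amplitude 4-9 Hz fibrillatory
    oscillation.  STD: Normal morphology with the ST segment depressed by a
    configured depth.  A 30 dB white-noise floor makes raw differ from clean.
    """
    if not (8.0 <= duration_s <= 138.0):
        raise ValueError(f"duration_s={duration_s} outside the supported [8, 138] s range")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng() if rng is None else rng
    p = params or MorphologyParams()

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)

    is_af = class_label == "AF"
    hr = p.af_hr_bpm if is_af else p.normal_hr_bpm
    hr *= rng.uniform(0.92, 1.08)  # per-subject rate variation
    cv = p.af_rr_cv if is_af else p.normal_rr_cv
    mean_rr = 60.0 / hr
    amp_scale = rng.uniform(0.9, 1.1)

    n_beats = int(np.ceil(duration_s / 0.30)) + 2
    rr = _draw_rr(rng, n_beats, mean_rr, cv)
    r_times = np.cumsum(rr) - rr[0] + rng.uniform(0.1, mean_rr)
    r_times = r_times[r_times < duration_s + 0.5]

    st_windows = []
    half_span = 0.45  # beat support radius, s
    for r0 in r_times:
        i0 = max(0, int((r0 - half_span) * fs))
        i1 = min(n, int((r0 + half_span) * fs) + 1)
        if i1 <= i0:
            continue
        tt = t[i0:i1] - r0
        y[i0:i1] += _beat_template(tt, amp_scale, with_p=not is_af)
        if class_label == "STD":
            # flat depression over the annotated ST window with 20 ms
            # cosine ramps outside it, so the annotated mean equals -depth
            w0, w1 = p.st_window_s
            ramp = 0.020
            dep = np.zeros_like(tt)
            core = (tt >= w0) & (tt <= w1)
            dep[core] = 1.0
            lead = (tt >= w0 - ramp) & (tt < w0)
            dep[lead] = 0.5 * (1 - np.cos(np.pi * (tt[lead] - (w0 - ramp)) / ramp))
            trail = (tt > w1) & (tt <= w1 + ramp)
            dep[trail] = 0.5 * (1 + np.cos(np.pi * (tt[trail] - w1) / ramp))
            y[i0:i1] -= p.std_depth_mv * dep
        if 0 <= r0 < duration_s:
            st_windows.append((r0 + p.st_window_s[0], r0 + p.st_window_s[1]))

    if is_af:
        # continuous low-amplitude fibrillatory oscillation (f waves)
        f0 = rng.uniform(*p.af_fwave_freq_hz)
        phase = rng.uniform(0, 2 * np.pi)
        drift = np.cumsum(rng.normal(0, 0.15 / np.sqrt(fs), n))  # slow FM
        y += p.af_fwave_amp_mv * np.sin(2 * np.pi * f0 * t + phase + drift)

    # residual noise floor so that raw != clean
    sig_power = float(np.sum(y**2))
    if sig_power > 0:
        noise_power = sig_power / 10.0 ** (p.raw_noise_snr_db / 10.0)
        y += rng.normal(0.0, np.sqrt(noise_power / n), n)

    meta = {
        "r_times_s": np.asarray([r for r in r_times if r < duration_s]),
        "st_windows_s": np.asarray(st_windows),
        "heart_rate_bpm": hr,
    }
    return ECGRecord(record_id, class_label, fs, y, duration_s, "raw", meta)


def generate_cohort(config: CohortConfig | None = None) -> list[ECGRecord]:
    """Generate the full labelled cohort; deterministic in ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    master = np.random.default_rng(config.seed)
    lo, hi = config.duration_range_s
    records = []
    idx = 0
    for label in CLASSES:
        for _ in range(int(config.counts.get(label, 0))):
            rid = f"S{idx:05d}"
            sub = np.random.default_rng(master.integers(0, 2**31))
            duration = float(np.round(sub.uniform(lo, hi), 3))
            rec = generate_record(
                label, duration, config.fs, sub, config.morphology, record_id=rid
            )
            rec.meta["seed"] = config.seed
            records.append(rec)
            idx += 1
    return records


# ---------------------------------------------------------------------------
# noise bank

@dataclass
class NoiseParams:
    duration_s: float = 30.0 * 60.0
    # bw: drifting sub-0.5 Hz sinusoids with random-walk amplitude
    bw_n_components: int = 4
    bw_freq_range_hz: tuple[float, float] = (0.05, 0.45)
    bw_amp_mv: float = 0.35
    # em: Poisson transient episodes, near-zero elsewhere
    em_rate_per_min: float = 6.0
    em_episode_s: tuple[float, float] = (0.5, 3.0)
    em_amp_mv: float = 0.8
    # ma: band-limited Gaussian noise with slowly varying bursty envelope
    ma_band_hz: tuple[float, float] = (5.0, 100.0)
    ma_amp_mv: float = 0.15


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    sos = sps.butter(2, cutoff_hz, "lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _gen_bw(rng, n: int, fs: float, p: NoiseParams) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(p.bw_n_components):
        f = rng.uniform(*p.bw_freq_range_hz)
        phase = rng.uniform(0, 2 * np.pi)
        # amplitude random walk, smoothed well below the carrier band
        walk = np.cumsum(rng.normal(0, 1.0 / np.sqrt(fs), n))
        amp = 1.0 + 0.5 * walk / (np.std(walk) + 1e-12)
        out += amp * np.sin(2 * np.pi * f * t + phase)
    out *= p.bw_amp_mv / (np.std(out) + 1e-12)
    return out - out.mean()


def _gen_em(rng, n: int, fs: float, p: NoiseParams) -> np.ndarray:
    out = np.zeros(n)
    n_ep = rng.poisson(p.em_rate_per_min * (n / fs) / 60.0)
    for _ in range(n_ep):
        dur = rng.uniform(*p.em_episode_s)
        start = rng.integers(0, max(1, n - int(dur * fs)))
        m = int(dur * fs)
        u = np.linspace(0, 1, m)
        # smoothed biphasic transient: sharp rise, slow recovery to zero
        shape = np.sin(np.pi * u) ** 2 * np.exp(-2.5 * u)
        out[start : start + m] += rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0) * p.em_amp_mv * shape
    return out - out.mean()


def _gen_ma(rng, n: int, fs: float, p: NoiseParams) -> np.ndarray:
    white = rng.normal(0, 1, n)
    hi = min(p.ma_band_hz[1], 0.45 * fs)
    sos = sps.butter(4, [p.ma_band_hz[0], hi], "bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    env = _smooth(rng.normal(0, 1, n), fs, 0.2)
    env = np.exp(1.2 * env / (np.std(env) + 1e-12))  # bursty lognormal envelope
    out = band * env
    out *= p.ma_amp_mv / (np.std(out) + 1e-12)
    return out - out.mean()


def generate_noise_bank(
    fs: float = 500.0,
    rng: np.random.Generator | int | None = None,
    params: NoiseParams | None = None,
) -> NoiseBank:
    """Generate the three 30-minute physiological noise series.

    bw concentrates its power below 1 Hz; em is near-zero outside sparse
    transient episodes; ma is broadband with a bursty envelope.  All three
    are zero-mean by construction.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    p = params or NoiseParams()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(p.duration_s * fs))
    return NoiseBank(
        fs=fs,
        bw=_gen_bw(rng, n, fs, p),
        em=_gen_em(rng, n, fs, p),
        ma=_gen_ma(rng, n, fs, p),
        seed=seed,
    )


def stable_seed(master_seed: int, *tokens) -> int:
    """Deterministic child seed < 2**31 derived from a master seed and tokens."""
    h = hashlib.sha256(repr((int(master_seed),) + tuple(tokens)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
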