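"""Synthetic fractionated atrial electrograms with ground-truth annotations.

Clinical CFAE recordings are rarely shareable, so every downstream stage of the
package is exercised on surrogate signals: quasi-periodic trains of biphasic
activation complexes (cycle length with jitter), optional sub-deflections that
mimic fractionation, baseline noise, powerline interference, and the two
artifact classes the quality screen must catch (low-frequency drift and
signal-loss intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FS = 1000
"""Sampling rate of every recording, Hz."""

DURATION_S = 16
"""Recording length, seconds."""

N_SAMPLES = FS * DURATION_S

SITES = ("LSPV", "LIPV", "RSPV", "RIPV", "ANT", "POS")
"""Left-atrial recording sites: the four pulmonary veins plus the anterior and
posterior free wall."""

REFRACTORY_MS = 100.0
"""Physiologic floor on the interval between successive atrial activations."""


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters for one electrogram.

    Parameters
    ----------
    af_type : {"ParAF", "PerAF"}
        Class label attached to the recording.
    mean_cl : float
        Mean activation cycle length, ms. Must be >= 120 ms, consistent with
        the fractionated-electrogram definition (cycle length >= 120 ms with
        isoelectric intervals).
    cl_jitter_sd : float
        Standard deviation of cycle-length jitter, ms.
    fractionation : int
        Number of sub-deflections per activation complex (>= 1). One means a
        single clean biphasic deflection.
    deflection_width : float
        Nominal width of one deflection, ms.
    noise_sd : float
        Baseline noise SD, mV. The noise is band-limited (low-passed at
        ``noise_bandwidth``): broadband sample-to-sample noise would make the
        phase-space trajectory untrackable and degenerate the determinism
        index to zero, which no contact electrogram exhibits.
    noise_bandwidth : float
        Low-pass corner of the baseline noise, Hz.
    powerline_amp : float
        Amplitude of an additive mains tone, mV (0 disables it).
    powerline_freq : float
        Mains frequency, Hz.
    seed : int
        RNG seed; identical ``(params, seed)`` reproduce the signal
        bit-for-bit.
    """

    af_type: str = "ParAF"
    mean_cl: float = 185.0
    cl_jitter_sd: float = 10.0
    fractionation: int = 2
    deflection_width: float = 12.0
    noise_sd: float = 0.05
    noise_bandwidth: float = 100.0
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.af_type not in ("ParAF", "PerAF"):
            raise ValueError(f"af_type must be ParAF or PerAF, got {self.af_type!r}")
        if self.mean_cl < 120.0:
            raise ValueError(
                f"mean_cl must be >= 120 ms (CFAE definition), got {self.mean_cl}"
            )
        if self.cl_jitter_sd < 0:
            raise ValueError("cl_jitter_sd must be >= 0")
        if self.fractionation < 1:
            raise ValueError("fractionation must be >= 1")
        if self.deflection_width <= 0:
            raise ValueError("deflection_width must be > 0")


@dataclass(frozen=True)
class DriftSpec:
    """One low-frequency drift interval (seconds, amplitude mV, freq < 2 Hz)."""

    start: float
    end: float
    amplitude: float = 5.0
    freq: float = 0.7


@dataclass(frozen=True)
class LossSpec:
    """One signal-loss interval: amplitude suppressed toward 0 mV."""

    start: float
    end: float


@dataclass(frozen=True)
class ArtifactSchedule:
    """Scheduled artifacts for :func:`inject_artifacts`."""

    drift_intervals: tuple[DriftSpec, ...] = ()
    loss_intervals: tuple[LossSpec, ...] = ()

    def __post_init__(self) -> None:
        for iv in (*self.drift_intervals, *self.loss_intervals):
            if not (0.0 <= iv.start <= iv.end <= DURATION_S):
                raise ValueError(f"interval ({iv.start}, {iv.end}) outside [0, 16] s")
        for d in self.drift_intervals:
            if not (0.0 < d.freq < 2.0):
                raise ValueError("drift frequency must lie in (0, 2) Hz")
            for l in self.loss_intervals:
                if d.start < l.end and l.start < d.end:
                    raise ValueError(
                        f"drift ({d.start},{d.end}) overlaps loss ({l.start},{l.end})"
                    )


@dataclass
class Recording:
    """A single 16 s, 1 kHz bipolar atrial electrogram with metadata.

    ``truth`` holds generator-side ground truth (activation times in ms and the
    artifact schedule) when the recording is synthetic.
    """

    patient_id: str
    af_type: str
    site: str
    samples: np.ndarray
    fs: int = FS
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs != FS:
            raise ValueError(f"fs must be {FS} Hz, got {self.fs}")
        if self.samples.shape != (N_SAMPLES,):
            raise ValueError(
                f"expected {N_SAMPLES} samples, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


# ---------------------------------------------------------------------------
# activation trains and complex rendering


def generate_activation_train(
    params: SynthParams, duration: float = DURATION_S, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw a strictly increasing train of activation times (ms).

    Successive intervals are Gaussian around ``mean_cl`` with SD
    ``cl_jitter_sd``, truncated below at the 100 ms refractory floor.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if params.mean_cl <= REFRACTORY_MS:
        raise ValueError(
            f"mean_cl must exceed the {REFRACTORY_MS:.0f} ms refractory floor"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    horizon = duration * 1000.0
    times = []
    # first activation half a cycle in, so edge complexes are rendered whole
    t = params.mean_cl / 2.0
    while t < horizon:
        times.append(t)
        iv = rng.normal(params.mean_cl, params.cl_jitter_sd)
        t += max(iv, REFRACTORY_MS)
    return np.asarray(times)


def _biphasic_wavelet(width_ms: float) -> np.ndarray:
    """Derivative-of-Gaussian biphasic deflection, unit peak, finite support."""
    sigma = width_ms / 4.0 / 1000.0 * FS  # samples
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1, dtype=float)
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.abs(w).max()


def _bandlimited_noise(rng: np.random.Generator, sd: float, bandwidth: float) -> np.ndarray:
    from scipy import signal as sps

    w = rng.normal(0.0, 1.0, N_SAMPLES)
    sos = sps.butter(4, bandwidth, btype="lowpass", fs=FS, output="sos")
    y = sps.sosfiltfilt(sos, w)
    return sd * y / y.std()


def generate_cfae(params: SynthParams) -> Recording:
    """Synthesize one fractionated electrogram.

    Each activation is a biphasic wavelet; ``fractionation`` extra
    sub-deflections are placed with jittered offsets within +/-25 ms of the
    activation time, reproducing the multi-deflection morphology of CFAEs.
    Peak amplitude is normalized to ~1 mV before noise is added.
    """
    rng = np.random.default_rng(params.seed)
    times = generate_activation_train(params, DURATION_S, rng)
    x = np.zeros(N_SAMPLES)
    wav = _biphasic_wavelet(params.deflection_width)
    half = len(wav) // 2
    for t_ms in times:
        offsets = [0.0]
        amps = [1.0]
        for _ in range(params.fractionation - 1):
            offsets.append(rng.uniform(-25.0, 25.0))
            amps.append(rng.uniform(0.4, 0.8))
        for off, amp in zip(offsets, amps):
            c = int(round((t_ms + off) / 1000.0 * FS))
            lo, hi = c - half, c + half + 1
            wlo = max(0, -lo)
            whi = len(wav) - max(0, hi - N_SAMPLES)
            lo, hi = max(lo, 0), min(hi, N_SAMPLES)
            if lo < hi:
                x[lo:hi] += amp * wav[wlo:whi]
    peak = np.abs(x).max()
    if peak > 0:
        x /= peak
    if params.noise_sd > 0:
        x = x + _bandlimited_noise(rng, params.noise_sd, params.noise_bandwidth)
    if params.powerline_amp > 0:
        t = np.arange(N_SAMPLES) / FS
        x = x + params.powerline_amp * np.sin(2 * np.pi * params.powerline_freq * t)
    return Recording(
        patient_id="synthetic",
        af_type=params.af_type,
        site="LSPV",
        samples=x,
        truth={"activation_times_ms": times, "schedule": ArtifactSchedule()},
    )


def inject_artifacts(rec: Recording, sched: ArtifactSchedule) -> Recording:
    """Return a copy of ``rec`` with scheduled drift and signal-loss artifacts.

    Drift intervals gain a high-amplitude sub-2 Hz raised-cosine-windowed
    sinusoid; loss intervals are attenuated to 1% amplitude plus tiny noise so
    "near zero mV" detection thresholds are exercised rather than trivially hit.
    """
    x = rec.samples.copy()
    t = np.arange(N_SAMPLES) / FS
    for d in sched.drift_intervals:
        lo, hi = int(d.start * FS), int(d.end * FS)
        seg_t = t[lo:hi] - d.start
        dur = max(d.end - d.start, 1e-9)
        window = 0.5 * (1 - np.cos(2 * np.pi * seg_t / dur))
        x[lo:hi] += d.amplitude * window * np.sin(2 * np.pi * d.freq * seg_t)
    rng = np.random.default_rng(0xA5F1CE ^ abs(hash(rec.patient_id)) % (2**31))
    for l in sched.loss_intervals:
        lo, hi = int(l.start * FS), int(l.end * FS)
        x[lo:hi] = 0.01 * x[lo:hi] + rng.normal(0.0, 1e-4, hi - lo)
    truth = dict(rec.truth)
    truth["schedule"] = sched
    return Recording(rec.patient_id, rec.af_type, rec.site, x, rec.fs, truth)


# ---------------------------------------------------------------------------
# class presets and cohorts

PRESETS: dict[str, SynthParams] = {
    # Persistent AF: shorter cycle length, more jitter, heavier fractionation
    # -> higher sample entropy, lower determinism, higher dominant frequency.
    "ParAF": SynthParams(af_type="ParAF", mean_cl=185.0, cl_jitter_sd=10.0,
                         fractionation=2, noise_sd=0.04),
    "PerAF": SynthParams(af_type="PerAF", mean_cl=145.0, cl_jitter_sd=25.0,
                         fractionation=5, noise_sd=0.06),
}

# Inter-patient spread of preset parameters within a class.
_PATIENT_CL_SD = 8.0
_PATIENT_JITTER_SD = 2.0


def patient_params(
    af_type: str, rng: np.random.Generator, separation: float = 1.0
) -> SynthParams:
    """Draw one patient's generator parameters from the class preset.

    ``separation`` scales the between-class contrast: 1.0 keeps the presets as
    configured, 0.0 collapses both classes onto the midpoint (a null cohort).
    """
    base = PRESETS[af_type]
    mid_cl = (PRESETS["ParAF"].mean_cl + PRESETS["PerAF"].mean_cl) / 2
    mid_jit = (PRESETS["ParAF"].cl_jitter_sd + PRESETS["PerAF"].cl_jitter_sd) / 2
    mean_cl = mid_cl + separation * (base.mean_cl - mid_cl)
    jitter = mid_jit + separation * (base.cl_jitter_sd - mid_jit)
    frac = base.fractionation if separation > 0.5 else 3
    return replace(
        base,
        mean_cl=max(125.0, rng.normal(mean_cl, _PATIENT_CL_SD)),
        cl_jitter_sd=max(0.0, rng.normal(jitter, _PATIENT_JITTER_SD)),
        fractionation=frac,
        seed=int(rng.integers(0, 2**31)),
    )


def generate_cohort(
    n_par: int,
    n_per: int,
    sites: tuple[str, ...] = SITES,
    seed: int = 0,
    separation: float = 1.0,
) -> list[Recording]:
    """Generate one recording per patient x site, deterministic under seed."""
    if n_par < 1 or n_per < 1:
        raise ValueError("need at least one patient per class")
    if not sites:
        raise ValueError("site list must be non-empty")
    rng = np.random.default_rng(seed)
    cohort: list[Recording] = []
    labels = [("ParAF", i) for i in range(n_par)] + [("PerAF", i) for i in range(n_per)]
    for af_type, i in labels:
        pid = f"{af_type[:3].upper()}{i + 1:03d}"
        base = patient_params(af_type, rng, separation)
        for site in sites:
            p = replace(base, seed=int(rng.integers(0, 2**31)))
            rec = generate_cfae(p)
            rec.patient_id = pid
            rec.site = site
            cohort.append(rec)
    return cohort
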