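"""Segment-quality screening and quality-vector propagation.

Each 16 s electrogram is cut into non-overlapping windows of w ∈ {1, 2, 4} s.
A binary quality vector q_w of length 16/w marks each window as acceptable (1)
or low quality (0). The 1 s vector q1 is built first by two automated
criteria — a low-frequency (0-2 Hz) spectral-peak test for drift-type
artifacts combined with an abnormal-amplitude check, and an amplitude-range
test for signal-loss intervals — and coarser vectors are derived by
multiplying consecutive disjoint groups of q1 elements, preserving time
correspondence between the three window lengths. An optional manual override
replaces the automated bits for a recording.

Reports index segments 1-based, following the q_w(i) notation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import FS, DURATION_S, Recording

WINDOW_LENGTHS = (1, 2, 4)


@dataclass(frozen=True)
class QualityCriteria:
    """Thresholds for the two automated discard criteria.

    lf_band : frequency range, Hz, inspected for drift-type artifacts.
    af_band : fibrillatory reference band, Hz.
    lf_peak_ratio : a segment fails the spectral test when its peak PSD inside
        ``lf_band`` exceeds ``lf_peak_ratio`` times its peak PSD inside
        ``af_band``.
    amp_factor : the drift criterion additionally requires the segment's peak
        |amplitude| to exceed ``amp_factor`` times the recording's median
        per-second peak (the "abnormal amplitude and/or shape" condition).
    loss_range_frac : a segment is a signal-loss candidate when its amplitude
        range (max - min) falls strictly below ``loss_range_frac`` times the
        recording's median per-second range.
    """

    lf_band: tuple[float, float] = (0.0, 2.0)
    af_band: tuple[float, float] = (3.0, 12.0)
    lf_peak_ratio: float = 1.0
    amp_factor: float = 2.0
    loss_range_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.lf_peak_ratio <= 0 or self.amp_factor <= 0 or self.loss_range_frac <= 0:
            raise ValueError("thresholds must be positive")

    def resolve(self, rec: Recording) -> "ResolvedCriteria":
        """Turn relative thresholds into absolute ones for one recording."""
        segs = segment_signal(rec, 1)
        peaks = np.array([np.abs(s).max() for s in segs])
        ranges = np.array([s.max() - s.min() for s in segs])
        return ResolvedCriteria(
            lf_band=self.lf_band,
            af_band=self.af_band,
            lf_peak_ratio=self.lf_peak_ratio,
            amp_threshold=self.amp_factor * float(np.median(peaks)),
            loss_range=self.loss_range_frac * float(np.median(ranges)),
        )


@dataclass(frozen=True)
class ResolvedCriteria:
    """Absolute per-recording thresholds derived from :class:`QualityCriteria`."""

    lf_band: tuple[float, float] = (0.0, 2.0)
    af_band: tuple[float, float] = (3.0, 12.0)
    lf_peak_ratio: float = 1.0
    amp_threshold: float = 2.0
    loss_range: float = 0.05


@dataclass
class QualityVector:
    """Binary per-segment quality flags for one recording at window length w."""

    recording_id: str
    w: int
    bits: np.ndarray

    def __post_init__(self) -> None:
        if self.w not in WINDOW_LENGTHS:
            raise ValueError(f"w must be one of {WINDOW_LENGTHS}")
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.shape != (DURATION_S // self.w,):
            raise ValueError(
                f"q{self.w} must have {DURATION_S // self.w} elements"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    @property
    def bad_positions(self) -> np.ndarray:
        """1-based indices of low-quality elements."""
        return np.flatnonzero(self.bits == 0) + 1


def segment_signal(rec: Recording, w: int) -> list[np.ndarray]:
    """Cut a 16 s recording into 16/w non-overlapping w-second segments."""
    if w not in WINDOW_LENGTHS:
        raise ValueError(f"window length must be one of {WINDOW_LENGTHS}, got {w}")
    n = w * FS
    x = rec.samples
    return [x[i * n : (i + 1) * n] for i in range(DURATION_S // w)]


def _screen_psd(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 512-sample Hamming windows, 50% overlap, zero-padded FFT: a shorter
    # window cannot separate the 0-2 Hz drift band from the 3-12 Hz
    # fibrillatory band (its spectral mainlobe spans both)
    return sps.welch(
        segment, fs=FS, window="hamming", nperseg=512, noverlap=256, nfft=2048
    )


def lowfreq_artifact_flag(segment: np.ndarray, crit: ResolvedCriteria) -> bool:
    """True (bad) iff the 0-2 Hz spectral peak dominates the fibrillatory band
    AND the segment's peak amplitude is abnormal for its recording."""
    f, p = _screen_psd(segment)
    lf = p[(f >= crit.lf_band[0]) & (f <= crit.lf_band[1])].max()
    af = p[(f >= crit.af_band[0]) & (f <= crit.af_band[1])].max()
    spectral_hit = lf > crit.lf_peak_ratio * af
    amplitude_hit = np.abs(segment).max() > crit.amp_threshold
    return bool(spectral_hit and amplitude_hit)


def signal_loss_flag(segment: np.ndarray, crit: ResolvedCriteria) -> bool:
    """True iff the amplitude range is strictly below the loss threshold."""
    return bool((segment.max() - segment.min()) < crit.loss_range)


def build_q1(
    rec: Recording,
    crit: QualityCriteria = QualityCriteria(),
    override: np.ndarray | None = None,
) -> QualityVector:
    """Automated 1 s quality vector; a manual override replaces it entirely."""
    if override is not None:
        override = np.asarray(override, dtype=int)
        if override.shape != (DURATION_S,):
            raise ValueError(f"override must have {DURATION_S} bits")
        return QualityVector(rec.patient_id + "/" + rec.site, 1, override)
    resolved = crit.resolve(rec)
    bits = np.ones(DURATION_S, dtype=int)
    for i, seg in enumerate(segment_signal(rec, 1)):
        if lowfreq_artifact_flag(seg, resolved) or signal_loss_flag(seg, resolved):
            bits[i] = 0
    return QualityVector(rec.patient_id + "/" + rec.site, 1, bits)


def propagate_quality(q1: QualityVector, w: int) -> QualityVector:
    """Derive q_w (w ∈ {2, 4}) by multiplying consecutive disjoint groups of
    q1 elements; element j of q_w covers seconds (j-1)*w+1 .. j*w."""
    if q1.w != 1:
        raise ValueError("propagation starts from the 1 s vector")
    if w not in (2, 4):
        raise ValueError("target window length must be 2 or 4 s")
    bits = q1.bits.reshape(-1, w).prod(axis=1)
    return QualityVector(q1.recording_id, w, bits)


def quality_vectors(
    rec: Recording,
    crit: QualityCriteria = QualityCriteria(),
    override: np.ndarray | None = None,
) -> dict[int, QualityVector]:
    """q1, q2, q4 for one recording."""
    q1 = build_q1(rec, crit, override)
    return {1: q1, 2: propagate_quality(q1, 2), 4: propagate_quality(q1, 4)}


def discard_summary(q1_vectors: dict, recordings: list[Recording] | None = None) -> pd.DataFrame:
    """Discard and information-loss percentages per window length.

    ``q1_vectors`` maps recording key -> q1 :class:`QualityVector` (the coarser
    vectors are re-derived by propagation). For each w:

    * ``discard_pct`` — 100 x (# zero elements) / (# elements);
    * ``info_loss_pct`` — 100 x (# good 1 s sub-segments lying inside
      discarded w-length segments) / (# 1 s segments): the good short
      sequences sacrificed by coarse windowing.

    When ``recordings`` is given (parallel to the dict ordering), per-site and
    per-AF-type breakdowns are included with group="site:<s>"/"af:<t>" rows.
    """
    if not q1_vectors:
        raise ValueError("empty cohort")
    keys = list(q1_vectors)
    groups: dict[str, list] = {"all": keys}
    if recordings is not None:
        meta = {k: r for k, r in zip(keys, recordings)}
        for k, r in meta.items():
            groups.setdefault(f"site:{r.site}", []).append(k)
            groups.setdefault(f"af:{r.af_type}", []).append(k)
    rows = []
    for gname, gkeys in groups.items():
        for w in WINDOW_LENGTHS:
            n_el = bad = info_lost = n_sub = 0
            for k in gkeys:
                q1 = q1_vectors[k]
                qw = q1 if w == 1 else propagate_quality(q1, w)
                n_el += len(qw.bits)
                bad += int((qw.bits == 0).sum())
                n_sub += len(q1.bits)
                sub = q1.bits.reshape(-1, w)
                info_lost += int(sub[qw.bits == 0].sum())
            rows.append(
                {
                    "group": gname,
                    "w": w,
                    "discard_pct": 100.0 * bad / n_el,
                    "info_loss_pct": 100.0 * info_lost / n_sub,
                }
            )
    return pd.DataFrame(rows)
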