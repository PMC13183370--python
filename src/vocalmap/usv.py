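"""Ultrasonic vocalization (USV) event segmentation and per-event features.

Mouse courtship calls are near-tonal frequency-modulated whistles above 30 kHz.
Events are segmented from a band-limited spectrogram with a spectral-bandwidth rule:
a frame belongs to a call when (i) its in-band energy clears an adaptive threshold
above the recording's noise floor and (ii) the minimal contiguous frequency interval
around the spectral peak holding half of the frame's in-band energy is narrow
(tonal), which rejects broadband noise bursts. Call-positive runs separated by gaps
no longer than the hold time (20 ms) are merged into one event; merged runs shorter
than the post-filter duration (1 ms) are discarded.

Per event, peak frequency and peak amplitude are read at three loci: the start frame,
the end frame and the maximum-amplitude frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

_DB_FLOOR = -200.0  # dBFS floor used in place of log(0)


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time Fourier transform settings for USV analysis.

    The defaults (512-sample Hann window, 75% overlap) give a hop of about 0.5 ms at
    a 250 kHz sampling rate, fine enough to resolve the 1 ms post-filter. The analysis
    band is 30-120 kHz; bins outside it carry zero weight downstream.
    """

    window_samples: int = 512
    overlap_fraction: float = 0.75
    band_low_khz: float = 30.0
    band_high_khz: float = 120.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 < self.band_low_khz < self.band_high_khz:
            raise ValueError("need 0 < band_low_khz < band_high_khz")
        if self.window_samples < 8:
            raise ValueError("window_samples too small")


@dataclass(frozen=True)
class SegmentationParams:
    """Spectral-bandwidth segmentation settings.

    energy_threshold_db is measured above the recording's median in-band frame energy
    (a robust noise-floor estimate). bandwidth_fraction is the energy fraction of the
    tonality criterion; the 50%-energy interval must be narrower than
    ``tonality_ceiling_khz`` for a frame to count as call-positive.
    """

    energy_threshold_db: float = 6.0
    bandwidth_fraction: float = 0.5
    hold_time_ms: float = 20.0
    postfilter_ms: float = 1.0
    tonality_ceiling_khz: float = 20.0
    edge_trim_db: float = 6.0

    def __post_init__(self) -> None:
        if not self.hold_time_ms > self.postfilter_ms > 0:
            raise ValueError("need hold_time_ms > postfilter_ms > 0")
        if not 0 < self.bandwidth_fraction < 1:
            raise ValueError("bandwidth_fraction must be in (0, 1)")


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency magnitude array in dB re full scale, with axes and band mask."""

    magnitude_db: np.ndarray  # (n_freqs, n_frames)
    times_s: np.ndarray
    freqs_hz: np.ndarray
    band_mask: np.ndarray  # True for bins inside the analysis band
    sample_rate_hz: float
    params: SpectrogramParams

    @property
    def hop_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0]) if len(self.times_s) > 1 else 0.0

    def inband_power(self) -> np.ndarray:
        """Linear power per frame summed over in-band bins."""
        p = 10.0 ** (self.magnitude_db / 10.0)
        p[self.magnitude_db <= _DB_FLOOR] = 0.0
        return p[self.band_mask].sum(axis=0)

    def inband_energy_db(self) -> np.ndarray:
        """In-band frame energy in dB (floor applied to silent frames)."""
        p = self.inband_power()
        with np.errstate(divide="ignore"):
            e = 10.0 * np.log10(p)
        return np.where(np.isfinite(e), e, _DB_FLOOR)


@dataclass(frozen=True)
class USVEvent:
    """One segmented call with features at the start / end / max-amplitude loci."""

    start_s: float
    end_s: float
    duration_ms: float
    pf_start_khz: float = np.nan
    pf_end_khz: float = np.nan
    pf_max_khz: float = np.nan
    amp_start_db: float = np.nan
    amp_end_db: float = np.nan
    amp_max_db: float = np.nan
    frame_slice: tuple[int, int] = field(default=(0, 0), compare=False)

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("event must have end_s > start_s")


def compute_spectrogram(
    waveform: np.ndarray, sample_rate_hz: float, params: SpectrogramParams | None = None
) -> Spectrogram:
    """STFT magnitude spectrogram in dB relative to full scale.

    A full-scale sine (amplitude 1.0) peaks at 0 dB. Frames are centred; times are
    seconds from recording start. Raises if the waveform is shorter than one window.
    """
    if params is None:
        params = SpectrogramParams()
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    if x.size < params.window_samples:
        raise ValueError("waveform shorter than one analysis window")
    if params.band_high_khz * 1e3 > sample_rate_hz / 2 + 1e-9:
        raise ValueError("band_high_khz exceeds the Nyquist frequency")
    win = hann(params.window_samples, sym=False)
    hop = max(1, int(round(params.window_samples * (1 - params.overlap_fraction))))
    sft = ShortTimeFFT(win, hop=hop, fs=sample_rate_hz, scale_to=None)
    S = sft.stft(x)
    # amplitude of a full-scale sine maps to win.sum()/2 in an un-scaled STFT
    mag = 2.0 * np.abs(S) / win.sum()
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(mag)
    mag_db = np.where(np.isfinite(mag_db), mag_db, _DB_FLOOR)
    mag_db = np.maximum(mag_db, _DB_FLOOR)
    times = sft.t(x.size)
    freqs = sft.f
    band = (freqs >= params.band_low_khz * 1e3) & (freqs <= params.band_high_khz * 1e3)
    return Spectrogram(mag_db, times, freqs, band, sample_rate_hz, params)


def _bandwidth_khz(power_col: np.ndarray, freqs_khz: np.ndarray, fraction: float) -> float:
    """Width of the minimal contiguous bin interval around the peak holding
    ``fraction`` of the column's total energy, in kHz."""
    total = power_col.sum()
    if total <= 0:
        return np.inf
    k = int(np.argmax(power_col))
    lo = hi = k
    acc = power_col[k]
    target = fraction * total
    while acc < target:
        left = power_col[lo - 1] if lo > 0 else -1.0
        right = power_col[hi + 1] if hi + 1 < power_col.size else -1.0
        if left < 0 and right < 0:
            break
        if right > left:
            hi += 1
            acc += power_col[hi]
        else:
            lo -= 1
            acc += power_col[lo]
    df = freqs_khz[1] - freqs_khz[0] if freqs_khz.size > 1 else 0.0
    return (hi - lo + 1) * df


def call_positive_frames(spec: Spectrogram, params: SegmentationParams) -> np.ndarray:
    """Boolean frame mask of the two-part call criterion (energy and tonality)."""
    energy_db = spec.inband_energy_db()
    floor_db = float(np.median(energy_db))
    loud = energy_db >= floor_db + params.energy_threshold_db
    if floor_db <= _DB_FLOOR:  # silent recording: the floor itself is undefined
        return np.zeros_like(loud)
    power = 10.0 ** (spec.magnitude_db / 10.0)
    power[spec.magnitude_db <= _DB_FLOOR] = 0.0
    power = power[spec.band_mask]
    freqs_khz = spec.freqs_hz[spec.band_mask] / 1e3
    positive = np.zeros_like(loud)
    for t in np.nonzero(loud)[0]:
        bw = _bandwidth_khz(power[:, t], freqs_khz, params.bandwidth_fraction)
        positive[t] = bw < params.tonality_ceiling_khz
    return positive


def segment_events(spec: Spectrogram, params: SegmentationParams | None = None) -> list[USVEvent]:
    """Segment call events from a band-annotated spectrogram.

    Positive runs separated by gaps <= hold_time_ms are merged, then trimmed at half
    power: leading/trailing frames more than edge_trim_db below the run's peak
    in-band energy are dropped, undoing the temporal smearing of the analysis window
    at the event edges. Merged runs whose trimmed duration (span of positive frame
    centres) is below postfilter_ms are discarded. Events are reported at frame
    centres, time-ordered and non-overlapping.
    """
    if params is None:
        params = SegmentationParams()
    positive = call_positive_frames(spec, params)
    if not positive.any():
        return []
    hop = spec.hop_s
    idx = np.nonzero(positive)[0]
    # contiguous runs of positive frames
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = [(int(r[0]), int(r[-1])) for r in np.split(idx, breaks + 1)]
    # merge runs whose inter-run gap (time between facing frame centres) <= hold time
    merged = [runs[0]]
    hold_s = params.hold_time_ms / 1e3
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if (s - pe) * hop <= hold_s:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    energy_db = spec.inband_energy_db()
    events = []
    for s, e in merged:
        peak = energy_db[s : e + 1].max()
        while e > s and energy_db[s] < peak - params.edge_trim_db:
            s += 1
        while e > s and energy_db[e] < peak - params.edge_trim_db:
            e -= 1
        duration_s = (e - s) * hop
        if duration_s < params.postfilter_ms / 1e3:
            continue
        events.append(
            USVEvent(
                start_s=float(spec.times_s[s]),
                end_s=float(spec.times_s[e]),
                duration_ms=duration_s * 1e3,
                frame_slice=(s, e),
            )
        )
    return events


def extract_features(event: USVEvent, spec: Spectrogram) -> USVEvent:
    """Fill the event's peak frequency and amplitude at the three loci.

    Locus frames are the event's first frame, last frame and the frame with the
    largest in-band peak magnitude; per locus the peak frequency is the
    argmax-magnitude in-band bin and the amplitude is that bin's dB value.
    """
    s, e = event.frame_slice
    if s < 0 or e >= spec.magnitude_db.shape[1] or e < s:
        raise ValueError("event frames outside the spectrogram extent")
    band_db = spec.magnitude_db[spec.band_mask]
    freqs_khz = spec.freqs_hz[spec.band_mask] / 1e3
    seg = band_db[:, s : e + 1]
    frame_peaks = seg.max(axis=0)
    k_max = int(np.argmax(frame_peaks)) + s

    def locus(t: int) -> tuple[float, float]:
        col = band_db[:, t]
        k = int(np.argmax(col))
        return float(freqs_khz[k]), float(col[k])

    pf_s, amp_s = locus(s)
    pf_e, amp_e = locus(e)
    pf_m, amp_m = locus(k_max)
    return replace(
        event,
        pf_start_khz=pf_s, pf_end_khz=pf_e, pf_max_khz=pf_m,
        amp_start_db=amp_s, amp_end_db=amp_e, amp_max_db=amp_m,
    )


def detect_usv(
    waveform: np.ndarray,
    sample_rate_hz: float,
    spec_params: SpectrogramParams | None = None,
    seg_params: SegmentationParams | None = None,
) -> list[USVEvent]:
    """Full detection pipeline: spectrogram -> segmentation -> features."""
    spec = compute_spectrogram(waveform, sample_rate_hz, spec_params)
    events = segment_events(spec, seg_params)
    return [extract_features(ev, spec) for ev in events]


def count_events(events: list[USVEvent]) -> dict:
    """Per-session summary: event count and total vocal time."""
    return {
        "n_events": len(events),
        "total_vocal_time_s": float(sum(ev.duration_ms for ev in events)) / 1e3,
    }


def events_table(events: list[USVEvent], mouse_id: str = "") -> pd.DataFrame:
    """Events as the long export table."""
    rows = [
        {
            "mouse_id": mouse_id,
            "event_index": i,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_ms": ev.duration_ms,
            "pf_start_khz": ev.pf_start_khz,
            "pf_end_khz": ev.pf_end_khz,
            "pf_max_khz": ev.pf_max_khz,
            "amp_start_db": ev.amp_start_db,
            "amp_end_db": ev.amp_end_db,
            "amp_max_db": ev.amp_max_db,
        }
        for i, ev in enumerate(events)
    ]
    return pd.DataFrame(rows)


def evaluate_detection(
    events: list[USVEvent],
    truth_events: list[tuple[float, float]],
    boundary_tol_s: float = 0.005,
) -> dict:
    """Precision / recall of detected events against ground-truth (start, end) pairs.

    A detection matches a truth call when the intervals overlap; each truth call can
    be claimed by at most one detection (greedy by start time). Boundary error is the
    larger of the start and end offsets of matched pairs.
    """
    matched_truth = set()
    matches = []
    for ev in events:
        best = None
        for k, (ts, te) in enumerate(truth_events):
            if k in matched_truth:
                continue
            if ev.start_s <= te and ev.end_s >= ts:
                best = k
                break
        if best is not None:
            matched_truth.add(best)
            ts, te = truth_events[best]
            matches.append(max(abs(ev.start_s - ts), abs(ev.end_s - te)))
    tp = len(matches)
    precision = tp / len(events) if events else (1.0 if not truth_events else 0.0)
    recall = tp / len(truth_events) if truth_events else 1.0
    within = [m for m in matches if m <= boundary_tol_s]
    return {
        "precision": precision,
        "recall": recall,
        "n_detected": len(events),
        "n_truth": len(truth_events),
        "n_matched": tp,
        "n_matched_within_tol": len(within),
        "max_boundary_error_s": max(matches) if matches else 0.0,
    }
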