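"""SI-projection navigator simulation and threshold motion gating.

One navigator readout per IR segment yields a 1D superior-inferior
projection profile of the head.  Head motion (modelled as instantaneous
rigid SI translations) shifts the profile; the scalar navigator trace is
the profile amplitude at a fixed reference pixel (the position of maximum
signal at the first time point).  Threshold gating clusters the trace into
contiguous plateaus, keeps the plateau containing the most segments, and
rejects everything else — every spoke of a rejected segment is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "NavigatorRecord",
    "GatingResult",
    "default_head_profile",
    "si_projection",
    "simulate_navigator",
    "extract_trace",
    "threshold_gate",
    "reject_fraction_mask",
]


def default_head_profile(n_z: int = 220) -> np.ndarray:
    """Synthetic head SI-projection: smooth envelope + bright vertex feature.

    The localized bright feature (subcutaneous fat at the vertex) gives the
    trace a well-defined reference pixel that is sensitive to SI shifts.
    """
    z = np.arange(n_z, dtype=float)
    c = n_z / 2.0
    half = 0.38 * n_z
    arg = np.clip((z - c) / half, -1.0, 1.0)
    envelope = np.clip(np.cos(0.5 * np.pi * arg), 0.0, None) ** 0.7
    feature = 0.8 * np.exp(-((z - (c - 0.55 * half)) ** 2) / (2 * (0.04 * n_z) ** 2))
    return envelope + feature


def si_projection(image: np.ndarray) -> np.ndarray:
    """SI projection of a 2D image: sum along the left-right axis."""
    return np.asarray(image, dtype=float).sum(axis=1)


@dataclass
class MotionTrace:
    """Piecewise-constant rigid SI head position over the scan.

    ``event_segments[i]`` is the first segment acquired *after* the i-th
    instantaneous movement; ``shifts[i]`` the SI displacement (mm) added at
    that event.  ``baseline_profile`` is the head projection P(z) at the
    initial position.
    """

    baseline_profile: np.ndarray
    event_segments: list[int] = field(default_factory=list)
    shifts: list[float] = field(default_factory=list)  # mm per event
    pixel_size: float = 1.0  # mm per profile pixel

    def __post_init__(self) -> None:
        self.baseline_profile = np.asarray(self.baseline_profile, dtype=float)
        if len(self.event_segments) != len(self.shifts):
            raise ValueError("event_segments and shifts must have equal length")
        if list(self.event_segments) != sorted(set(self.event_segments)):
            raise ValueError("event_segments must be strictly increasing")
        fov = len(self.baseline_profile) * self.pixel_size
        if any(abs(np.cumsum(self.shifts)) > fov / 4):
            raise ValueError("cumulative shift exceeds FOV/4")

    def cumulative_shift(self, segment: int) -> float:
        """Total SI displacement (mm) in effect at a given segment."""
        total = 0.0
        for ev, sh in zip(self.event_segments, self.shifts):
            if segment >= ev:
                total += sh
        return total


@dataclass
class NavigatorRecord:
    """Per-segment SI projection profiles and the derived scalar trace."""

    profiles: np.ndarray                # (n_segments, N_z)
    ref_pixel: int | None = None
    trace: np.ndarray | None = None


def _fourier_shift(profile: np.ndarray, shift_px: float) -> np.ndarray:
    """Circular sub-pixel translation via the Fourier shift theorem."""
    n = len(profile)
    freqs = np.fft.fftfreq(n)
    phase = np.exp(-2j * np.pi * freqs * shift_px)
    return np.real(np.fft.ifft(np.fft.fft(profile) * phase))


def simulate_navigator(
    motion: MotionTrace,
    n_segments: int,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> NavigatorRecord:
    """Simulate the per-segment navigator profiles under the motion trace.

    Profile for segment ``s`` is the baseline projection translated by the
    cumulative shift in effect at ``s`` (circular Fourier shift), plus white
    Gaussian noise of standard deviation ``noise_sd``.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_z = len(motion.baseline_profile)
    profiles = np.empty((n_segments, n_z))
    # shifts are piecewise constant: compute one translated profile per level
    cache: dict[float, np.ndarray] = {}
    for s in range(n_segments):
        shift_px = motion.cumulative_shift(s) / motion.pixel_size
        if shift_px not in cache:
            cache[shift_px] = _fourier_shift(motion.baseline_profile, shift_px)
        profiles[s] = cache[shift_px]
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)
    return NavigatorRecord(profiles=profiles)


def extract_trace(record: NavigatorRecord) -> np.ndarray:
    """Navigator trace: profile amplitude at the fixed reference pixel.

    The reference pixel is the argmax of the first profile; the record's
    ``ref_pixel``/``trace`` fields are filled in place.
    """
    if record.profiles.ndim != 2 or record.profiles.shape[0] < 1:
        raise ValueError("record must contain at least one profile")
    first = record.profiles[0]
    if not np.any(first != 0):
        raise ValueError("first profile is all-zero: no reference pixel definable")
    ref = int(np.argmax(first))
    record.ref_pixel = ref
    record.trace = record.profiles[:, ref].copy()
    return record.trace


@dataclass
class GatingResult:
    """Accept/reject decision per segment and per spoke."""

    segment_accept: np.ndarray      # bool, (n_segments,)
    spoke_accept: np.ndarray        # bool, (n_spokes,)
    threshold: float                # gating window half-width
    plateau_level: float            # selected plateau level c
    rejected_count: int             # spokes rejected
    rejected_fraction: float

    def to_frame(self, trace: np.ndarray | None = None) -> pd.DataFrame:
        cols = {"segment": np.arange(len(self.segment_accept)),
                "accepted": self.segment_accept.astype(int)}
        if trace is not None:
            cols["trace"] = trace
        return pd.DataFrame(cols)


def _contiguous_runs(trace: np.ndarray, max_range: float) -> list[tuple[int, int]]:
    """Greedy left-to-right split into runs whose value range <= max_range."""
    runs = []
    start = 0
    lo = hi = trace[0]
    for s in range(1, len(trace)):
        lo2, hi2 = min(lo, trace[s]), max(hi, trace[s])
        if hi2 - lo2 > max_range:
            runs.append((start, s))
            start, lo, hi = s, trace[s], trace[s]
        else:
            lo, hi = lo2, hi2
    runs.append((start, len(trace)))
    return runs


def threshold_gate(
    trace: np.ndarray,
    window: float | None = None,
    segment_id: np.ndarray | None = None,
    spokes_per_segment: int | None = None,
) -> GatingResult:
    """Threshold gating: keep the longest stable plateau of the trace.

    The trace is split into contiguous runs whose in-run range is at most
    ``2 * window``; the run containing the most segments wins (ties go to
    the earliest run).  Segments are accepted iff they lie in the selected
    run and within ``window`` of its level ``c`` (the run midrange).
    ``window`` defaults to 3x the robust noise SD of the trace
    (median absolute deviation x 1.4826).

    Spoke-level masks are derived from ``segment_id`` (per-spoke segment
    index) or ``spokes_per_segment``; with neither, one spoke per segment
    is assumed.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 1:
        raise ValueError("trace must be a non-empty 1D array")
    if window is None:
        mad = np.median(np.abs(trace - np.median(trace)))
        window = 3.0 * 1.4826 * mad
        if window == 0.0:  # noiseless/constant trace: any positive window works
            window = max(1e-6, 1e-6 * abs(float(np.median(trace))))
    if window <= 0:
        raise ValueError("window must be > 0")

    runs = _contiguous_runs(trace, 2.0 * window)
    best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    if best[1] - best[0] < 2 and len(trace) >= 2:
        raise ValueError(
            "no stable plateau found: the gating window is too small for the "
            "trace variability; increase the window"
        )
    vals = trace[best[0]:best[1]]
    level = 0.5 * (vals.min() + vals.max())
    segment_accept = np.zeros(len(trace), dtype=bool)
    idx = np.arange(best[0], best[1])
    segment_accept[idx] = np.abs(trace[idx] - level) <= window + 1e-12

    if segment_id is not None:
        segment_id = np.asarray(segment_id)
        spoke_accept = segment_accept[segment_id]
    elif spokes_per_segment is not None:
        spoke_accept = np.repeat(segment_accept, spokes_per_segment)
    else:
        spoke_accept = segment_accept.copy()

    rejected = int((~spoke_accept).sum())
    return GatingResult(
        segment_accept=segment_accept,
        spoke_accept=spoke_accept,
        threshold=float(window),
        plateau_level=float(level),
        rejected_count=rejected,
        rejected_fraction=rejected / len(spoke_accept),
    )


def reject_fraction_mask(
    n_spokes: int, fraction: float, start: int | None = None
) -> np.ndarray:
    """Accept mask rejecting one contiguous acquisition-order block.

    ``floor(fraction * n_spokes)`` spokes are rejected; by default the final
    block of the acquisition (mimicking a late motion event).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    n_reject = int(np.floor(fraction * n_spokes))
    accept = np.ones(n_spokes, dtype=bool)
    if n_reject == 0:
        return accept
    if start is None:
        start = n_spokes - n_reject
    if start < 0 or start + n_reject > n_spokes:
        raise ValueError("rejected block does not fit in the acquisition")
    accept[start:start + n_reject] = False
    return accept
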