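"""Microglial process recruitment to focal ATP events.

Given a paired pair of traces — the ATP-sensor ΔF/F within an event ROI and
the microglia-reporter mean fluorescence (MFI) over the same ROI — this
module quantifies the recruitment response as a percent change of baseline
(Δ%MFI), classifies the response as a directed movement, estimates the
movement latency, and aggregates directed-movement prevalence with a
binomial confidence interval.

The Δ%MFI rule follows the two-branch definition used for these recordings:
baseline is the mean reporter signal over the 100 s preceding the ATP event
peak; the response is the reporter value at the peak closest in time to the
ATP peak when a definitive peak exists within 300 s after it, and otherwise
the mean over the 100 s after the ATP peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import binomtest

__all__ = [
    "RecruitmentPair",
    "RecruitmentResult",
    "recruitment_dmfi",
    "classify_directed",
    "directed_prevalence",
    "movement_latency",
]

#: Default analysis windows (s): baseline before the ATP peak, peak search
#: after it, and the fallback post-event averaging window.
BASELINE_WINDOW_S = 100.0
SEARCH_WINDOW_S = 300.0
POST_WINDOW_S = 100.0


@dataclass(frozen=True)
class RecruitmentPair:
    """ATP ΔF/F trace and microglia-reporter MFI trace over one event ROI."""

    atp_trace: np.ndarray
    mg_trace: np.ndarray
    dt: float
    atp_peak_time: float

    def __post_init__(self) -> None:
        atp = np.asarray(self.atp_trace, dtype=float)
        mg = np.asarray(self.mg_trace, dtype=float)
        object.__setattr__(self, "atp_trace", atp)
        object.__setattr__(self, "mg_trace", mg)
        if atp.shape != mg.shape or atp.ndim != 1:
            raise ValueError("atp_trace and mg_trace must be 1-D and equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        span = (atp.size - 1) * self.dt
        if not 0 <= self.atp_peak_time <= span:
            raise ValueError("atp_peak_time outside the trace span")


@dataclass
class RecruitmentResult:
    baseline: float
    response: float
    dmfi_percent: float
    latency: float  # s, nan when undefined
    directed: bool
    rule_used: Literal["peak", "post-window-average"]


def recruitment_dmfi(
    pair: RecruitmentPair,
    search_window: float = SEARCH_WINDOW_S,
    baseline_window: float = BASELINE_WINDOW_S,
    post_window: float = POST_WINDOW_S,
    peak_prominence_sd: float = 3.0,
) -> RecruitmentResult:
    """Percent change of reporter MFI from pre-event baseline (Δ%MFI).

    A "definitive" reporter peak is a local maximum within ``search_window``
    seconds after the ATP peak rising at least ``peak_prominence_sd``
    baseline-window SDs above the baseline with at least that same
    prominence (noise wobble inside the baseline band, or riding on a
    rising limb, never counts as a response).  When one exists, the
    response is the reporter value at the peak closest in time to the ATP
    peak (``rule_used="peak"``); otherwise the reporter signal is averaged
    over ``post_window`` seconds after the ATP peak
    (``rule_used="post-window-average"``).
    """
    mg = pair.mg_trace
    ipk = int(round(pair.atp_peak_time / pair.dt))
    n_base = int(round(baseline_window / pair.dt))
    if ipk - n_base < 0:
        raise ValueError(
            f"need {baseline_window} s of reporter signal before the ATP peak"
        )
    base_seg = mg[ipk - n_base : ipk]
    baseline = float(base_seg.mean())
    if baseline <= 0:
        raise ValueError("nonpositive baseline MFI")
    base_sd = float(base_seg.std())
    height = baseline + peak_prominence_sd * base_sd if base_sd > 0 else None
    prominence = peak_prominence_sd * base_sd if base_sd > 0 else None

    n_search = int(round(search_window / pair.dt))
    stop = min(mg.size, ipk + n_search + 1)
    seg = mg[ipk:stop]
    peaks, _ = find_peaks(seg, height=height, prominence=prominence)
    if peaks.size > 0:
        nearest = int(peaks[np.argmin(peaks)])  # peaks are offsets from ipk
        response = float(seg[nearest])
        rule: Literal["peak", "post-window-average"] = "peak"
    else:
        n_post = int(round(post_window / pair.dt))
        post = mg[ipk : min(mg.size, ipk + n_post)]
        if post.size == 0:
            raise ValueError("no samples after the ATP peak")
        response = float(post.mean())
        rule = "post-window-average"
    dmfi = 100.0 * (response - baseline) / baseline
    return RecruitmentResult(
        baseline=baseline,
        response=response,
        dmfi_percent=dmfi,
        latency=math.nan,
        directed=False,
        rule_used=rule,
    )


def classify_directed(
    result: RecruitmentResult,
    dmfi_min: float = 10.0,
    require_peak: bool = False,
) -> bool:
    """Directed movement: Δ%MFI at or above ``dmfi_min`` percent.

    With ``require_peak`` the peak branch of the Δ%MFI rule must have fired
    (a definitive reporter peak existed); the flag is also stored on the
    result in place.
    """
    directed = result.dmfi_percent >= dmfi_min
    if require_peak:
        directed = directed and result.rule_used == "peak"
    result.directed = directed
    return directed


def directed_prevalence(
    results: Sequence[RecruitmentResult],
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fraction of responses classified directed, with a binomial CI."""
    if len(results) == 0:
        raise ValueError("prevalence undefined for an empty result set")
    k = sum(r.directed for r in results)
    n = len(results)
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence)
    return k / n, (float(ci.low), float(ci.high))


def movement_latency(
    pair: RecruitmentPair,
    k_sd: float = 2.0,
    baseline_window: float = BASELINE_WINDOW_S,
    min_sustained: int = 2,
) -> float:
    """Latency from the ATP peak to the onset of the reporter response.

    The onset is the first time after the ATP peak at which the reporter
    trace exceeds ``baseline + k_sd * SD(baseline window)`` and stays above
    for at least ``min_sustained`` consecutive samples.  Returns ``nan``
    when the threshold is never exceeded.  (The published measurement was
    shown graphically only; this explicit rule is this package's own.)
    """
    mg = pair.mg_trace
    ipk = int(round(pair.atp_peak_time / pair.dt))
    n_base = int(round(baseline_window / pair.dt))
    if ipk - n_base < 0:
        raise ValueError("insufficient baseline samples before the ATP peak")
    base_seg = mg[ipk - n_base : ipk]
    threshold = float(base_seg.mean()) + k_sd * float(base_seg.std())
    above = mg[ipk + 1 :] > threshold
    run = 0
    for offset, flag in enumerate(above, start=1):
        run = run + 1 if flag else 0
        if run >= min_sustained:
            onset = offset - min_sustained + 1
            return onset * pair.dt
    return math.nan
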