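"""Synthetic ground-truth generators for every pipeline input.

The source recordings and images behind these analyses are not publicly
deposited, so each downstream stage is exercised on synthetic data with
known ground truth:

* :func:`simulate_lfp` — pink-noise (1/f) field potential with sharp-wave
  deflections carrying a ~200 Hz ripple under a Gaussian envelope,
* :func:`simulate_atp_movie` — time-lapse movie with a decaying background
  and focal sensor transients drawn from two log-normal feature clusters
  (flash vs surge),
* :func:`simulate_recruitment_pair` — paired ATP/microglia-reporter traces
  with an optional delayed directed response,
* :func:`simulate_cell_map` — depth-drifting cell populations in a slab,
* :func:`simulate_puncta_scene` — pre/post/microglia puncta images with true
  synapse positions and contact flags.

All randomness flows through one seeded generator per call; identical spec
plus seed reproduces bit-identical output.  Every generated feature has
exactly one ground-truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .atp_events import TimelapseStack
from .histo_quant import PunctaScene
from .lfp_swr import LFPRecording

__all__ = [
    "ValidationError",
    "PlacementError",
    "GroundTruth",
    "SWRSimSpec",
    "ATPClassParams",
    "ATPSimSpec",
    "FLASH_PARAMS",
    "SURGE_PARAMS",
    "simulate_lfp",
    "simulate_atp_movie",
    "sample_event_features",
    "simulate_recruitment_pair",
    "simulate_cell_map",
    "simulate_puncta_scene",
]


class ValidationError(ValueError):
    """A simulation spec violates its invariants; the message names the field."""


class PlacementError(RuntimeError):
    """The scene is too small to place the requested objects."""


def _require(ok: bool, name: str, msg: str) -> None:
    if not ok:
        raise ValidationError(f"{name}: {msg}")


@dataclass
class GroundTruth:
    """Per-generator truth: one record per generated feature, plus metadata."""

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.events)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# LFP with sharp wave-ripples
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SWRSimSpec:
    """Parameters of the sharp wave-ripple field-potential simulation.

    Sharp waves are negative deflections (the convention of CA3 pyramidal
    layer recordings) with a Gaussian envelope of SD ``swr_width`` seconds
    and peak magnitude ``swr_amplitude`` µV, carrying a ripple oscillation
    at ``ripple_freq`` Hz under the same envelope.  Event times follow a
    Poisson process of rate ``event_rate``; alternatively ``n_events`` fixes
    the exact count, with times drawn uniformly at least ``min_event_gap``
    seconds apart.  The background is 1/f-coloured noise of SD ``noise_sd``.
    """

    duration: float
    fs: float = 10_000.0  # acquisition default: 10 kHz digitization
    noise_sd: float = 20.0
    event_rate: float = 0.5
    swr_amplitude: float = 120.0
    swr_width: float = 0.03
    ripple_freq: float = 200.0
    ripple_amplitude: float = 30.0
    seed: int = 0
    n_events: int | None = None
    min_event_gap: float = 0.3

    def __post_init__(self) -> None:
        _require(self.duration > 0, "duration", "must be positive")
        _require(self.fs > 2 * self.ripple_freq, "fs", "must exceed 2 x ripple_freq")
        _require(self.event_rate >= 0, "event_rate", "must be nonnegative")
        for name in ("noise_sd", "swr_amplitude", "ripple_amplitude"):
            _require(getattr(self, name) >= 0, name, "must be nonnegative")
        _require(self.swr_width > 0, "swr_width", "must be positive")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-coloured noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spectrum * shape, n)
    return x / x.std()


def _draw_event_times(spec: SWRSimSpec, rng: np.random.Generator) -> np.ndarray:
    margin = 5.0 * spec.swr_width
    lo, hi = margin, spec.duration - margin
    if hi <= lo:
        return np.array([])
    if spec.n_events is not None:
        times: list[float] = []
        for _ in range(200 * spec.n_events + 200):
            if len(times) == spec.n_events:
                break
            t = float(rng.uniform(lo, hi))
            if all(abs(t - u) >= spec.min_event_gap for u in times):
                times.append(t)
        if len(times) < spec.n_events:
            raise PlacementError(
                f"could not place {spec.n_events} events {spec.min_event_gap} s apart "
                f"in {spec.duration} s"
            )
        return np.sort(times)
    count = rng.poisson(spec.event_rate * spec.duration)
    return np.sort(rng.uniform(lo, hi, size=count))


def simulate_lfp(spec: SWRSimSpec) -> tuple[LFPRecording, GroundTruth]:
    """Generate a field-potential trace with embedded sharp wave-ripples.

    Returns the recording (µV) and the ground truth listing every event's
    peak time, sharp-wave amplitude and ripple frequency.  With both
    ``swr_amplitude`` and ``ripple_amplitude`` zero, the output is pure
    noise and the truth is empty.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.fs)
    x = _pink_noise(n, rng) * spec.noise_sd
    silent = spec.swr_amplitude == 0 and spec.ripple_amplitude == 0
    times = np.array([]) if silent else _draw_event_times(spec, rng)
    t_axis = np.arange(n) / spec.fs
    for t0 in times:
        i0 = max(0, int((t0 - 5 * spec.swr_width) * spec.fs))
        i1 = min(n, int((t0 + 5 * spec.swr_width) * spec.fs) + 1)
        tt = t_axis[i0:i1] - t0
        envelope = np.exp(-(tt**2) / (2 * spec.swr_width**2))
        x[i0:i1] -= spec.swr_amplitude * envelope
        x[i0:i1] -= spec.ripple_amplitude * envelope * np.cos(
            2 * math.pi * spec.ripple_freq * tt
        )
    truth = GroundTruth(
        events=pd.DataFrame(
            {
                "peak_time_s": times,
                "amplitude_uv": np.full(times.size, spec.swr_amplitude),
                "ripple_freq_hz": np.full(times.size, spec.ripple_freq),
            }
        ),
        meta={"spec": spec},
    )
    return LFPRecording(samples=x, fs=spec.fs), truth


# --------------------------------------------------------------------------- #
# ATP-sensor movies
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ATPClassParams:
    """Log-normal feature parameters of one event class (natural-log space).

    Event features reported for these sensors follow log-normal
    distributions; flashes are dimmer/faster/smaller, surges
    brighter/slower/bigger.  ``*_log_mean`` is the log of the class median.
    """

    peak_dff_log_mean: float
    area_log_mean: float  # µm²
    duration_log_mean: float  # s (FWHM)
    rise_log_mean: float  # s (exponential rise tau)
    decay_log_mean: float  # s (exponential decay tau)
    log_sd: float = 0.3

    def __post_init__(self) -> None:
        _require(self.log_sd > 0, "log_sd", "must be positive")


FLASH_PARAMS = ATPClassParams(
    peak_dff_log_mean=math.log(0.4),
    area_log_mean=math.log(30.0),
    duration_log_mean=math.log(10.0),
    rise_log_mean=math.log(1.5),
    decay_log_mean=math.log(4.0),
)
SURGE_PARAMS = ATPClassParams(
    peak_dff_log_mean=math.log(1.6),
    area_log_mean=math.log(150.0),
    duration_log_mean=math.log(40.0),
    rise_log_mean=math.log(5.0),
    decay_log_mean=math.log(12.0),
)


@dataclass(frozen=True)
class ATPSimSpec:
    """Parameters of the ATP-sensor time-lapse simulation.

    Defaults emulate the acquisition conditions: 10 min movies at
    0.5 frame/s (300 frames, dt 2 s) over a 256 x 128 µm field, with a
    background that decays exponentially from ``background_f0`` and focal
    transients from the flash and surge clusters at ``flash_rate`` and
    ``surge_rate`` expected events per movie.
    """

    n_frames: int = 300
    dt: float = 2.0
    height: int = 128
    width: int = 256
    pixel_size: float = 1.0  # µm / px
    background_f0: float = 100.0
    background_decay_tau: float = 1200.0
    flash_params: ATPClassParams = FLASH_PARAMS
    surge_params: ATPClassParams = SURGE_PARAMS
    flash_rate: float = 10.0
    surge_rate: float = 5.0
    shot_noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(self.dt > 0, "dt", "must be positive")
        _require(self.pixel_size > 0, "pixel_size", "must be positive")
        _require(self.height > 0 and self.width > 0, "height/width", "must be positive")
        _require(self.background_f0 > 0, "background_f0", "must be positive")
        _require(self.background_decay_tau > 0, "background_decay_tau", "must be positive")
        _require(self.flash_rate >= 0, "flash_rate", "must be nonnegative")
        _require(self.surge_rate >= 0, "surge_rate", "must be nonnegative")


def sample_event_features(
    params: ATPClassParams, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` log-normal feature vectors for one event class."""
    def draw(mu: float) -> np.ndarray:
        return np.exp(rng.normal(mu, params.log_sd, size=n))

    return pd.DataFrame(
        {
            "peak_dff": draw(params.peak_dff_log_mean),
            "area_um2": draw(params.area_log_mean),
            "duration_s": draw(params.duration_log_mean),
            "rise_tau_s": draw(params.rise_log_mean),
            "decay_tau_s": draw(params.decay_log_mean),
        }
    )


_RISE_SPAN_TAUS = 5.0  # the rise limb spans 5 rise-taus up to the peak


def _kernel_fwhm_parts(rise_tau: float, decay_tau: float, duration: float) -> tuple[float, float]:
    """(plateau, realized FWHM) of the rise-plateau-decay temporal kernel."""
    ceiling = 1.0 - math.exp(-_RISE_SPAN_TAUS)
    t_half = -rise_tau * math.log(1.0 - 0.5 * ceiling)
    rise_part = _RISE_SPAN_TAUS * rise_tau - t_half
    decay_part = decay_tau * math.log(2.0)
    plateau = max(0.0, duration - rise_part - decay_part)
    return plateau, rise_part + plateau + decay_part


def _event_time_profile(
    frame_times: np.ndarray, t_peak: float, rise_tau: float, decay_tau: float, plateau: float
) -> np.ndarray:
    """Normalized rise-plateau-decay kernel evaluated at the frame times."""
    t_on = t_peak - _RISE_SPAN_TAUS * rise_tau
    ceiling = 1.0 - math.exp(-_RISE_SPAN_TAUS)
    out = np.zeros_like(frame_times)
    rising = (frame_times >= t_on) & (frame_times < t_peak)
    out[rising] = (1.0 - np.exp(-(frame_times[rising] - t_on) / rise_tau)) / ceiling
    flat = (frame_times >= t_peak) & (frame_times <= t_peak + plateau)
    out[flat] = 1.0
    falling = frame_times > t_peak + plateau
    out[falling] = np.exp(-(frame_times[falling] - t_peak - plateau) / decay_tau)
    return out


def simulate_atp_movie(spec: ATPSimSpec) -> tuple[TimelapseStack, GroundTruth]:
    """Generate an ATP-sensor movie with ground-truth flash/surge events.

    Each event has a 2-D Gaussian spatial footprint (sigma set so the
    half-maximum disk matches the drawn area) and a temporal kernel that
    rises exponentially with the drawn rise tau, holds a plateau long enough
    to honor the drawn FWHM duration, and decays exponentially with the
    drawn decay tau.  The ground truth records the realized kernel FWHM as
    the event duration.  Shot-like noise with SD proportional to the square
    root of the local intensity is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames) * spec.dt
    background = spec.background_f0 * np.exp(-times / spec.background_decay_tau)
    dff_field = np.zeros((spec.n_frames, spec.height, spec.width))
    rows_axis = np.arange(spec.height)[:, None]
    cols_axis = np.arange(spec.width)[None, :]

    records: list[dict] = []
    for label, params, rate in (
        ("flash", spec.flash_params, spec.flash_rate),
        ("surge", spec.surge_params, spec.surge_rate),
    ):
        n_events = rng.poisson(rate)
        feats = sample_event_features(params, n_events, rng)
        for _, f in feats.iterrows():
            plateau, fwhm = _kernel_fwhm_parts(
                f.rise_tau_s, f.decay_tau_s, f.duration_s
            )
            span_before = _RISE_SPAN_TAUS * f.rise_tau_s
            span_after = plateau + 5.0 * f.decay_tau_s
            lo = span_before
            hi = max(lo + spec.dt, times[-1] - span_after)
            t_peak = float(rng.uniform(lo, hi))
            r0 = float(rng.uniform(0, spec.height))
            c0 = float(rng.uniform(0, spec.width))
            sigma_px = math.sqrt(f.area_um2 / (2 * math.pi * math.log(2))) / spec.pixel_size
            footprint = np.exp(
                -((rows_axis - r0) ** 2 + (cols_axis - c0) ** 2) / (2 * sigma_px**2)
            )
            profile = _event_time_profile(
                times, t_peak, f.rise_tau_s, f.decay_tau_s, plateau
            )
            dff_field += f.peak_dff * profile[:, None, None] * footprint[None]
            records.append(
                {
                    "label": label,
                    "t_peak_s": t_peak,
                    "row": r0,
                    "col": c0,
                    "peak_dff": f.peak_dff,
                    "area_um2": f.area_um2,
                    "duration_s": fwhm,
                    "rise_tau_s": f.rise_tau_s,
                    "decay_tau_s": f.decay_tau_s,
                }
            )
    frames = background[:, None, None] * (1.0 + dff_field)
    frames = frames + rng.normal(
        0.0, spec.shot_noise_scale * np.sqrt(np.clip(frames, 0, None))
    )
    truth = GroundTruth(
        events=pd.DataFrame(
            records,
            columns=[
                "label",
                "t_peak_s",
                "row",
                "col",
                "peak_dff",
                "area_um2",
                "duration_s",
                "rise_tau_s",
                "decay_tau_s",
            ],
        ),
        meta={"spec": spec},
    )
    stack = TimelapseStack(frames=frames, dt=spec.dt, pixel_size=spec.pixel_size)
    return stack, truth


# --------------------------------------------------------------------------- #
# recruitment trace pairs
# --------------------------------------------------------------------------- #


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_recruitment_pair(
    directed: bool,
    dmfi_true: float = 30.0,
    latency_true: float = 60.0,
    dt: float = 2.0,
    seed: int = 0,
    duration: float = 900.0,
    atp_peak_time: float = 300.0,
    baseline_mfi: float = 100.0,
    rise_duration: float = 60.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Paired ATP ΔF/F and microglia-reporter traces with known response.

    The ATP trace carries one transient peaking at ``atp_peak_time``.  When
    ``directed``, the reporter trace rises smoothly (exactly zero before the
    onset) by ``dmfi_true`` percent of baseline, starting ``latency_true``
    seconds after the ATP peak; otherwise it stays flat.  Gaussian noise of
    SD ``noise_sd`` is added to the reporter trace.
    """
    _require(dt > 0, "dt", "must be positive")
    _require(dmfi_true >= 0, "dmfi_true", "must be nonnegative")
    _require(latency_true >= 0, "latency_true", "must be nonnegative")
    _require(0 < atp_peak_time < duration, "atp_peak_time", "must lie inside the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    atp = _event_time_profile(t, atp_peak_time, rise_tau=5.0, decay_tau=15.0, plateau=0.0)
    mg = np.full(t.size, baseline_mfi)
    if directed:
        onset = atp_peak_time + latency_true
        mg = baseline_mfi * (1.0 + dmfi_true / 100.0 * _smoothstep((t - onset) / rise_duration))
    if noise_sd > 0:
        mg = mg + rng.normal(0.0, noise_sd, size=t.size)
    truth = GroundTruth(
        events=pd.DataFrame(
            {
                "atp_peak_time_s": [atp_peak_time],
                "directed": [directed],
                "dmfi_true_percent": [dmfi_true if directed else 0.0],
                "latency_true_s": [latency_true if directed else math.nan],
            }
        ),
        meta={"dt": dt, "baseline_mfi": baseline_mfi},
    )
    return atp, mg, truth


# --------------------------------------------------------------------------- #
# depth-drifting cell maps
# --------------------------------------------------------------------------- #


def simulate_cell_map(
    n_cells: int,
    thickness: float = 300.0,
    drift_to_top: float = 30.0,
    drift_noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Cell depths (µm from the top surface) before and after a noisy drift.

    Initial depths are uniform over the slab; final depths are the initial
    ones shifted toward the top by ``drift_to_top`` plus Gaussian noise,
    clipped to the slab.  Counts are conserved between timepoints.
    """
    _require(n_cells >= 1, "n_cells", "must be >= 1")
    _require(thickness > 0, "thickness", "must be positive")
    _require(0 <= drift_to_top < thickness, "drift_to_top", "must be in [0, thickness)")
    rng = np.random.default_rng(seed)
    t0 = rng.uniform(0.0, thickness, size=n_cells)
    noise = rng.normal(0.0, drift_noise_sd, size=n_cells) if drift_noise_sd > 0 else 0.0
    t1 = np.clip(t0 - drift_to_top + noise, 0.0, thickness)
    truth = GroundTruth(
        events=pd.DataFrame({"depth_t0_um": t0, "depth_t1_um": t1}),
        meta={
            "thickness_um": thickness,
            "drift_to_top_um": drift_to_top,
            "drift_noise_sd_um": drift_noise_sd,
        },
    )
    return t0, t1, truth


# --------------------------------------------------------------------------- #
# puncta scenes
# --------------------------------------------------------------------------- #


def _disk(shape: tuple[int, int], r0: float, c0: float, radius: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def simulate_puncta_scene(
    n_synapses: int,
    n_orphan_pre: int = 0,
    n_orphan_post: int = 0,
    microglia_geometry: Sequence[tuple[float, float, float]] = (),
    pixel_size: float = 50.0,  # nm / px, acquisition default
    shape: tuple[int, int] = (256, 256),
    punctum_radius_px: float = 3.0,
    seed: int = 0,
    background: float = 10.0,
    amplitude: float = 200.0,
    noise_sd: float = 4.0,
) -> tuple[PunctaScene, GroundTruth]:
    """Synthetic pre/post/microglia scene with known synapses and contacts.

    True synapses are touching pre/post punctum pairs (centres
    ``2 * radius - 1`` px apart so the disks stay 8-adjacent after one
    erosion); orphan puncta are isolated placements at least 6 px (boundary
    gap) from every opposite-channel punctum.  ``microglia_geometry`` lists
    microglial disks as ``(row, col, radius_px)``.  The ground truth records
    each synapse midpoint and whether it lies within the 200 nm contact
    distance of the microglia mask (minimum Euclidean distance transform
    over the pair footprint, strictly below 200 nm / pixel_size pixels).
    """
    _require(n_synapses >= 0, "n_synapses", "must be nonnegative")
    _require(n_orphan_pre >= 0 and n_orphan_post >= 0, "orphans", "must be nonnegative")
    _require(pixel_size > 0, "pixel_size", "must be positive")
    rng = np.random.default_rng(seed)
    H, W = shape
    margin = 4 * punctum_radius_px + 8
    if H <= 2 * margin or W <= 2 * margin:
        raise PlacementError(f"scene {shape} too small for margin {margin}")

    pair_offset = 2 * punctum_radius_px - 3  # touching with overlap, robust to pixelization
    min_center_gap = 4 * punctum_radius_px + 12  # keep objects resolvable

    placed: list[tuple[float, float]] = []

    def place_one() -> tuple[float, float]:
        for _ in range(2000):
            r = float(rng.uniform(margin, H - margin))
            c = float(rng.uniform(margin, W - margin))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_center_gap**2 for pr, pc in placed):
                placed.append((r, c))
                return r, c
        raise PlacementError("could not place an object without violating separation")

    pre_mask = np.zeros(shape, dtype=bool)
    post_mask = np.zeros(shape, dtype=bool)
    syn_records = []
    syn_footprints: list[np.ndarray] = []
    for i in range(n_synapses):
        r, c = place_one()
        theta = float(rng.uniform(0, 2 * math.pi))
        dr, dc = pair_offset * math.sin(theta), pair_offset * math.cos(theta)
        pre = _disk(shape, r, c, punctum_radius_px)
        post = _disk(shape, r + dr, c + dc, punctum_radius_px)
        pre_mask |= pre
        post_mask |= post
        syn_footprints.append(pre | post)
        syn_records.append(
            {
                "synapse_id": i,
                "row": r + dr / 2.0,
                "col": c + dc / 2.0,
            }
        )
    for _ in range(n_orphan_pre):
        r, c = place_one()
        pre_mask |= _disk(shape, r, c, punctum_radius_px)
    for _ in range(n_orphan_post):
        r, c = place_one()
        post_mask |= _disk(shape, r, c, punctum_radius_px)

    mg_mask = np.zeros(shape, dtype=bool)
    for r, c, radius in microglia_geometry:
        mg_mask |= _disk(shape, r, c, radius)

    contact_px = (200.0 / pixel_size)
    if mg_mask.any():
        dist = ndimage.distance_transform_edt(~mg_mask)
    else:
        dist = np.full(shape, np.inf)
    for rec, fp in zip(syn_records, syn_footprints):
        d = float(dist[fp].min()) if fp.any() else math.inf
        rec["min_dist_px"] = d
        rec["contacted"] = d < contact_px

    def render(mask: np.ndarray) -> np.ndarray:
        img = background + amplitude * mask.astype(float)
        return img + rng.normal(0.0, noise_sd, size=shape)

    scene = PunctaScene(
        pre_channel=render(pre_mask),
        post_channel=render(post_mask),
        microglia_channel=render(mg_mask),
        pixel_size=pixel_size,
    )
    truth = GroundTruth(
        events=pd.DataFrame(
            syn_records, columns=["synapse_id", "row", "col", "min_dist_px", "contacted"]
        ),
        meta={
            "n_orphan_pre": n_orphan_pre,
            "n_orphan_post": n_orphan_post,
            "pixel_size_nm": pixel_size,
            "microglia_mask_area_px": int(mg_mask.sum()),
        },
    )
    return scene, truth
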