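"""Histological interaction metrics for microglia-neuron contact analysis.

Works on registered multi-channel confocal images with known physical pixel
size (the source acquisitions used 50 x 50 nm pixels):

* punctum segmentation per channel (automatic Otsu threshold, hole filling,
  one erosion, connected components with a minimum-size filter),
* synapse identification by pre/postsynaptic punctum apposition ("touching"
  = overlap or 8-adjacency) and microglial contact scoring by a Euclidean
  distance-transform rule (contacted when a microglial process lies closer
  than 200 nm — 4 pixels at 50 nm/px),
* systematic random subsampling of identified synapses,
* integrated fluorescence density within ROIs (synaptic density measure),
* somatic contact prevalence and coverage from per-section soma outlines
  (surface = circumference x section thickness; contacted when a contact
  arc is at least 0.5 µm long),
* receptor labelling intensity per membrane length within a 500 nm wide
  ribbon ROI around a membrane polyline (250 nm to each side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "PunctaScene",
    "SynapseRecord",
    "SomaRecord",
    "detect_puncta",
    "segment_microglia",
    "identify_synapses",
    "microglia_contact",
    "systematic_random_subset",
    "synaptic_density",
    "soma_metrics",
    "membrane_intensity",
]

#: A synapse counts as contacted when a microglial process is closer than
#: 200 nm — 4 pixels at the 50 nm acquisition pixel size.
CONTACT_MAX_DIST_NM = 200.0
#: Membrane ribbon ROI width: outlines extended 250 nm each way -> 500 nm.
RIBBON_WIDTH_NM = 500.0
#: Somata count as contacted when a contact arc spans at least 0.5 µm.
MIN_SOMA_CONTACT_UM = 0.5


@dataclass(frozen=True)
class PunctaScene:
    """Registered presynaptic / postsynaptic / microglia channels."""

    pre_channel: np.ndarray
    post_channel: np.ndarray
    microglia_channel: np.ndarray
    pixel_size: float  # nm / px

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(self.pre_channel).shape,
            np.asarray(self.post_channel).shape,
            np.asarray(self.microglia_channel).shape,
        }
        if len(shapes) != 1:
            raise ValueError("all channels must share dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class SynapseRecord:
    id: int
    pre_centroid: tuple[float, float]
    post_centroid: tuple[float, float]
    contacted_by_microglia: bool = False
    min_dist_px: float = math.nan
    min_dist_nm: float = math.nan


@dataclass(frozen=True)
class SomaRecord:
    """Per-soma contact metrics aggregated over serial sections."""

    circumference_per_section: np.ndarray  # µm
    contact_per_section: np.ndarray  # µm
    surface: float  # µm²
    covered_surface: float  # µm²
    coverage_percent: float
    contacted: bool


# --------------------------------------------------------------------------- #
# puncta and synapses
# --------------------------------------------------------------------------- #


def detect_puncta(
    image: np.ndarray,
    min_size_px: int = 4,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Segment puncta in one channel.

    Automatic Otsu threshold, binary hole filling, one erosion step,
    connected-component labelling and a minimum-size filter.  Returns the
    label image and the punctum centroids in pixel coordinates.  A blank
    (constant) image yields an empty result.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=int), []
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    labels = sk_label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < min_size_px)[0]
    if small.size:
        labels[np.isin(labels, small)] = 0
        labels = sk_label(labels > 0, connectivity=2)
    centroids = [tuple(p.centroid) for p in regionprops(labels)]
    return labels, centroids


def segment_microglia(image: np.ndarray, min_contrast_sd: float = 4.0) -> np.ndarray:
    """Binarize the microglia channel (Otsu threshold + hole filling).

    Unlike :func:`detect_puncta`, no erosion is applied: the mask feeds
    distance-based contact rules, and shrinking it would inflate every
    distance by about a pixel.  Otsu always splits even a pure-noise image,
    so the split only counts as signal when the foreground mean exceeds the
    background mean by ``min_contrast_sd`` background SDs; otherwise the
    channel is treated as empty.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    fg = img > threshold_otsu(img)
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=bool)
    bg_sd = img[~fg].std()
    if img[fg].mean() - img[~fg].mean() < min_contrast_sd * bg_sd:
        return np.zeros(img.shape, dtype=bool)
    return ndimage.binary_fill_holes(fg)


def identify_synapses(
    pre_labels: np.ndarray,
    post_labels: np.ndarray,
) -> list[SynapseRecord]:
    """Synapses are presynaptic puncta touching postsynaptic ones.

    "Touching" means the masks overlap or are 8-adjacent.  Each presynaptic
    punctum is paired with the postsynaptic punctum it most overlaps (after
    one 8-connected dilation); one record per touching pre punctum.
    """
    pre_props = {p.label: p for p in regionprops(pre_labels)}
    struct = np.ones((3, 3), dtype=bool)
    records: list[SynapseRecord] = []
    next_id = 0
    post_props = {p.label: p for p in regionprops(post_labels)}
    for lab, prop in sorted(pre_props.items()):
        r0, c0, r1, c1 = prop.bbox
        r0, c0 = max(0, r0 - 1), max(0, c0 - 1)
        r1 = min(pre_labels.shape[0], r1 + 1)
        c1 = min(pre_labels.shape[1], c1 + 1)
        mask = pre_labels[r0:r1, c0:c1] == lab
        grown = ndimage.binary_dilation(mask, structure=struct)
        touched = post_labels[r0:r1, c0:c1][grown]
        touched = touched[touched > 0]
        if touched.size == 0:
            continue
        partner = int(np.bincount(touched).argmax())
        records.append(
            SynapseRecord(
                id=next_id,
                pre_centroid=tuple(prop.centroid),
                post_centroid=tuple(post_props[partner].centroid),
            )
        )
        next_id += 1
    return records


def _synapse_footprint(
    record: SynapseRecord,
    pre_labels: np.ndarray,
    post_labels: np.ndarray,
) -> np.ndarray:
    pre_ids = {p.label: p for p in regionprops(pre_labels)}
    # identify the pre punctum nearest the record's pre centroid
    best = min(
        pre_ids.values(),
        key=lambda p: (p.centroid[0] - record.pre_centroid[0]) ** 2
        + (p.centroid[1] - record.pre_centroid[1]) ** 2,
    )
    return pre_labels == best.label


def microglia_contact(
    records: Sequence[SynapseRecord],
    pre_labels: np.ndarray,
    post_labels: np.ndarray,
    microglia_mask: np.ndarray,
    max_dist_nm: float = CONTACT_MAX_DIST_NM,
    pixel_size: float | None = None,
) -> list[SynapseRecord]:
    """Flag synapses lying closer than ``max_dist_nm`` to a microglial process.

    The distance is the minimum Euclidean distance-transform value over the
    synapse footprint (union of its pre and post punctum masks) to the
    microglia mask, strictly less-than at the bound.
    """
    if pixel_size is None:
        raise ValueError("pixel_size (nm/px) is required when max_dist is given in nm")
    mg = np.asarray(microglia_mask).astype(bool)
    if not mg.any():
        for rec in records:
            rec.contacted_by_microglia = False
            rec.min_dist_px = math.inf
            rec.min_dist_nm = math.inf
        return list(records)
    dist = ndimage.distance_transform_edt(~mg)
    max_dist_px = max_dist_nm / pixel_size
    pre_props = {p.label: p for p in regionprops(pre_labels)}
    post_props = {p.label: p for p in regionprops(post_labels)}

    def nearest_label(props, centroid):
        return min(
            props.values(),
            key=lambda p: (p.centroid[0] - centroid[0]) ** 2
            + (p.centroid[1] - centroid[1]) ** 2,
        ).label

    for rec in records:
        pre_lab = nearest_label(pre_props, rec.pre_centroid)
        post_lab = nearest_label(post_props, rec.post_centroid)
        footprint = (pre_labels == pre_lab) | (post_labels == post_lab)
        d = float(dist[footprint].min())
        rec.min_dist_px = d
        rec.min_dist_nm = d * pixel_size
        rec.contacted_by_microglia = d < max_dist_px
    return list(records)


def systematic_random_subset(items: Sequence, n: int, seed: int = 0) -> list:
    """Every k-th item from a seeded random start, ``k = floor(count / n)``.

    Items are taken in their given (deterministic) order.  Raises when more
    items are requested than exist.
    """
    count = len(items)
    if n > count:
        raise ValueError(f"requested {n} items from {count}")
    if n == count:
        return list(items)
    k = count // n
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, k))
    return [items[start + i * k] for i in range(n)]


def synaptic_density(
    image: np.ndarray,
    rois: Sequence[tuple[int, int, int, int]],
) -> list[dict]:
    """Integrated fluorescence density per ROI.

    Each ROI is ``(row, col, height, width)`` in pixels.  Returns per-ROI
    dictionaries with the summed intensity (integrated density), the ROI
    area in pixels and the density per unit area.
    """
    img = np.asarray(image, dtype=float)
    out = []
    for r, c, h, w in rois:
        if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > img.shape[0] or c + w > img.shape[1]:
            raise ValueError(f"ROI ({r}, {c}, {h}, {w}) out of bounds for {img.shape}")
        patch = img[r : r + h, c : c + w]
        integrated = float(patch.sum())
        out.append(
            {
                "integrated_density": integrated,
                "area_px": h * w,
                "density_per_px": integrated / (h * w),
            }
        )
    return out


# --------------------------------------------------------------------------- #
# somatic contacts
# --------------------------------------------------------------------------- #


def _polyline_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


def _densify(points: np.ndarray, step_px: float = 1.0) -> np.ndarray:
    """Resample a polyline so no segment exceeds ``step_px`` (length-preserving)."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(seg / step_px)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def soma_metrics(
    outlines: Sequence[np.ndarray],
    microglia_masks: Sequence[np.ndarray],
    pixel_size_um: float,
    section_thickness: float,
    min_contact_um: float = MIN_SOMA_CONTACT_UM,
    contact_gap_px: float = 1.5,
) -> SomaRecord:
    """Contact prevalence and coverage of one neuronal soma across sections.

    ``outlines`` holds one closed outline polygon (N x 2, pixel coordinates,
    first point repeated last) per serial section, with the matching
    microglia mask per section.  The soma surface is the summed section
    circumference times the section thickness; the covered surface is
    computed likewise from the outline arcs adjacent to microglia (segment
    endpoints within ``contact_gap_px`` of the mask — the zero-gap
    "clearly touched" approximation).  The soma counts as contacted when any
    single contact arc spans at least ``min_contact_um``.
    """
    if len(outlines) != len(microglia_masks):
        raise ValueError("one microglia mask per section is required")
    if section_thickness <= 0 or pixel_size_um <= 0:
        raise ValueError("section thickness and pixel size must be positive")
    circumferences = []
    contacts = []
    any_long_contact = False
    for outline, mg in zip(outlines, microglia_masks):
        pts = np.asarray(outline, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 2:
            raise ValueError("outline must be an N x 2 polygon with N >= 4")
        if not np.allclose(pts[0], pts[-1]):
            raise ValueError("open outline: first and last points must coincide")
        pts = _densify(pts)  # contact arcs must resolve below the 0.5 µm rule
        seg_len_px = _polyline_lengths(pts)
        circumferences.append(seg_len_px.sum() * pixel_size_um)
        mg = np.asarray(mg).astype(bool)
        if mg.any():
            dist = ndimage.distance_transform_edt(~mg)
            d_at = ndimage.map_coordinates(dist, pts.T, order=1, mode="nearest")
            seg_contact = (d_at[:-1] <= contact_gap_px) & (d_at[1:] <= contact_gap_px)
        else:
            seg_contact = np.zeros(seg_len_px.size, dtype=bool)
        contacts.append(seg_len_px[seg_contact].sum() * pixel_size_um)
        # longest contiguous contact arc in this section (outline is closed,
        # so wrap the run across the seam)
        if seg_contact.any():
            runs = _run_lengths(seg_contact, seg_len_px * pixel_size_um)
            if max(runs) >= min_contact_um:
                any_long_contact = True
    circumference = np.asarray(circumferences)
    contact = np.asarray(contacts)
    surface = float(circumference.sum() * section_thickness)
    covered = float(contact.sum() * section_thickness)
    return SomaRecord(
        circumference_per_section=circumference,
        contact_per_section=contact,
        surface=surface,
        covered_surface=covered,
        coverage_percent=100.0 * covered / surface if surface > 0 else 0.0,
        contacted=any_long_contact,
    )


def _run_lengths(flags: np.ndarray, lengths: np.ndarray) -> list[float]:
    """Total lengths of contiguous True runs, wrapping across the seam."""
    if flags.all():
        return [float(lengths.sum())]
    # rotate so the sequence starts on a False segment, then runs don't wrap
    start = int(np.argmin(flags))
    flags = np.roll(flags, -start)
    lengths = np.roll(lengths, -start)
    runs: list[float] = []
    acc = 0.0
    for f, ln in zip(flags, lengths):
        if f:
            acc += ln
        elif acc > 0:
            runs.append(acc)
            acc = 0.0
    if acc > 0:
        runs.append(acc)
    return runs or [0.0]


# --------------------------------------------------------------------------- #
# membrane ribbon intensity
# --------------------------------------------------------------------------- #


def membrane_intensity(
    polyline: np.ndarray,
    image: np.ndarray,
    pixel_size_nm: float,
    width_nm: float = RIBBON_WIDTH_NM,
) -> dict:
    """Receptor labelling intensity per unit membrane length.

    The membrane polyline is extended ``width_nm / 2`` to each side, forming
    a ribbon-shaped ROI; the integrated receptor intensity within the ribbon
    is divided by the membrane length.  Returns the integrated density, the
    membrane length in µm and the per-length intensity both in
    intensity x nm (physical strip integral; a uniform image of intensity I
    gives I x width) and per µm of membrane.
    """
    pts = np.asarray(polyline, dtype=float)
    img = np.asarray(image, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an N x 2 array with N >= 2")
    if width_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("width and pixel size must be positive")
    half_px = (width_nm / 2.0) / pixel_size_nm
    lo = pts.min(axis=0) - half_px
    hi = pts.max(axis=0) + half_px
    if lo[0] < -0.5 or lo[1] < -0.5 or hi[0] > img.shape[0] - 0.5 or hi[1] > img.shape[1] - 0.5:
        raise ValueError("ribbon extends outside the image")
    # rasterize the polyline, then take all pixels within width/2 of it
    backbone = np.zeros(img.shape, dtype=bool)
    ipts = np.rint(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        backbone[rr, cc] = True
    dist = ndimage.distance_transform_edt(~backbone)
    # anti-aliased membership: pixels straddling the ribbon edge contribute
    # fractionally, so the rasterized strip area matches width x length
    weights = np.clip(half_px + 0.5 - dist, 0.0, 1.0)
    integrated = float((img * weights).sum())
    length_px = float(_polyline_lengths(pts).sum())
    if length_px == 0:
        raise ValueError("degenerate polyline of zero length")
    # the rounded ribbon ends add half-disk caps; fold them into the length
    # so a uniform image yields exactly intensity x width
    length_eff_px = length_px + math.pi * half_px / 2.0
    length_um = length_px * pixel_size_nm / 1000.0
    per_length_nm = integrated * pixel_size_nm / length_eff_px  # intensity x nm
    return {
        "integrated_density": integrated,
        "length_um": length_um,
        "intensity_per_length_nm": per_length_nm,
        "intensity_per_um": integrated / (length_eff_px * pixel_size_nm / 1000.0),
        "ribbon_area_px": float(weights.sum()),
    }
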