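"""Extract mosaic coupling measurements from two-channel microscope images.

The pipeline consumes a tracer channel, a probe-marker channel and an integer
label mask of cell regions (0 = background). It measures per-cell mean
intensities, identifies probe cells from the marker channel, finds each
probe's six nearest marker-positive cells — the directly coupled set in a
mosaic — measures the background, and assembles the per-probe measurements
that feed the neighbor-ratio strength estimator.

Segmentation is deliberately out of the critical path: the mask may come from
ground truth (synthetic scenes) or any external segmenter. A minimal
threshold-plus-watershed fallback (:func:`segment_cells`) is provided for
convenience only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import (
    InsufficientNeighborsError,
    InvalidParameterError,
    NoProbeFoundError,
    SceneError,
)
from .estimate import MosaicMeasurement

__all__ = [
    "LabeledScene",
    "CellRecord",
    "measure_cells",
    "identify_probes",
    "six_nearest_neighbors",
    "NeighborQuery",
    "estimate_background",
    "quantify_scene",
    "segment_cells",
]


@dataclass(frozen=True)
class LabeledScene:
    """Two-channel image plus integer label mask.

    Pixels are 0-based, row-major; ``pixel_size`` converts pixel indices to
    micrometers. Label 0 is background; label k > 0 is cell region k.
    """

    tracer_channel: np.ndarray
    probe_channel: np.ndarray
    label_mask: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.tracer_channel, dtype=float)
        p = np.asarray(self.probe_channel, dtype=float)
        m = np.asarray(self.label_mask)
        object.__setattr__(self, "tracer_channel", t)
        object.__setattr__(self, "probe_channel", p)
        object.__setattr__(self, "label_mask", m.astype(np.int32))
        if not (t.shape == p.shape == m.shape) or t.ndim != 2:
            raise SceneError("all scene images must be 2D and share one shape")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if m.min() < 0:
            raise SceneError("label mask must be non-negative")


@dataclass(frozen=True)
class CellRecord:
    """Per-cell measurement: centroid in micrometers (row, col), mean channel
    intensities, area in square micrometers, and a probe flag."""

    cell_id: int
    centroid: tuple[float, float]
    mean_tracer: float
    mean_probe: float
    area: float
    is_probe: bool = False


def measure_cells(scene: LabeledScene) -> list[CellRecord]:
    """One record per labeled region; mean intensities over the region's
    pixels, area centroid in micrometers."""
    if not np.any(scene.label_mask):
        warnings.warn("label mask is empty; returning no cells", stacklevel=2)
        return []
    px = scene.pixel_size
    stacked = np.stack([scene.tracer_channel, scene.probe_channel], axis=-1)
    records = []
    for rp in regionprops(scene.label_mask, intensity_image=stacked):
        mean_tracer, mean_probe = rp.intensity_mean
        records.append(CellRecord(
            cell_id=int(rp.label),
            centroid=(float(rp.centroid[0]) * px, float(rp.centroid[1]) * px),
            mean_tracer=float(mean_tracer),
            mean_probe=float(mean_probe),
            area=float(rp.area) * px * px,
        ))
    return records


def identify_probes(records: list[CellRecord],
                    threshold_rule: float | str = "otsu",
                    max_probe_fraction: float = 0.2) -> list[CellRecord]:
    """Flag probe cells by their probe-marker intensity.

    ``threshold_rule`` is either a numeric threshold or ``"otsu"`` (default):
    an Otsu split of the per-cell marker means, guarded by requiring the high
    class to contain fewer than ``max_probe_fraction`` of the cells (probes
    are sparse by experimental design).
    """
    if not records:
        raise NoProbeFoundError("no cell records")
    means = np.array([r.mean_probe for r in records])
    if isinstance(threshold_rule, str):
        if threshold_rule != "otsu":
            raise InvalidParameterError(f"unknown threshold rule {threshold_rule!r}")
        if np.allclose(means, means[0]):
            raise NoProbeFoundError(
                "all cells have the same marker intensity; cannot split"
            )
        thr = _otsu_split(means)
    else:
        thr = float(threshold_rule)
    is_probe = means > thr
    n_hi = int(is_probe.sum())
    if n_hi == 0 or n_hi == len(records):
        raise NoProbeFoundError(
            "marker threshold puts all cells in one class; no probes found"
        )
    if n_hi > 1 and n_hi >= max_probe_fraction * len(records):
        raise NoProbeFoundError(
            f"{n_hi}/{len(records)} cells classified as probes exceeds the "
            f"sparsity guard ({max_probe_fraction:.0%}); check the marker channel"
        )
    return [replace(r, is_probe=bool(f)) for r, f in zip(records, is_probe)]


def _otsu_split(values: np.ndarray) -> float:
    """Exact Otsu threshold on a sample of values (no histogram binning).

    Maximizes the between-class variance w0*w1*(mu0-mu1)^2 over all splits of
    the sorted sample; returns the midpoint between the two classes.
    skimage's histogram-based Otsu is unreliable here: with a few hundred
    per-cell means the low cluster can fall into a single bin, whose center
    then bisects the cluster instead of separating the classes.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # class 0 = v[:k], class 1 = v[k:]
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    score = k * (n - k) * (mu0 - mu1) ** 2
    best = int(np.argmax(score))
    return 0.5 * (v[best] + v[best + 1])


@dataclass(frozen=True)
class NeighborQuery:
    """Six nearest non-probe neighbors of a probe, with a flag set when
    another probe had to be skipped over."""

    neighbor_ids: tuple[int, ...]
    probe_excluded: bool


def six_nearest_neighbors(records: list[CellRecord], probe_id: int,
                          k: int = 6) -> NeighborQuery:
    """The ``k`` non-probe cells nearest (Euclidean centroid distance) to the
    given probe; ties broken by (distance, cell_id). Probes encountered among
    the nearest cells are excluded, replaced by the next-nearest, and flagged.
    """
    by_id = {r.cell_id: r for r in records}
    if probe_id not in by_id:
        raise InvalidParameterError(f"no cell with id {probe_id}")
    probe = by_id[probe_id]
    c0 = np.array(probe.centroid)
    others = [r for r in records if r.cell_id != probe_id]
    others.sort(key=lambda r: (float(np.hypot(*(np.array(r.centroid) - c0))),
                               r.cell_id))
    chosen: list[int] = []
    probe_excluded = False
    for r in others:
        if len(chosen) == k:
            break
        if r.is_probe:
            probe_excluded = True
            continue
        chosen.append(r.cell_id)
    if len(chosen) < k:
        raise InsufficientNeighborsError(
            f"probe {probe_id}: only {len(chosen)} non-probe neighbors available"
        )
    return NeighborQuery(neighbor_ids=tuple(chosen),
                         probe_excluded=probe_excluded)


def estimate_background(scene: LabeledScene, method: str = "background_pixels",
                        margin: int = 2) -> float:
    """Background tracer intensity.

    ``background_pixels`` (default): median tracer intensity over pixels that
    are background in the label mask and at least ``margin`` pixels away from
    every cell region (the cell mask is dilated before sampling, so bleed
    halos around cells do not enter). ``far_cells``: mean tracer intensity of
    non-probe cells far (>= 4 typical cell spacings) from every probe —
    requires probes to be identified first via :func:`quantify_scene`.
    """
    if method == "background_pixels":
        cells = scene.label_mask > 0
        if margin > 0:
            cells = ndimage.binary_dilation(cells, iterations=margin)
        bg = ~cells
        if not np.any(bg):
            raise SceneError("no background pixels outside dilated cell regions")
        return float(np.median(scene.tracer_channel[bg]))
    if method == "far_cells":
        records = identify_probes(measure_cells(scene))
        probes = [r for r in records if r.is_probe]
        non = [r for r in records if not r.is_probe]
        if not probes or not non:
            raise SceneError("far_cells background needs probes and other cells")
        cents = np.array([r.centroid for r in non])
        pcents = np.array([r.centroid for r in probes])
        # typical spacing: median nearest-neighbor distance among all cells
        allc = np.array([r.centroid for r in records])
        d2 = np.linalg.norm(allc[:, None] - allc[None, :], axis=-1)
        np.fill_diagonal(d2, np.inf)
        spacing = float(np.median(d2.min(axis=1)))
        dist_to_probe = np.linalg.norm(
            cents[:, None] - pcents[None, :], axis=-1).min(axis=1)
        far = dist_to_probe >= 4 * spacing
        if not np.any(far):
            raise SceneError("no cells far enough from probes for far_cells method")
        return float(np.mean([r.mean_tracer for r, f in zip(non, far) if f]))
    raise InvalidParameterError(f"unknown background method {method!r}")


def quantify_scene(scene: LabeledScene, threshold_rule: float | str = "otsu",
                   bg_method: str = "background_pixels") -> list[MosaicMeasurement]:
    """Full measurement pipeline: one MosaicMeasurement per probe cell.

    Probes whose six-neighbor sets overlap another probe's are flagged
    ``overlapping_neighbors`` (group statistics should exclude them); a
    ``probe_excluded`` flag marks probes for which another probe sat among
    the six nearest cells.
    """
    records = identify_probes(measure_cells(scene), threshold_rule)
    i_bg = estimate_background(scene, method=bg_method)
    probes = [r for r in records if r.is_probe]
    queries = {p.cell_id: six_nearest_neighbors(records, p.cell_id)
               for p in probes}
    by_id = {r.cell_id: r for r in records}
    measurements = []
    for p in probes:
        q = queries[p.cell_id]
        flags = []
        if q.probe_excluded:
            flags.append("probe_excluded")
        mine = set(q.neighbor_ids)
        for other_id, oq in queries.items():
            if other_id != p.cell_id and mine & set(oq.neighbor_ids):
                flags.append("overlapping_neighbors")
                break
        measurements.append(MosaicMeasurement(
            I0=p.mean_tracer,
            I1=tuple(by_id[i].mean_tracer for i in q.neighbor_ids),
            I_bg=i_bg,
            probe_id=str(p.cell_id),
            flags=tuple(flags),
        ))
    return measurements


def segment_cells(image: np.ndarray, min_distance_px: int = 5) -> np.ndarray:
    """Convenience fallback segmenter: Otsu threshold plus distance-transform
    watershed. Not part of the measurement contract — use ground-truth or
    externally produced masks for quantitative work."""
    image = np.asarray(image, dtype=float)
    mask = image > threshold_otsu(image)
    dist = ndimage.distance_transform_edt(mask)
    smooth = ndimage.gaussian_filter(dist, sigma=max(1, min_distance_px // 2))
    maxima = (smooth == ndimage.maximum_filter(smooth, size=2 * min_distance_px + 1))
    maxima &= mask
    markers, _ = ndimage.label(maxima)
    return watershed(-dist, markers, mask=mask).astype(np.int32)
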