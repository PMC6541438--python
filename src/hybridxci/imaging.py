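"""Nuclear immunofluorescence intensity quantification.

DAPI-channel nuclei are segmented by thresholding (Otsu by default)
into regions of interest, per-nucleus mean intensities are measured in
every channel, a user-supplied non-nuclear background region's mean is
subtracted, and nucleus values are averaged into a per-embryo mean.
Embryos are binned into approximate developmental stages by cell
count.  A synthetic multi-channel embryo image generator provides
ground-truth masks for testing the whole chain.

This is a 2D re-implementation of a voxel-based commercial procedure;
touching nuclei merge into one ROI, a known limitation of plain
threshold segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

CHANNEL_DAPI = 0

#: stage bins by cell count (inclusive ranges)
STAGE_BINS = (
    ((2, 3), "~2-cell"),
    ((4, 5), "~4-cell"),
    ((6, 10), "~8-cell"),
    ((14, 19), "~16-cell"),
)


@dataclass(frozen=True)
class NucleusMeasurement:
    """Background-corrected mean channel intensities of one nucleus."""

    embryo_id: str
    nucleus_id: int
    channel_means: tuple
    background_corrected: bool = True


def stage_embryo(n_cells: int) -> str:
    """Developmental stage bin for a cell count.

    2–3 cells → ~2-cell, 4–5 → ~4-cell, 6–10 → ~8-cell, 14–19 →
    ~16-cell; counts outside every bin (1, 11–13, >=20) are
    ``unstaged`` rather than forced into a nearest bin.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for (lo, hi), label in STAGE_BINS:
        if lo <= n_cells <= hi:
            return label
    return "unstaged"


def make_synthetic_embryo_image(n_nuclei: int, nucleus_intensity, background_level: float,
                                noise_sd: float, seed: int, shape=(256, 256),
                                radius: int = 12, n_channels: int | None = None):
    """Generate a multi-channel embryo image with truth masks.

    Nuclei are non-overlapping disks of the given radius; channel 0 is
    the DAPI stain.  ``nucleus_intensity`` is a sequence of per-channel
    intra-nuclear intensities (added on top of ``background_level``).
    Gaussian noise of ``noise_sd`` is added everywhere.  Returns
    ``(image[H, W, C], label_mask, background_region)`` where the
    background region is an ``(y0, y1, x0, x1)`` rectangle guaranteed
    free of nuclei.

    Raises if the requested nuclei cannot be placed in the frame.
    """
    rng = np.random.default_rng(seed)
    intens = np.asarray(nucleus_intensity, dtype=float)
    if n_channels is None:
        n_channels = intens.size
    if intens.size != n_channels:
        raise ValueError("one nucleus intensity per channel required")
    if (intens <= 0).any():
        raise ValueError("nucleus intensities must be positive")
    h, w = shape
    margin = radius + 2
    bg_size = 32
    # reserve the top-left corner for the background rectangle
    bg_region = (0, bg_size, 0, bg_size)

    centers = []
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 2000 * n_nuclei:
            raise ValueError(
                f"cannot place {n_nuclei} non-overlapping nuclei of radius {radius} "
                f"in a {h}x{w} frame"
            )
        cy = rng.integers(margin, h - margin)
        cx = rng.integers(margin, w - margin)
        if cy < bg_size + radius and cx < bg_size + radius:
            continue  # keep the background region clean
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * radius + 2) ** 2 for y, x in centers):
            centers.append((int(cy), int(cx)))

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        labels[disk] = i

    image = np.full((h, w, n_channels), float(background_level))
    for c in range(n_channels):
        image[..., c][labels > 0] += intens[c]
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    return image, labels, bg_region


def segment_nuclei(dapi_channel: np.ndarray, min_size: int = 16,
                   threshold: float | None = None) -> np.ndarray:
    """Segment nuclei from a DAPI image into a label image.

    Otsu threshold (or an explicit one) → binary mask → small-object
    removal → connected components.  A flat image yields zero ROIs.
    Touching nuclei form a single ROI — the method cannot distinguish
    overlapping nuclei.
    """
    img = np.asarray(dapi_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = filters.threshold_otsu(img) if threshold is None else threshold
    binary = img > thr
    binary = morphology.remove_small_objects(binary, max_size=min_size - 1)
    return measure.label(binary).astype(np.int32)


def measure_embryo(image: np.ndarray, labels: np.ndarray, background_region,
                   embryo_id: str = "embryo"):
    """Per-nucleus background-corrected means and the per-embryo average.

    ``background_region`` is an ``(y0, y1, x0, x1)`` rectangle that must
    not overlap any nucleus; its per-channel mean is subtracted from
    every nucleus's raw mean.  The embryo mean is the unweighted mean
    over nuclei.  Returns ``(measurements, embryo_means)``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    y0, y1, x0, x1 = background_region
    if (labels[y0:y1, x0:x1] > 0).any():
        raise ValueError("background region overlaps a nucleus ROI")
    bg = img[y0:y1, x0:x1].reshape(-1, img.shape[-1]).mean(axis=0)
    measurements = []
    for nid in np.unique(labels):
        if nid == 0:
            continue
        pix = img[labels == nid]
        corrected = pix.mean(axis=0) - bg
        measurements.append(
            NucleusMeasurement(
                embryo_id=embryo_id,
                nucleus_id=int(nid),
                channel_means=tuple(float(v) for v in corrected),
            )
        )
    if measurements:
        embryo_means = tuple(
            float(np.mean([m.channel_means[c] for m in measurements]))
            for c in range(img.shape[-1])
        )
    else:
        embryo_means = tuple(float("nan") for _ in range(img.shape[-1]))
    return measurements, embryo_means
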