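"""Image-analysis chain: registration, segmentation, measurement, tracking,
and dye-gradient quantification.

Mirrors the classical workflow for this kind of assay: frames are aligned
by integer-pixel phase correlation, cells are segmented by Gaussian
smoothing + Otsu thresholding (with an optional watershed split of touching
objects), measured with moment-based descriptors (area = pixel count,
eccentricity of the equivalent ellipse), linked across frames by optimal
(Hungarian) assignment on centroid distance, and the dye channel is
collapsed to a normalized percent profile along the gradient axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.signal import medfilt
from skimage import measure as skmeasure
from skimage import morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import DegenerateGradientError, RegistrationError

MEASUREMENT_COLUMNS = ["label", "x_px", "y_px", "area_px", "eccentricity"]


def register_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[tuple[int, int], np.ndarray]:
    """Integer-pixel translation of ``moving`` relative to ``reference``.

    Returns ``((dx, dy), registered)``: (dx, dy) is the detected
    displacement (columns, rows) of the moving frame's content, found by
    phase correlation, and ``registered`` is the moving image shifted back
    by that displacement so it aligns with the reference.  Rotation and
    scaling are not modeled.
    """
    if reference.shape != moving.shape:
        raise RegistrationError("images must share a shape")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise RegistrationError("cannot register a flat (zero-variance) image")
    shift, _, _ = phase_cross_correlation(
        reference.astype(float), moving.astype(float), upsample_factor=1, normalization=None
    )
    # phase_cross_correlation returns the shift to apply to `moving`;
    # the displacement of its content is the negation.
    corr_dy, corr_dx = int(round(shift[0])), int(round(shift[1]))
    registered = ndimage.shift(
        moving.astype(float), (corr_dy, corr_dx), order=0, mode="constant", cval=float(np.median(moving))
    )
    return (-corr_dx, -corr_dy), registered


def segment(
    image: np.ndarray,
    *,
    smoothing_sigma: float = 1.0,
    min_area_px: int = 30,
    split_touching: bool = True,
    min_distance_px: int = 7,
) -> np.ndarray:
    """Label map from a single-channel cell image.

    Gaussian smooth → Otsu global threshold → hole fill → drop objects
    below ``min_area_px`` → optional watershed split on the distance
    transform.  A blank image yields an empty (all-zero) label map rather
    than an error.  Labels are consecutive positive integers.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True) if smoothing_sigma > 0 else img
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(binary)
    binary = morphology.remove_small_objects(binary, max_size=min_area_px - 1)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    if split_touching:
        distance = ndimage.distance_transform_edt(binary)
        peaks = peak_local_max(
            distance, min_distance=min_distance_px, labels=binary, exclude_border=False
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers, _ = ndimage.label(markers > 0)
        labels = segmentation.watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary)

    labels = morphology.remove_small_objects(labels, max_size=min_area_px - 1)
    return segmentation.relabel_sequential(labels)[0].astype(np.int32)


def measure(labelmap: np.ndarray) -> pd.DataFrame:
    """Per-object area (px count), centroid (px) and moment eccentricity.

    Eccentricity is that of the ellipse with the same second central
    moments as the pixel set: sqrt(1 − λ_minor/λ_major) with λ the
    covariance eigenvalues — 0 for a circle, < 1 for any finite object.
    """
    props = skmeasure.regionprops(labelmap)
    rows = [
        {
            "label": p.label,
            "x_px": p.centroid[1],
            "y_px": p.centroid[0],
            "area_px": int(p.area),
            "eccentricity": p.eccentricity,
        }
        for p in props
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def track(frames: list[pd.DataFrame], max_displacement_px: float = 25.0) -> pd.DataFrame:
    """Link per-frame measurements into tracks by Hungarian assignment.

    Cost is centroid Euclidean distance; links longer than
    ``max_displacement_px`` are forbidden.  Unmatched previous objects
    close their track; unmatched new objects open tracks; no gap closing.
    A track is ``complete`` when it spans every frame, else ``truncated``.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame of measurements")
    n_frames = len(frames)
    next_id = 0
    records: list[dict] = []
    active: dict[int, tuple[float, float]] = {}

    big = 1e9
    for fi, df in enumerate(frames):
        pts = df[["x_px", "y_px"]].to_numpy(float) if len(df) else np.empty((0, 2))
        if fi == 0 or not active:
            assigned = {}
        else:
            ids = list(active.keys())
            prev = np.array([active[i] for i in ids])
            if len(pts):
                d = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
                cost = np.where(d <= max_displacement_px, d, big)
                ri, ci = linear_sum_assignment(cost)
                assigned = {
                    int(c): ids[int(r)]
                    for r, c in zip(ri, ci)
                    if cost[r, c] < big
                }
            else:
                assigned = {}
        new_active: dict[int, tuple[float, float]] = {}
        for j in range(len(pts)):
            if j in assigned:
                tid = assigned[j]
            else:
                tid = next_id
                next_id += 1
            new_active[tid] = (pts[j, 0], pts[j, 1])
            row = df.iloc[j]
            records.append(
                {
                    "track_id": tid,
                    "frame": fi,
                    "label": int(row["label"]),
                    "x_px": float(row["x_px"]),
                    "y_px": float(row["y_px"]),
                    "area_px": int(row["area_px"]),
                    "eccentricity": float(row["eccentricity"]),
                }
            )
        active = new_active

    out = pd.DataFrame(
        records,
        columns=["track_id", "frame", "label", "x_px", "y_px", "area_px", "eccentricity"],
    )
    if len(out):
        lengths = out.groupby("track_id")["frame"].agg(["min", "max", "count"])
        complete = lengths.index[
            (lengths["min"] == 0) & (lengths["max"] == n_frames - 1) & (lengths["count"] == n_frames)
        ]
        out["status"] = np.where(out["track_id"].isin(complete), "complete", "truncated")
    else:
        out["status"] = pd.Series(dtype=str)
    return out


@dataclass
class GradientProfile:
    """Normalized dye-intensity profile along the gradient axis."""

    positions_um: np.ndarray
    intensity_pct: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.positions_um)
        self.positions_um = np.asarray(self.positions_um, float)[order]
        self.intensity_pct = np.asarray(self.intensity_pct, float)[order]


def quantify_gradient(
    red_image: np.ndarray,
    mask_px: np.ndarray,
    pixel_size_um: float,
    *,
    origin_offset_px: float = 0.0,
    ref_fraction: float = 0.05,
    median_size: int = 5,
    noise_floor: float = 1.0,
    edge_trim_px: int = 2,
) -> GradientProfile:
    """Collapse the dye channel to a percent profile along the gradient axis.

    Per-column masked mean intensity, median-filtered, then mapped to
    percent via (I − I_sink)/(I_source − I_sink) × 100 using the mean of
    the ``ref_fraction`` of columns nearest each face as the 100% / 0%
    references.  ``edge_trim_px`` columns at each face are discarded first
    (PSF bleed across the chamber wall depresses them).  Values are
    clipped to [−10, 110]% (noise allowance).
    """
    img = np.asarray(red_image, float)
    if img.shape != mask_px.shape:
        raise ValueError("mask and image shapes differ")
    counts = mask_px.sum(axis=0)
    cols = np.flatnonzero(counts > 0)
    if edge_trim_px > 0 and cols.size > 2 * edge_trim_px + 2:
        cols = cols[edge_trim_px:-edge_trim_px]
    if cols.size < 3:
        raise DegenerateGradientError("footprint mask covers too few columns")
    sums = np.where(mask_px, img, 0.0).sum(axis=0)
    profile = sums[cols] / counts[cols]
    if median_size > 1:
        k = median_size if median_size % 2 == 1 else median_size + 1
        k = min(k, cols.size if cols.size % 2 == 1 else cols.size - 1)
        if k >= 3:
            profile = medfilt(profile, kernel_size=k)
    n_ref = max(1, int(round(ref_fraction * cols.size)))
    i_source = float(profile[:n_ref].mean())
    i_sink = float(profile[-n_ref:].mean())
    if abs(i_source - i_sink) < noise_floor:
        raise DegenerateGradientError(
            f"source/sink intensity difference {abs(i_source - i_sink):.3g} "
            f"below the noise floor {noise_floor:g}"
        )
    pct = np.clip((profile - i_sink) / (i_source - i_sink) * 100.0, -10.0, 110.0)
    positions = (cols - origin_offset_px + 0.5) * pixel_size_um
    return GradientProfile(positions_um=positions, intensity_pct=pct)
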