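"""Ellipse-based eye tracking on binarized camera frames.

The tracker binarizes each frame, requires a single connected foreground
component, and fits an ellipse from the second-order moments (covariance)
of the component's pixel coordinates.  For a filled ellipse the pixel
covariance is ``diag(s1^2, s2^2) / 4`` in the principal frame, so the
semi-axes are twice the square roots of the covariance eigenvalues.  The
reported angle is measured between the major axis and the supplied body
axis, positive counter-clockwise in image coordinates with the origin at
the top-left (i.e. with the row axis pointing down, so "up" in the image
is the positive second coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import EyeTrace

__all__ = ["EllipseFit", "ComponentError", "GapError",
           "fit_eye_ellipse", "track_frames"]

MIN_COMPONENT_PX = 50


class ComponentError(ValueError):
    """Binarized image does not contain exactly one usable component."""


class GapError(ValueError):
    """Too many consecutive frames failed to track."""


@dataclass
class EllipseFit:
    center: tuple  # (col, row), px
    major_len: float  # px
    minor_len: float  # px
    angle: float  # deg in [-90, 90) relative to the body axis
    ill_defined: bool  # axis ratio > 0.95: angle unreliable


def fit_eye_ellipse(image: np.ndarray, threshold: float = 0.5,
                    body_axis: float = 0.0) -> EllipseFit:
    """Moment-based ellipse fit of the single binarized eye component.

    Raises :class:`ComponentError` unless exactly one connected component
    of at least 50 px is present.
    """
    mask = np.asarray(image) > threshold
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    big = [i + 1 for i, s in enumerate(sizes) if s >= MIN_COMPONENT_PX]
    if len(big) != 1:
        raise ComponentError(
            f"expected exactly 1 component >= {MIN_COMPONENT_PX} px, found "
            f"{len(big)} (of {n} total components)")
    rows, cols = np.nonzero(labels == big[0])
    # Math coordinates: u1 = column, u2 = -row (up is positive).
    u = np.stack([cols.astype(float), -rows.astype(float)])
    center = (float(cols.mean()), float(rows.mean()))
    cov = np.cov(u)
    lam, vec = np.linalg.eigh(cov)
    semi = 2.0 * np.sqrt(np.maximum(lam, 0.0))
    major, minor = semi[1], semi[0]
    mvec = vec[:, 1]
    raw_angle = np.degrees(np.arctan2(mvec[1], mvec[0]))
    angle = (raw_angle - body_axis + 90.0) % 180.0 - 90.0
    return EllipseFit(center=center, major_len=2 * major, minor_len=2 * minor,
                      angle=float(angle),
                      ill_defined=bool(minor / major > 0.95))


def track_frames(frames, body_axis: float = 0.0, *,
                 sample_rate: float = 20.0, plane: str = "vertical",
                 eye: str = "left", threshold: float = 0.5,
                 max_gap: int = 3):
    """Track a frame sequence into an eye trace plus axis-length series.

    Frames where the fit fails are marked missing and linearly
    interpolated, up to ``max_gap`` consecutive failures; longer gaps
    raise :class:`GapError`.  Returns ``(EyeTrace, major_len, minor_len)``
    with the axis-length series retained for minor-axis verification.
    """
    angles, majors, minors = [], [], []
    for f in frames:
        try:
            fit = fit_eye_ellipse(f, threshold=threshold, body_axis=body_axis)
            angles.append(fit.angle)
            majors.append(fit.major_len)
            minors.append(fit.minor_len)
        except ComponentError:
            angles.append(np.nan)
            majors.append(np.nan)
            minors.append(np.nan)
    angles = np.asarray(angles)
    majors = np.asarray(majors, dtype=float)
    minors = np.asarray(minors, dtype=float)
    missing = np.isnan(angles)
    if missing.all():
        raise GapError("no frame could be tracked")
    if missing.any():
        run = 0
        for m in missing:
            run = run + 1 if m else 0
            if run > max_gap:
                raise GapError(
                    f"more than {max_gap} consecutive untrackable frames")
        idx = np.arange(angles.size)
        for arr in (angles, majors, minors):
            good = ~np.isnan(arr)
            arr[~good] = np.interp(idx[~good], idx[good], arr[good])
    trace = EyeTrace(positions=angles, sample_rate=sample_rate,
                     plane=plane, eye=eye)
    return trace, majors, minors
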