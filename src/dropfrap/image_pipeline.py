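"""From raw midplane movies to normalized radial profiles and boundary traces.

The measurement chain for one bleached droplet:

1. azimuthally average every frame around the droplet center;
2. subtract the camera background and divide by the background-subtracted
   prebleach profile (this also removes static radial gain artefacts such as
   the brighter droplet center seen in confocal data);
3. locate the droplet boundary R as the inflection point of the prebleach
   profile;
4. extract the recovery time course a fixed margin inside R — the dynamic
   boundary condition for the inside-diffusion fit — optionally sorted
   ascending to suppress small fluctuations in an otherwise monotone
   recovery;
5. drop the first frames (fast uniform recovery of unknown origin) and mask
   the bins adjacent to the boundary (optically broadened interface) before
   any fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pde_sphere import BoundaryTrace

__all__ = [
    "FrapMovie",
    "ProfileStack",
    "azimuthal_average",
    "normalize_stack",
    "detect_boundary",
    "extract_boundary_trace",
    "apply_bleach_corrections",
]


@dataclass
class FrapMovie:
    """A midplane time-lapse of one droplet, in raw camera counts.

    ``center`` is in pixel coordinates (col, row), sub-pixel allowed; if
    None it is estimated from the background-subtracted intensity centroid
    of the prebleach frame.
    """

    frames: np.ndarray  # (n_frames, H, W)
    times: np.ndarray  # s
    pixel_size: float  # um / px
    background: float  # camera counts
    prebleach_index: int = 0
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.times.size != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.background < 0:
            raise ValueError("camera background must be non-negative")
        if not 0 <= self.prebleach_index < self.frames.shape[0]:
            raise ValueError("prebleach index outside the movie")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        img = self.frames[self.prebleach_index].astype(float) - self.background
        img = np.clip(img, 0, None)
        total = img.sum()
        if total <= 0:
            raise ValueError("cannot auto-center: prebleach frame is empty")
        rows, cols = np.indices(img.shape)
        return (float((cols * img).sum() / total), float((rows * img).sum() / total))


@dataclass
class ProfileStack:
    """Azimuthally averaged, prebleach-normalized radial profiles.

    ``intensities[k, j]`` is the normalized intensity at ``times[k]`` and
    radial bin center ``radii[j]`` (um).  ``mask`` marks the bins admitted
    to fitting; ``R`` is the detected droplet boundary once known.
    """

    radii: np.ndarray
    times: np.ndarray
    intensities: np.ndarray
    bin_counts: np.ndarray
    mask: np.ndarray | None = None
    R: float | None = None
    prebleach: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.times.size, self.radii.size):
            raise ValueError("intensities must be (n_times, n_radii)")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.mask is None:
            self.mask = np.ones(self.radii.size, dtype=bool)

    @property
    def bin_width(self) -> float:
        return float(np.median(np.diff(self.radii)))

    def to_frame(self) -> pd.DataFrame:
        t = np.repeat(self.times, self.radii.size)
        r = np.tile(self.radii, self.times.size)
        counts = np.tile(self.bin_counts, self.times.size)
        return pd.DataFrame(
            {"time": t, "r": r, "intensity": self.intensities.ravel(), "bin_count": counts}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProfileStack":
        df = pd.read_csv(path)
        times = np.unique(df["time"].to_numpy())
        radii = np.unique(df["r"].to_numpy())
        vals = (
            df.pivot_table(index="time", columns="r", values="intensity")
            .to_numpy()
        )
        counts = (
            df.sort_values("r").groupby("r")["bin_count"].first().to_numpy()
        )
        return cls(radii, times, vals, counts)


def azimuthal_average(
    frame: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    bin_width: float = 1.0,
    effective_radii: bool = False,
):
    """Mean intensity per radial annulus around ``center``.

    Pixels are assigned to half-open bins ``[k w, (k+1) w)`` (``w`` in
    pixels) by the distance of their center to ``center``; pixel centers sit
    at integer coordinates.  Returns bin radii (um), mean intensity and
    pixel count per bin; empty bins get NaN intensity and count 0.  Radii
    are the nominal bin centers, or — with ``effective_radii=True`` — the
    mean actual pixel distance per bin, which matters when a bin holds only
    a handful of pixels (very coarse grids).
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = center
    h, w = frame.shape
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("droplet center outside the frame")
    rows, cols = np.indices(frame.shape)
    dist = np.hypot(cols - cx, rows - cy)
    idx = np.floor(dist / bin_width).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    sums = np.bincount(idx.ravel(), weights=frame.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if effective_radii:
        rsums = np.bincount(idx.ravel(), weights=dist.ravel(), minlength=n_bins)
        radii = np.where(
            counts > 0,
            rsums / np.maximum(counts, 1),
            np.arange(n_bins) + 0.5,
        ) * pixel_size
    else:
        radii = (np.arange(n_bins) + 0.5) * bin_width * pixel_size
    return radii, means, counts


def normalize_stack(movie: FrapMovie, bin_width: float = 1.0) -> ProfileStack:
    """Background-subtract and prebleach-normalize all frames of a movie.

    Each frame's azimuthal average (minus camera background) is divided,
    radius by radius, by the background-subtracted prebleach profile, which
    both normalizes the recovery to the prebleach level and cancels static
    radial gain artefacts.  The prebleach frame itself maps to all ones.
    Only radii where the prebleach signal is clearly above background are
    retained.
    """
    center = movie.resolved_center()
    radii, pre, counts = azimuthal_average(
        movie.frames[movie.prebleach_index], center, movie.pixel_size, bin_width
    )
    pre = pre - movie.background
    good = counts > 0
    if np.any(pre[good] <= 0):
        # keep the contiguous leading run of usable radii
        bad = np.nonzero(good & ~(np.nan_to_num(pre, nan=-1) > 0))[0]
        cut = bad.min()
        if cut < 3:
            raise ValueError("prebleach intensity at or below background")
        good[cut:] = False
    keep = np.nonzero(good)[0]
    profiles = np.empty((movie.frames.shape[0], keep.size))
    for k in range(movie.frames.shape[0]):
        _, prof, _ = azimuthal_average(movie.frames[k], center, movie.pixel_size, bin_width)
        profiles[k] = (prof[keep] - movie.background) / pre[keep]
    return ProfileStack(
        radii=radii[keep],
        times=movie.times.copy(),
        intensities=profiles,
        bin_counts=counts[keep],
        prebleach=pre[keep],  # raw (background-subtracted), for boundary detection
        meta={
            "center": center,
            "pixel_size": movie.pixel_size,
            "background": movie.background,
            "prebleach_index": movie.prebleach_index,
        },
    )


def detect_boundary(
    radii: np.ndarray,
    profile: np.ndarray,
    smooth_window: int = 5,
) -> float:
    """Droplet radius from the inflection point of a prebleach profile.

    The profile is smoothed with a centered moving average, the radius of
    steepest descent is taken as the minimum of the first derivative, and a
    local quadratic fit to the derivative refines it to sub-bin precision.
    Raises if the profile has no interior descent extremum (e.g. a ramp).
    """
    radii = np.asarray(radii, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if radii.size < max(smooth_window + 2, 5):
        raise ValueError("profile too short for boundary detection")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(profile, kernel, mode="same")
        # edges of a same-mode convolution are biased; ignore them below
        edge = smooth_window // 2 + 1
    else:
        sm = profile
        edge = 1
    d = np.gradient(sm, radii)
    interior = slice(edge, radii.size - edge)
    i = int(np.argmin(d[interior])) + edge
    if i <= edge or i >= radii.size - edge - 1:
        raise ValueError("no interior inflection point found")
    span = d.max() - d.min()
    if not (d[i] < d[edge] - 1e-12 and d[i] < d[-edge - 1] - 1e-12 and span > 0):
        raise ValueError("profile has no pronounced descent extremum")
    # quadratic refinement on the three points around the minimum
    y0, y1, y2 = d[i - 1], d[i], d[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    shift = float(np.clip(shift, -1, 1))
    return float(radii[i] + shift * (radii[min(i + 1, radii.size - 1)] - radii[i]))


def extract_boundary_trace(
    stack: ProfileStack,
    R: float,
    margin: float = 1.4,
    sort: bool = False,
    mode: str = "sort",
) -> BoundaryTrace:
    """Recovery time course at the bin nearest ``r = R - margin``.

    With ``sort=True`` the values are reordered ascending while the frame
    times are kept — the literal monotone cleanup for a recovering boundary
    (``mode="sort"``); ``mode="running_max"`` instead applies a monotone
    envelope (cumulative maximum), preserving the time of each first
    attainment.  Either way the multiset of values is unchanged only for
    ``"sort"``.
    """
    if margin >= R:
        raise ValueError("extraction margin must be smaller than the radius")
    r_x = R - margin
    if r_x < stack.radii[0]:
        raise ValueError("extraction radius below the first bin")
    j = int(np.argmin(np.abs(stack.radii - r_x)))
    vals = stack.intensities[:, j].copy()
    if sort:
        if mode == "sort":
            vals = np.sort(vals)
        elif mode == "running_max":
            vals = np.maximum.accumulate(vals)
        else:
            raise ValueError(f"unknown sort mode: {mode!r}")
    return BoundaryTrace(stack.times.copy(), vals)


def apply_bleach_corrections(
    stack: ProfileStack,
    time_lag: int = 0,
    exclusion_bins: int = 10,
) -> tuple[ProfileStack, dict]:
    """Trim the fast uniform-recovery frames and mask boundary-adjacent bins.

    Drops the first ``time_lag`` frames (the unresolved fast uniform
    recovery right after the bleach); the first retained frame becomes the
    fit's initial condition with its incomplete-bleach offset left in.  The
    ``exclusion_bins`` bins closest to the boundary — and everything beyond
    it — are masked out of all subsequent fitting (optically broadened
    interface).  Requires ``stack.R`` to be set when ``exclusion_bins > 0``.
    """
    if time_lag >= stack.times.size:
        raise ValueError("time lag drops every frame")
    mask = stack.mask.copy()
    if exclusion_bins > 0:
        if stack.R is None:
            raise ValueError("boundary radius must be detected before masking")
        r_cut = stack.R - exclusion_bins * stack.bin_width
        mask &= stack.radii <= r_cut
    trimmed = replace(
        stack,
        times=stack.times[time_lag:].copy(),
        intensities=stack.intensities[time_lag:].copy(),
        mask=mask,
    )
    meta = {
        "time_lag_frames": int(time_lag),
        "first_retained_time": float(trimmed.times[0]),
        "exclusion_bins": int(exclusion_bins),
        "n_masked_bins": int((~mask).sum()),
    }
    trimmed.meta = {**stack.meta, **meta}
    return trimmed, meta
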