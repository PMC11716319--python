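"""Thin-sheet fascia thickness mapping.

The deep (crural) fascia is modeled as an irregular thin tube. Working slice
by slice on a binary fascia mask, the pipeline extracts the band's one-pixel
middle line (topological skeleton, spur-pruned) and measures, at every
retained centerline pixel, the Euclidean distance from the middle line to
the inner and to the outer boundary along the local band normal; their sum
is the local thickness. Boundaries are located at sub-pixel precision as the
0.5 crossing of the bilinearly interpolated band indicator, which removes
most of the grid-alignment wobble a voxel-quantized distance transform
exhibits on bands only a few pixels wide. Pooling the samples over all
slices yields the thickness distribution through the leg; an independent
algebraic estimate (volume / (mean centerline arclength x slab width))
serves as a cross-check on the algorithmic mean.

Centerline arclength uses Kulpa's corrected step weights (0.948 per axial
step, 1.343 per diagonal step), which remove most of the systematic
overestimate of naive 8-connected chain length on smooth curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .core import LabeledMask3D

__all__ = [
    "ThicknessMap",
    "ThicknessHistogram",
    "ShiftReport",
    "dual_echo_subtract",
    "slice_centerline",
    "thickness_map",
    "mean_thickness_algebraic",
    "thickness_histogram",
    "compare_thickness",
    "threshold_segment",
]

# Kulpa's length-estimator weights for 8-connected digital curves
_W_AXIAL = 0.948
_W_DIAG = 1.343


def dual_echo_subtract(te1_image: np.ndarray, te2_image: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Ultrashort-echo minus short-echo image, the fascia-selective contrast.

    Fascia has a very short T2*, so it retains signal at the ultrashort echo
    (TE1) but has decayed by the short echo (TE2); the voxelwise difference
    therefore maximizes fascia signal and contrast. Negative values are
    clipped to zero and the result is optionally rescaled to [0, 1] by its
    maximum.
    """
    te1 = np.asarray(te1_image, dtype=float)
    te2 = np.asarray(te2_image, dtype=float)
    if te1.shape != te2.shape:
        raise ValueError(f"echo images differ in shape: {te1.shape} vs {te2.shape}")
    out = np.clip(te1 - te2, 0.0, None)
    if rescale and out.max() > 0:
        out = out / out.max()
    return out


def _prune_spurs(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Remove skeleton spur branches up to ``prune_px`` pixels long.

    Endpoint pixels (exactly one 8-connected neighbor) are peeled iteratively;
    closed loops have no endpoints and survive intact.
    """
    kernel = np.ones((3, 3), dtype=int)
    skel = skel.copy()
    for _ in range(prune_px):
        nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant") - skel
        endpoints = skel & (nbrs == 1)
        if not endpoints.any():
            break
        skel &= ~endpoints
    return skel


def _skeleton_arclength_px(skel: np.ndarray) -> float:
    """Arclength of a one-pixel skeleton in pixel units.

    Axial neighbor pairs contribute ``_W_AXIAL`` and diagonal pairs
    ``_W_DIAG`` (Kulpa's corrected weights); a diagonal step is skipped when
    the pair is already linked through a shared axial skeleton pixel, which
    would otherwise double-count the path.
    """
    s = skel.astype(bool)
    n_ax = np.count_nonzero(s[1:, :] & s[:-1, :]) + np.count_nonzero(s[:, 1:] & s[:, :-1])
    # main diagonal (dr=+1, dc=+1) and anti-diagonal (dr=+1, dc=-1) pairs
    d1 = s[1:, 1:] & s[:-1, :-1]
    d1_short = d1 & ~(s[1:, :-1] | s[:-1, 1:])
    d2 = s[1:, :-1] & s[:-1, 1:]
    d2_short = d2 & ~(s[1:, 1:] | s[:-1, :-1])
    return _W_AXIAL * n_ax + _W_DIAG * (np.count_nonzero(d1_short) + np.count_nonzero(d2_short))


def slice_centerline(
    binary_slice: np.ndarray,
    spacing_inplane: tuple[float, float],
    prune_px: int = 5,
) -> tuple[np.ndarray, float, dict]:
    """Middle line of a thin band on one slice, with its arclength in mm.

    Returns ``(centerline, arclength_mm, flags)`` where ``centerline`` is a
    boolean image of the spur-pruned one-pixel skeleton. An empty slice yields
    an empty centerline, arclength 0 and ``flags['empty']``; a band locally
    thinner than two pixels sets ``flags['thin_band']``.
    """
    dx, dy = (float(s) for s in spacing_inplane)
    if dx <= 0 or dy <= 0:
        raise ValueError("in-plane spacing must be positive")
    band = np.asarray(binary_slice).astype(bool)
    flags = {"empty": False, "thin_band": False}
    if not band.any():
        flags["empty"] = True
        return np.zeros_like(band), 0.0, flags
    if abs(dx - dy) > 1e-9 * max(dx, dy):
        warnings.warn("anisotropic in-plane spacing; arclength uses the mean pitch", stacklevel=2)
    pitch = 0.5 * (dx + dy)
    # local width check: EDT < 1 px at skeleton means the band is ~1 px wide
    edt_px = ndimage.distance_transform_edt(band)
    skel = skeletonize(band)
    skel = _prune_spurs(skel, prune_px)
    if skel.any() and float(edt_px[skel].min()) < 1.5:
        flags["thin_band"] = True
    arclength = _skeleton_arclength_px(skel) * pitch
    return skel, arclength, flags


def _centerline_tangents(skel: np.ndarray, spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent per skeleton pixel from the 5x5 neighborhood moments.

    Returns ``(keep, tangents)``: a boolean image of pixels with enough
    neighbors to define a direction, and an (N, 2) array of unit tangents
    (mm space) for those pixels in ``np.nonzero`` order.
    """
    dx, dy = spacing
    s = skel.astype(float)
    sxx = np.zeros_like(s)
    sxy = np.zeros_like(s)
    syy = np.zeros_like(s)
    cnt = np.zeros_like(s)
    for di in range(-2, 3):
        for dj in range(-2, 3):
            if di == 0 and dj == 0:
                continue
            shifted = np.roll(np.roll(s, -di, axis=0), -dj, axis=1)
            # roll wraps; zero out wrapped rows/cols
            if di > 0:
                shifted[-di:, :] = 0
            elif di < 0:
                shifted[:-di, :] = 0
            if dj > 0:
                shifted[:, -dj:] = 0
            elif dj < 0:
                shifted[:, :-dj] = 0
            ox, oy = di * dx, dj * dy
            sxx += ox * ox * shifted
            sxy += ox * oy * shifted
            syy += oy * oy * shifted
            cnt += shifted
    keep = skel & (cnt >= 2)
    a, b, c = sxx[keep], sxy[keep], syy[keep]
    # principal eigenvector of the 2x2 moment matrix [[a, b], [b, c]]
    lam = 0.5 * (a + c + np.sqrt((a - c) ** 2 + 4 * b * b))
    off_diagonal = np.abs(b) > 1e-12 * np.maximum(a, c)
    tx = np.where(off_diagonal, b, np.where(a >= c, 1.0, 0.0))
    ty = np.where(off_diagonal, lam - a, np.where(a >= c, 0.0, 1.0))
    norm = np.hypot(tx, ty)
    return keep, np.stack([tx / norm, ty / norm], axis=1)


def _normal_band_widths(
    band: np.ndarray,
    skel: np.ndarray,
    spacing: tuple[float, float],
    march_step_px: float = 0.5,
    max_march_px: float = 30.0,
    n_bisect: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-pixel band width at each centerline pixel, along the local normal.

    From every usable skeleton pixel two rays are cast along +/- the band
    normal; each boundary is the 0.5 level crossing of the bilinearly
    interpolated indicator, refined by vectorized bisection. Returns pixel
    rows, columns and widths (mm) for the samples that found both boundaries.
    """
    dx, dy = spacing
    keep, tangents = _centerline_tangents(skel, spacing)
    ii, jj = np.nonzero(keep)
    if len(ii) == 0:
        return ii, jj, np.zeros(0)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    bandf = band.astype(float)
    origin = np.stack([(ii + 0.5) * dx, (jj + 0.5) * dy], axis=1)
    pitch = 0.5 * (dx + dy)

    def inside_at(t, sign):
        pts = origin + sign * t[:, None] * normals
        coords = np.stack([pts[:, 0] / dx - 0.5, pts[:, 1] / dy - 0.5])
        return ndimage.map_coordinates(bandf, coords, order=1, mode="constant", cval=0.0) >= 0.5

    widths = np.zeros(len(ii))
    ok = np.ones(len(ii), dtype=bool)
    step = march_step_px * pitch
    cap = max_march_px * pitch
    for sign in (1.0, -1.0):
        t = np.zeros(len(ii))
        exited = np.zeros(len(ii), dtype=bool)
        while not exited.all() and t.max() < cap:
            t_try = t + step
            still_in = inside_at(t_try, sign)
            exited |= ~exited & ~still_in
            t = np.where(~exited & still_in, t_try, t)
        ok &= exited
        lo, hi = t.copy(), t + step
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            m_in = inside_at(mid, sign)
            lo = np.where(m_in, mid, lo)
            hi = np.where(m_in, hi, mid)
        widths += 0.5 * (lo + hi)
    return ii[ok], jj[ok], widths[ok]


@dataclass
class ThicknessMap:
    """Pooled per-slice centerline thickness samples with summary statistics.

    ``samples`` has columns ``slice``, ``x_mm``, ``y_mm``, ``thickness_mm``.
    """

    samples: pd.DataFrame
    spacing: tuple[float, float, float]
    flags: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def global_mean(self) -> float:
        return float(self.samples["thickness_mm"].mean())

    @property
    def global_sd(self) -> float:
        return float(self.samples["thickness_mm"].std(ddof=1))

    @property
    def global_median(self) -> float:
        return float(self.samples["thickness_mm"].median())

    def per_slice_mean(self) -> pd.Series:
        return self.samples.groupby("slice")["thickness_mm"].mean()


def thickness_map(
    mask: LabeledMask3D,
    label: int | str | None = None,
    prune_px: int = 5,
    min_samples: int = 100,
) -> ThicknessMap:
    """Map local fascia thickness at every centerline pixel, all slices pooled.

    For each axial slice the band's middle line is extracted; at each
    centerline pixel the distances from the middle line to the inner and the
    outer boundary are measured along the local band normal (sub-pixel, via
    the interpolated indicator) and summed into the local thickness in mm.
    Fewer than ``min_samples`` pooled samples raises an error advising a
    finer grid.
    """
    fg = mask.binary(label)
    dx, dy, dz = mask.spacing
    rows = []
    any_thin = False
    for s in range(mask.shape[2]):
        band = fg[:, :, s]
        if not band.any():
            continue
        skel, _, flags = slice_centerline(band, (dx, dy), prune_px=prune_px)
        any_thin |= flags["thin_band"]
        if not skel.any():
            continue
        ii, jj, t = _normal_band_widths(band, skel, (dx, dy))
        keep = t > 0
        ii, jj, t = ii[keep], jj[keep], t[keep]
        if len(t) == 0:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "slice": s,
                    "x_mm": (ii + 0.5) * dx,
                    "y_mm": (jj + 0.5) * dy,
                    "thickness_mm": t,
                }
            )
        )
    samples = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["slice", "x_mm", "y_mm", "thickness_mm"])
    )
    if len(samples) < min_samples:
        raise ValueError(
            f"only {len(samples)} thickness samples (< {min_samples}); "
            "use a finer in-plane resolution or a larger mask"
        )
    return ThicknessMap(samples, mask.spacing, flags={"thin_band": any_thin})


def mean_thickness_algebraic(
    mask: LabeledMask3D, label: int | str | None = None, prune_px: int = 5
) -> float:
    """Algebraic mean thickness: volume / (mean centerline arclength x width).

    The fascia volume V (mm^3, voxel sum) is divided by the mean per-slice
    centerline arclength L over non-empty slices and the slab width
    W = (number of non-empty slices) x slice thickness, giving the mean
    thickness of the segmented sheet. This is an independent cross-check on
    the distance-transform estimator.
    """
    fg = mask.binary(label)
    dx, dy, dz = mask.spacing
    volume = float(np.count_nonzero(fg)) * dx * dy * dz
    arclengths = []
    for s in range(mask.shape[2]):
        band = fg[:, :, s]
        if not band.any():
            continue
        _, arclen, _ = slice_centerline(band, (dx, dy), prune_px=prune_px)
        if arclen > 0:
            arclengths.append(arclen)
    if not arclengths:
        raise ValueError("mask has no non-empty slice with a measurable centerline")
    mean_arclength = float(np.mean(arclengths))
    width = len(arclengths) * dz
    return volume / (mean_arclength * width)


@dataclass
class ThicknessHistogram:
    """Fixed-width thickness histogram; counts conserve the sample number."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: bool = False


def thickness_histogram(tmap: ThicknessMap, bin_width_mm: float = 0.05, density: bool = False) -> ThicknessHistogram:
    """Histogram the pooled thickness samples with fixed-width bins from 0."""
    if bin_width_mm <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width_mm}")
    if tmap.n_samples == 0:
        raise ValueError("thickness map has no samples")
    t = tmap.samples["thickness_mm"].to_numpy()
    n_bins = max(1, int(np.ceil(t.max() / bin_width_mm)))
    edges = np.arange(n_bins + 1) * bin_width_mm
    counts, _ = np.histogram(t, bins=edges, density=density)
    return ThicknessHistogram(edges, counts, density=density)


@dataclass
class ShiftReport:
    """Pre-to-post thickness change summary."""

    mean_shift_pct: float
    median_shift_pct: float
    pre_mean_mm: float
    post_mean_mm: float
    pre_hist: ThicknessHistogram
    post_hist: ThicknessHistogram


def compare_thickness(
    pre_map: ThicknessMap, post_map: ThicknessMap, bin_width_mm: float = 0.05
) -> ShiftReport:
    """Percent change of mean and median thickness, with overlaid histograms.

    Shifts are 100*(post - pre)/pre; a rightward-shifted distribution gives a
    positive shift (thickening).
    """
    if pre_map.n_samples == 0 or post_map.n_samples == 0:
        raise ValueError("both thickness maps must be non-empty")
    mean_shift = 100.0 * (post_map.global_mean - pre_map.global_mean) / pre_map.global_mean
    median_shift = 100.0 * (post_map.global_median - pre_map.global_median) / pre_map.global_median
    return ShiftReport(
        mean_shift_pct=mean_shift,
        median_shift_pct=median_shift,
        pre_mean_mm=pre_map.global_mean,
        post_mean_mm=post_map.global_mean,
        pre_hist=thickness_histogram(pre_map, bin_width_mm),
        post_hist=thickness_histogram(post_map, bin_width_mm),
    )


def threshold_segment(subtraction_image: np.ndarray, threshold: float) -> np.ndarray:
    """Naive intensity threshold on a dual-echo subtraction image.

    Demonstration helper only — real fascia masks come from expert
    segmentation (or, in tests, from phantoms); this is not part of the
    quantification pipeline.
    """
    return np.asarray(subtraction_image) >= threshold


def plot_thickness_histograms(report: ShiftReport, path=None):
    """Overlaid pre/post thickness histograms (matplotlib figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for hist, lab, color in ((report.pre_hist, "pre", "C0"), (report.post_hist, "post", "C3")):
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        ax.bar(centers, hist.counts, width=np.diff(hist.bin_edges), alpha=0.5, label=lab, color=color)
    ax.set_xlabel("fascia thickness (mm)")
    ax.set_ylabel("count")
    ax.legend(title=f"mean shift {report.mean_shift_pct:+.2f}%")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
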