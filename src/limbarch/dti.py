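"""Diffusion-tensor muscle architecture: tensor fit, FA/MD, tractography,
boundary extrapolation, the length-based inclusion filter, and the
architecture metrics (fascicle length, pennation angle, PCSA).

The tensor is reconstructed per voxel by log-linear least squares; fiber
tracking is deterministic fixed-step Euler integration along the principal
eigenvector, bidirectional from uniformly sampled seeds. Tracts that stop
short of the muscle boundary are extended by fitting each coordinate as a
polynomial of arclength and marching the fitted curve outward until it
crosses the mask surface. Fascicle length is the polyline arclength of the
extrapolated tract, pennation the angle between the unit fascicle chord and
the muscle's line of action, and PCSA the muscle volume over the mean
fascicle length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import DWIStack, LabeledMask3D, TensorField

__all__ = [
    "TrackingParams",
    "FiberTract",
    "TractSet",
    "ArchitectureReport",
    "fit_tensors",
    "fa_md",
    "track_fibers",
    "extrapolate_tract",
    "filter_tracts",
    "line_of_action",
    "architecture_metrics",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tensor reconstruction and scalar maps
# ---------------------------------------------------------------------------

def _foreground(mask, shape) -> np.ndarray:
    if isinstance(mask, LabeledMask3D):
        fg = mask.binary()
    else:
        fg = np.asarray(mask).astype(bool)
    if fg.shape != shape:
        raise ValueError(f"mask shape {fg.shape} does not match grid {shape}")
    return fg


def fit_tensors(dwi: DWIStack, mask) -> TensorField:
    """Log-linear least-squares tensor reconstruction per masked voxel.

    Solves ``ln S(g) = ln S0 - b g' D g`` for the six unique tensor
    components and ``ln S0`` at every voxel of the mask. Voxels with any
    non-positive signal sample are flagged invalid and not fitted.
    """
    if dwi.n_volumes < 7:
        raise ValueError(
            f"tensor fit needs at least 7 volumes (6 directions + b0), got {dwi.n_volumes}"
        )
    if len(dwi.b0_indices) != 1:
        raise ValueError(f"exactly one b=0 volume required, found {len(dwi.b0_indices)}")
    fg = _foreground(mask, dwi.signal.shape[:3])
    if not fg.any():
        raise ValueError("mask selects no voxels")

    g = dwi.gradients
    b = dwi.b_values
    X = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones(dwi.n_volumes),
        ]
    )
    sig = dwi.signal[fg]  # (nvox, nvol)
    fitable = np.all(sig > 0, axis=1)
    coeffs = np.zeros((sig.shape[0], 7))
    if fitable.any():
        Y = np.log(sig[fitable]).T  # (nvol, nfit)
        sol, *_ = np.linalg.lstsq(X, Y, rcond=None)
        coeffs[fitable] = sol.T

    nx, ny, nz = dwi.signal.shape[:3]
    tensors = np.zeros((nx, ny, nz, 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, i] for i in range(6))
    T = np.empty((sig.shape[0], 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = dxx, dyy, dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz
    tensors[fg] = T
    valid = np.zeros((nx, ny, nz), dtype=bool)
    valid[fg] = fitable
    if not valid.any():
        raise ValueError("no voxel in the mask had all-positive signal to fit")
    return TensorField(tensors, valid, dwi.spacing)


def fa_md(tfield: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Fractional anisotropy and mean diffusivity maps.

    MD is the eigenvalue mean and FA the normalized eigenvalue dispersion::

        MD = (l1 + l2 + l3) / 3
        FA = sqrt(3/2) * sqrt(sum_i (l_i - MD)^2) / sqrt(sum_i l_i^2)

    clamped to [0, 1]. Voxels outside the validity mask, or with a negative
    eigenvalue, are NaN in both maps.
    """
    w = np.linalg.eigvalsh(tfield.tensors)
    ok = tfield.valid & np.all(w >= 0, axis=-1) & (np.sum(w**2, axis=-1) > 0)
    md = np.where(ok, w.mean(axis=-1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.sqrt(np.sum((w - w.mean(axis=-1, keepdims=True)) ** 2, axis=-1))
        den = np.sqrt(np.sum(w**2, axis=-1))
        fa = np.sqrt(1.5) * num / den
    fa = np.where(ok, np.clip(fa, 0.0, 1.0), np.nan)
    return fa, md


# ---------------------------------------------------------------------------
# tract containers
# ---------------------------------------------------------------------------

@dataclass
class FiberTract:
    """An ordered polyline in world coordinates (mm) with provenance."""

    points: np.ndarray  # (n, 3)
    raw_length: float
    extrapolated_length: float | None = None
    status: str = "raw"  # raw | extrapolated | accepted | rejected
    reason: str | None = None
    seed_point: np.ndarray | None = None

    @property
    def length(self) -> float:
        return self.extrapolated_length if self.extrapolated_length is not None else self.raw_length

    def chord_unit(self) -> np.ndarray:
        v = self.points[-1] - self.points[0]
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate tract: coincident endpoints")
        return v / n


@dataclass
class TractSet:
    """A collection of fiber tracts plus bookkeeping counts."""

    tracts: list[FiberTract]
    counts: dict = field(default_factory=dict)
    params: "TrackingParams | None" = None
    seed: int | None = None

    def with_status(self, status: str) -> list[FiberTract]:
        return [t for t in self.tracts if t.status == status]

    @property
    def accepted(self) -> list[FiberTract]:
        return self.with_status("accepted")


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# deterministic streamline tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackingParams:
    """Streamline integration parameters.

    Defaults: 1 mm Euler steps, a 30 degree per-step turning limit, FA gate
    [0.05, 0.6] (muscle FA is low; the ceiling rejects artifactual voxels),
    a 5-200 mm tract length window, a 1000-tract target and a 50 000-seed
    attempt budget.
    """

    step_mm: float = 1.0
    max_angle_deg: float = 30.0
    fa_min: float = 0.05
    fa_max: float = 0.6
    min_length_mm: float = 5.0
    max_length_mm: float = 200.0
    target_count: int = 1000
    max_seed_attempts: int = 50_000
    #: erode the seeding region by this many voxels to keep seeds out of
    #: partial-volume boundary voxels (tracking itself uses the full mask)
    seed_erosion_voxels: int = 1


def _trilinear(grid: np.ndarray, p: np.ndarray, spacing: np.ndarray) -> float:
    """Trilinear interpolation of a scalar grid at world point ``p`` (mm).

    Voxel values live at voxel centers; points beyond the outer half-voxel
    shell evaluate to 0.
    """
    u = p / spacing - 0.5
    n = grid.shape
    if np.any(u < -0.5) or np.any(u > np.asarray(n) - 0.5):
        return 0.0
    u = np.clip(u, 0.0, np.asarray(n) - 1.0 - 1e-12)
    i0 = u.astype(int)
    f = u - i0
    i1 = np.minimum(i0 + 1, np.asarray(n) - 1)
    # gather the 8 cell corners explicitly
    g = grid
    x0, y0, z0 = i0
    x1, y1, z1 = i1
    fx, fy, fz = f
    c00 = g[x0, y0, z0] * (1 - fx) + g[x1, y0, z0] * fx
    c10 = g[x0, y1, z0] * (1 - fx) + g[x1, y1, z0] * fx
    c01 = g[x0, y0, z1] * (1 - fx) + g[x1, y0, z1] * fx
    c11 = g[x0, y1, z1] * (1 - fx) + g[x1, y1, z1] * fx
    return float((c00 * (1 - fy) + c10 * fy) * (1 - fz) + (c01 * (1 - fy) + c11 * fy) * fz)


class _FieldSampler:
    """Field lookups for tracking.

    Trackability is the 0.5 level set of the trilinearly interpolated
    indicator of gated voxels (inside mask, valid fit, FA within bounds),
    which smooths rasterization staircase out of the stopping surface.
    Directions come from the nearest gated voxel.
    """

    def __init__(self, tfield: TensorField, fg: np.ndarray, params: TrackingParams):
        evals, evecs = tfield.eigensystem()
        self.e1 = evecs[..., :, 0]
        fa, _ = fa_md(tfield)
        with np.errstate(invalid="ignore"):
            self.ok = (
                fg & tfield.valid & np.isfinite(fa)
                & (fa >= params.fa_min) & (fa <= params.fa_max)
            )
        self.ok_float = self.ok.astype(float)
        self.spacing = np.asarray(tfield.spacing)
        self.shape = tfield.shape

    def trackable(self, p: np.ndarray) -> bool:
        return _trilinear(self.ok_float, p, self.spacing) >= 0.5

    def direction(self, p: np.ndarray) -> np.ndarray | None:
        idx = np.clip(np.floor(p / self.spacing).astype(int), 0, np.asarray(self.shape) - 1)
        if self.ok[tuple(idx)]:
            return self.e1[tuple(idx)]
        # nearest gated voxel among face neighbors (deterministic order)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            j = idx + d
            if np.all(j >= 0) and np.all(j < self.shape) and self.ok[tuple(j)]:
                return self.e1[tuple(j)]
        return None


def _bisect_boundary(inside_fn, p_in: np.ndarray, p_out: np.ndarray, tol_mm: float = 0.1) -> np.ndarray:
    """Locate the inside/outside transition on the segment to ``tol_mm``."""
    lo, hi = p_in, p_out
    while np.linalg.norm(hi - lo) > tol_mm:
        mid = 0.5 * (lo + hi)
        if inside_fn(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _trace_half(
    sampler: _FieldSampler, p0: np.ndarray, d0: np.ndarray, params: TrackingParams, budget_mm: float
) -> list[np.ndarray]:
    """One direction of a streamline from ``p0``; returns points after p0."""
    cos_max = math.cos(math.radians(params.max_angle_deg))
    pts: list[np.ndarray] = []
    p, d = p0, d0
    length = 0.0
    while length < budget_mm:
        q = p + params.step_mm * d
        if not sampler.trackable(q):
            crossing = _bisect_boundary(sampler.trackable, p, q)
            if np.linalg.norm(crossing - p) > 1e-9:
                pts.append(crossing)
            break
        e = sampler.direction(q)
        if e is None:
            pts.append(q)
            break
        c = float(np.dot(e, d))
        if c < 0:
            e, c = -e, -c  # eigenvector sign continuity with the previous step
        pts.append(q)
        length += params.step_mm
        if c < cos_max:
            break  # turning angle exceeded: stop at q
        p, d = q, e
    return pts


def track_fibers(
    tfield: TensorField,
    mask,
    params: TrackingParams | None = None,
    seed: int | None = 0,
) -> TractSet:
    """Deterministic bidirectional streamline tracking within a muscle mask.

    Seeds are drawn uniformly inside trackable voxels; each streamline is
    integrated with fixed-step Euler along the principal eigenvector in both
    directions, stopping on mask exit (the boundary crossing is appended by
    bisection), FA outside bounds, an excessive per-step turning angle, or
    the length ceiling. Tracts shorter than the length floor are discarded.
    Seeding continues until the target count is accepted or the attempt
    budget is exhausted (a warning is logged, never an exception). Identical
    seeds give bit-identical results.
    """
    params = params or TrackingParams()
    fg = _foreground(mask, tfield.shape)
    sampler = _FieldSampler(tfield, fg, params)
    seed_region = sampler.ok
    if params.seed_erosion_voxels > 0:
        eroded = ndimage.binary_erosion(
            seed_region, iterations=params.seed_erosion_voxels
        )
        if eroded.any():
            seed_region = eroded
        else:
            logger.warning("seed erosion emptied the mask; seeding from the full region")
    seed_voxels = np.argwhere(seed_region)
    tracts: list[FiberTract] = []
    attempts = 0
    if len(seed_voxels) == 0:
        logger.warning("no trackable voxels in mask; returning empty tract set")
        return TractSet([], {"seeded": 0, "tracked": 0}, params, seed)

    rng = np.random.default_rng(seed)
    spacing = sampler.spacing
    while len(tracts) < params.target_count and attempts < params.max_seed_attempts:
        attempts += 1
        vox = seed_voxels[rng.integers(len(seed_voxels))]
        p0 = (vox + rng.uniform(0.0, 1.0, 3)) * spacing
        if not sampler.trackable(p0):
            continue
        d0 = sampler.direction(p0)
        if d0 is None:
            continue
        fwd = _trace_half(sampler, p0, d0, params, params.max_length_mm)
        fwd_len = _polyline_length(np.vstack([p0, *fwd])) if fwd else 0.0
        bwd = _trace_half(sampler, p0, -d0, params, params.max_length_mm - fwd_len)
        points = np.vstack([*reversed(bwd), p0, *fwd]) if (fwd or bwd) else None
        if points is None or len(points) < 2:
            continue
        raw_length = _polyline_length(points)
        if raw_length < params.min_length_mm:
            continue
        tracts.append(FiberTract(points=points, raw_length=raw_length, seed_point=p0.copy()))
    if len(tracts) < params.target_count:
        logger.warning(
            "tracking accepted %d of %d requested tracts after %d seed attempts",
            len(tracts), params.target_count, attempts,
        )
    counts = {"seeded": attempts, "tracked": len(tracts)}
    return TractSet(tracts, counts, params, seed)


# ---------------------------------------------------------------------------
# polynomial extrapolation to the muscle boundary
# ---------------------------------------------------------------------------

def _inside_mask_fn(mask):
    """Point-in-mask predicate: 0.5 level set of the interpolated indicator."""
    if isinstance(mask, LabeledMask3D):
        fg, spacing = mask.binary().astype(float), np.asarray(mask.spacing)
    else:
        raise TypeError("extrapolation needs a LabeledMask3D for its boundary")

    def inside(p: np.ndarray) -> bool:
        return _trilinear(fg, p, spacing) >= 0.5

    return inside


def extrapolate_tract(
    tract: FiberTract,
    mask: LabeledMask3D,
    poly_order: int = 3,
    step_mm: float = 1.0,
    max_extension_frac: float = 0.5,
    bisect_tol_mm: float = 0.1,
) -> FiberTract:
    """Extend a tract to the muscle boundary by polynomial fitting.

    Each coordinate is fitted as a polynomial of arclength by least squares;
    the fitted curve is marched outward from both ends in steps of half the
    tracking step until it first leaves the mask, the crossing located by
    bisection. Extension is capped at ``max_extension_frac`` of the raw
    length per end; hitting the cap marks the tract ``rejected`` with reason
    ``no-boundary``. Tracts with fewer than ``poly_order + 1`` points are
    rejected with reason ``short`` (no exception raised).
    """
    n = len(tract.points)
    if n < poly_order + 1:
        return replace(tract, status="rejected", reason="short")
    inside = _inside_mask_fn(mask)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(tract.points, axis=0), axis=1))])
    polys = [
        np.polynomial.Polynomial.fit(s, tract.points[:, i], deg=poly_order) for i in range(3)
    ]

    def curve(t: float) -> np.ndarray:
        return np.array([p(t) for p in polys])

    h = step_mm / 2.0
    cap = max_extension_frac * tract.raw_length

    def extend(t_end: float, sign: float) -> np.ndarray | None:
        """Points beyond one end (ordered outward), or None on cap hit."""
        ts = []
        t_prev, ext = t_end, 0.0
        while True:
            t_next = t_prev + sign * h
            ext += h
            if ext > cap + h:
                return None
            if not inside(curve(t_next)):
                t_lo, t_hi = t_prev, t_next
                while abs(t_hi - t_lo) > bisect_tol_mm:
                    mid = 0.5 * (t_lo + t_hi)
                    if inside(curve(mid)):
                        t_lo = mid
                    else:
                        t_hi = mid
                ts.append(t_lo)
                return np.array([curve(t) for t in ts]) if ts else np.empty((0, 3))
            ts.append(t_next)
            t_prev = t_next

    head = extend(0.0, -1.0)
    tail = extend(s[-1], +1.0)
    if head is None or tail is None:
        return replace(tract, status="rejected", reason="no-boundary")
    points = np.vstack([head[::-1], tract.points, tail]) if (len(head) or len(tail)) else tract.points
    return replace(
        tract,
        points=points,
        extrapolated_length=_polyline_length(points),
        status="extrapolated",
        reason=None,
    )


def extrapolate_tracts(
    tractset: TractSet, mask: LabeledMask3D, poly_order: int = 3, step_mm: float | None = None
) -> TractSet:
    """Apply :func:`extrapolate_tract` to every tract of a set."""
    step = step_mm if step_mm is not None else (tractset.params.step_mm if tractset.params else 1.0)
    out = [extrapolate_tract(t, mask, poly_order=poly_order, step_mm=step) for t in tractset.tracts]
    counts = dict(tractset.counts)
    counts["extrapolated"] = sum(t.status == "extrapolated" for t in out)
    return TractSet(out, counts, tractset.params, tractset.seed)


# ---------------------------------------------------------------------------
# inclusion filter and architecture metrics
# ---------------------------------------------------------------------------

def filter_tracts(
    tractset: TractSet,
    max_extension_ratio: float = 1.3,
    min_length_mm: float = 5.0,
    max_length_mm: float = 200.0,
) -> TractSet:
    """Inclusion filter: keep extrapolated tracts within 30% of raw length.

    A tract is accepted when its extrapolation succeeded, its extrapolated
    length is at most ``max_extension_ratio`` times its raw length, and the
    extrapolated length lies in the tracking length window. Every rejection
    carries exactly one reason (``overextended``, ``too_short``, ``too_long``
    or the upstream extrapolation reason).
    """
    out = []
    for t in tractset.tracts:
        if t.status == "rejected":
            out.append(t)
        elif t.status != "extrapolated" or t.extrapolated_length is None:
            out.append(replace(t, status="rejected", reason="not-extrapolated"))
        elif t.extrapolated_length > max_extension_ratio * t.raw_length:
            out.append(replace(t, status="rejected", reason="overextended"))
        elif t.extrapolated_length < min_length_mm:
            out.append(replace(t, status="rejected", reason="too_short"))
        elif t.extrapolated_length > max_length_mm:
            out.append(replace(t, status="rejected", reason="too_long"))
        else:
            out.append(replace(t, status="accepted"))
    counts = dict(tractset.counts)
    counts["accepted"] = sum(t.status == "accepted" for t in out)
    counts["rejected"] = sum(t.status == "rejected" for t in out)
    return TractSet(out, counts, tractset.params, tractset.seed)


def line_of_action(mask: LabeledMask3D, label: int | str | None = None) -> np.ndarray:
    """Muscle line of action: principal axis of the voxel coordinate cloud.

    The principal eigenvector of the covariance of foreground voxel world
    coordinates, sign-oriented toward positive z, unit norm. Degenerate
    regions (planar or smaller) raise an error.
    """
    fg = mask.binary(label)
    idx = np.argwhere(fg)
    if len(idx) < 4:
        raise ValueError(f"region has only {len(idx)} voxels; need a 3-D extent")
    coords = (idx + 0.5) * np.asarray(mask.spacing)
    cov = np.cov(coords.T)
    w, v = np.linalg.eigh(cov)
    if w[0] <= 1e-9 * w[2]:
        raise ValueError("region is degenerate (planar or thinner); line of action undefined")
    loa = v[:, 2]
    if loa[2] < 0 or (loa[2] == 0 and (loa[0] < 0 or (loa[0] == 0 and loa[1] < 0))):
        loa = -loa
    return loa / np.linalg.norm(loa)


@dataclass
class ArchitectureReport:
    """Per-muscle architecture summary.

    Lengths in cm, angles in degrees, PCSA in cm^2. The defining identity
    ``PCSA * mean_fascicle_length_cm == volume_cm3`` holds exactly as stored.
    """

    muscle: str
    volume_cm3: float
    mean_fascicle_length_cm: float
    sd_fascicle_length_cm: float
    mean_pennation_deg: float
    sd_pennation_deg: float
    pcsa_cm2: float
    line_of_action: np.ndarray
    counts: dict = field(default_factory=dict)


def architecture_metrics(
    tractset: TractSet,
    loa: np.ndarray,
    muscle_volume_cm3: float,
    muscle: str = "muscle",
) -> ArchitectureReport:
    """Fascicle length, pennation angle and PCSA over the accepted tracts.

    Fascicle length is the polyline arclength of each accepted (extrapolated)
    tract; the fascicle vector is the unit chord from first to last point;
    pennation is ``arccos(|chord . loa|)`` in degrees (the absolute value
    folds arbitrary tract orientation into [0, 90]); PCSA is the muscle
    volume divided by the mean fascicle length.
    """
    loa = np.asarray(loa, dtype=float)
    if abs(np.linalg.norm(loa) - 1.0) > 1e-9:
        raise ValueError("line of action must be unit norm")
    if muscle_volume_cm3 <= 0:
        raise ValueError("muscle volume must be positive")
    accepted = tractset.accepted
    if not accepted:
        raise ValueError(
            "no accepted tracts; inspect tracking diagnostics (counts: "
            f"{tractset.counts})"
        )
    lengths_cm = np.array([t.length for t in accepted]) / 10.0
    chords = np.array([t.chord_unit() for t in accepted])
    cosines = np.clip(np.abs(chords @ loa), 0.0, 1.0)
    pennation = np.degrees(np.arccos(cosines))
    mean_len = float(lengths_cm.mean())
    return ArchitectureReport(
        muscle=muscle,
        volume_cm3=float(muscle_volume_cm3),
        mean_fascicle_length_cm=mean_len,
        sd_fascicle_length_cm=float(lengths_cm.std(ddof=1)) if len(lengths_cm) > 1 else 0.0,
        mean_pennation_deg=float(pennation.mean()),
        sd_pennation_deg=float(pennation.std(ddof=1)) if len(pennation) > 1 else 0.0,
        pcsa_cm2=float(muscle_volume_cm3) / mean_len,
        line_of_action=loa,
        counts=dict(tractset.counts),
    )
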