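"""Per-label and per-compartment volumetry with pre/post percent changes.

Volumes are computed by summing voxel volumes per label (exact integer counts
times the voxel volume), compartments are exact sums of their member labels,
and percent changes are always computed sum-then-ratio, never by averaging
member percentages.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .core import LabeledMask3D

__all__ = [
    "label_volume",
    "label_volumes",
    "percent_change",
    "volume_report",
    "group_compartments",
    "align_stacks_by_landmark",
    "DEFAULT_COMPARTMENTS",
]

#: Anatomical compartment groupings of the calf and thigh. Calf: the
#: superficial posterior compartment (triceps surae) comprises the medial and
#: lateral gastrocnemius and soleus; the anterior compartment the tibialis
#: anterior, digital extensors and popliteus; the deep posterior the tibialis
#: posterior; the lateral the peroneals. Thigh: anterior (quadriceps),
#: posterior (hamstrings) and medial (adductors + gracilis) compartments.
DEFAULT_COMPARTMENTS: dict[str, list[str]] = {
    "calf_superficial_posterior": ["medial_gastrocnemius", "lateral_gastrocnemius", "soleus"],
    "calf_anterior": [
        "tibialis_anterior",
        "extensor_digitorum_longus",
        "extensor_hallucis_longus",
        "popliteus",
    ],
    "calf_deep_posterior": ["tibialis_posterior"],
    "calf_lateral": ["peroneals"],
    "thigh_anterior": ["rectus_femoris", "vastus_medialis", "vastus_lateralis", "vastus_intermedius"],
    "thigh_posterior": [
        "biceps_femoris_short_head",
        "biceps_femoris_long_head",
        "semitendinosus",
        "semimembranosus",
    ],
    "thigh_medial": ["adductors", "gracilis"],
}


def label_volume(mask: LabeledMask3D, label: int | str) -> float:
    """Volume of one label in cm^3: voxel count times voxel volume.

    A label that is present in the label map but occupies no voxels has
    volume 0; an unknown label raises ``KeyError`` naming it.
    """
    lid = mask.id_for(label)
    count = int(np.count_nonzero(mask.voxels == lid))
    return count * mask.voxel_volume_mm3 / 1000.0


def label_volumes(mask: LabeledMask3D) -> dict[str, float]:
    """Volumes of every mapped label, keyed by name (cm^3)."""
    ids, counts = np.unique(mask.voxels, return_counts=True)
    by_id = dict(zip(ids.tolist(), counts.tolist()))
    return {
        name: by_id.get(lid, 0) * mask.voxel_volume_mm3 / 1000.0
        for lid, name in mask.labels.items()
    }


def percent_change(pre_value: float, post_value: float) -> float:
    """Signed percent change 100*(post - pre)/pre; negative means loss."""
    if pre_value <= 0:
        raise ValueError(f"pre_value must be positive, got {pre_value}")
    return 100.0 * (post_value - pre_value) / pre_value


def _rendering(pct: float) -> str:
    """Unsigned loss/gain phrasing used in report tables."""
    if pct < 0:
        return f"loss of {-pct:.2f}%"
    if pct > 0:
        return f"gain of {pct:.2f}%"
    return "no change"


def volume_report(pre: dict[str, float], post: dict[str, float]) -> pd.DataFrame:
    """Tabulate per-label pre/post volumes with signed percent changes.

    Labels present in only one time point are reported with NaN for the
    missing value and no percent change.
    """
    names = sorted(set(pre) | set(post))
    rows = []
    for name in names:
        p, q = pre.get(name, np.nan), post.get(name, np.nan)
        pct = percent_change(p, q) if (name in pre and name in post and p > 0) else np.nan
        rows.append(
            {
                "name": name,
                "pre_cm3": p,
                "post_cm3": q,
                "percent_change": pct,
                "change": _rendering(pct) if np.isfinite(pct) else "",
            }
        )
    return pd.DataFrame(rows)


def group_compartments(
    pre: dict[str, float],
    post: dict[str, float] | None,
    compartment_map: dict[str, list[str]],
) -> pd.DataFrame:
    """Aggregate label volumes into compartments and recompute percent changes.

    Compartment volumes are exact sums of member volumes; percent changes are
    computed from the summed volumes (sum-then-ratio), not averaged from the
    member percentages. Every member must be present in the per-label report.
    """
    for comp, members in compartment_map.items():
        if not members:
            raise ValueError(f"compartment {comp!r} has no members")
        missing = [m for m in members if m not in pre or (post is not None and m not in post)]
        if missing:
            raise KeyError(f"compartment {comp!r} is missing member labels: {missing}")
    rows = []
    for comp, members in compartment_map.items():
        p = sum(pre[m] for m in members)
        if post is None:
            rows.append({"name": comp, "pre_cm3": p})
            continue
        q = sum(post[m] for m in members)
        pct = percent_change(p, q)
        rows.append(
            {"name": comp, "pre_cm3": p, "post_cm3": q, "percent_change": pct, "change": _rendering(pct)}
        )
    return pd.DataFrame(rows)


def align_stacks_by_landmark(
    mask_pre: LabeledMask3D,
    mask_post: LabeledMask3D,
    landmark_slice_pre: int,
    landmark_slice_post: int,
) -> tuple[LabeledMask3D, LabeledMask3D]:
    """Align two stacks so a bony landmark slice coincides, then trim.

    The post stack is shifted by whole slices until the landmark slices line
    up and both stacks are cropped to their common z range; no resampling or
    interpolation is performed, so the in-plane grids must already match.
    """
    if mask_pre.spacing[:2] != mask_post.spacing[:2] or mask_pre.shape[:2] != mask_post.shape[:2]:
        raise ValueError(
            "pre and post stacks must share the in-plane grid and spacing "
            "(full registration is out of scope)"
        )
    if abs(mask_pre.spacing[2] - mask_post.spacing[2]) > 1e-9:
        raise ValueError("pre and post stacks must share slice thickness")
    nz_pre, nz_post = mask_pre.shape[2], mask_post.shape[2]
    if not (0 <= landmark_slice_pre < nz_pre):
        raise IndexError(f"landmark_slice_pre {landmark_slice_pre} outside [0, {nz_pre})")
    if not (0 <= landmark_slice_post < nz_post):
        raise IndexError(f"landmark_slice_post {landmark_slice_post} outside [0, {nz_post})")

    offset = landmark_slice_post - landmark_slice_pre  # post index = pre index + offset
    lo = max(0, -offset)
    hi = min(nz_pre, nz_post - offset)
    if hi <= lo:
        raise ValueError("no overlapping slices after landmark alignment")
    pre_trim = LabeledMask3D(
        mask_pre.voxels[:, :, lo:hi].copy(), mask_pre.spacing, dict(mask_pre.labels)
    )
    post_trim = LabeledMask3D(
        mask_post.voxels[:, :, lo + offset : hi + offset].copy(),
        mask_post.spacing,
        dict(mask_post.labels),
    )
    return pre_trim, post_trim
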