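"""Run orchestration: image preprocessing, run configuration, and the
pre-vs-post comparison driver that chains volumetry, fascia thickness and
DTI architecture into one reproducible report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import uniform_filter
from scipy.signal import convolve2d

from . import __version__
from . import dti as dti_mod
from . import fascia as fascia_mod
from . import io as lio
from . import volumetry as vol_mod

__all__ = ["preprocess_image", "RunConfig", "ComparisonReport", "run_comparison", "load_config", "save_config"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _adaptive_wiener(sl: np.ndarray, size: int) -> np.ndarray:
    """Local adaptive Wiener filter with reflective boundaries.

    Noise power is estimated as the mean local variance; where the local
    variance falls below it (flat patches, constants) the output is the
    local mean, so constant images pass through unchanged.
    """
    l_mean = uniform_filter(sl, size, mode="reflect")
    l_var = uniform_filter(sl * sl, size, mode="reflect") - l_mean**2
    l_var = np.maximum(l_var, 0.0)
    noise = l_var.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(l_var > noise, 1.0 - noise / l_var, 0.0)
    return l_mean + gain * (sl - l_mean)


def _binomial_kernel(size: int) -> np.ndarray:
    """Separable discrete Gaussian (binomial) kernel, normalized to sum 1."""
    row = np.array([1.0])
    for _ in range(size - 1):
        row = np.convolve(row, [0.5, 0.5])
    return np.outer(row, row)


def preprocess_image(image: np.ndarray, wiener_kernel: int = 3, gaussian_kernel: int = 3) -> np.ndarray:
    """Slice-wise Wiener then Gaussian smoothing (3x3 kernels by default).

    Operates on each axial slice independently. A kernel size of 1 is the
    identity for either filter; even kernel sizes are rejected. The Gaussian
    uses a normalized binomial kernel with reflective boundaries, so constant
    images are preserved and interior impulses keep their sum.
    """
    for name, k in (("wiener", wiener_kernel), ("gaussian", gaussian_kernel)):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"{name} kernel size must be odd and >= 1, got {k}")
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    if img.ndim != 3:
        raise ValueError("image must be 2-D or 3-D")
    out = np.empty_like(img)
    gk = _binomial_kernel(gaussian_kernel)
    for s in range(img.shape[2]):
        sl = img[:, :, s]
        if wiener_kernel > 1:
            sl = _adaptive_wiener(sl, wiener_kernel)
        if gaussian_kernel > 1:
            sl = convolve2d(sl, gk, mode="same", boundary="symm")
        out[:, :, s] = sl
    return out[..., 0] if squeeze else out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for a pre/post comparison run.

    Every tunable of the pipeline has exactly one home here; YAML
    serialization round-trips (``load(save(c)) == c``).
    """

    schema_version: int = 1
    # stage toggles
    run_volumetry: bool = True
    run_fascia: bool = True
    run_dti: bool = False
    # inputs (paths); landmark slices for z alignment
    pre_mask: str | None = None
    post_mask: str | None = None
    label_sidecar: str | None = None
    landmark_pre: int = 0
    landmark_post: int = 0
    pre_fascia_mask: str | None = None
    post_fascia_mask: str | None = None
    pre_dwi: str | None = None
    pre_bval: str | None = None
    pre_bvec: str | None = None
    post_dwi: str | None = None
    post_bval: str | None = None
    post_bvec: str | None = None
    dti_muscle_label: str | None = None
    compartments: dict[str, list[str]] | None = None
    # numeric defaults
    fascia_bin_width_mm: float = 0.05
    fascia_prune_px: int = 5
    fascia_min_samples: int = 100
    tracking: dict = field(
        default_factory=lambda: dataclasses.asdict(dti_mod.TrackingParams())
    )
    poly_order: int = 3
    # seeds, one per stochastic stage
    seeds: dict = field(default_factory=lambda: {"tracking_pre": 0, "tracking_post": 1})
    out_dir: str = "limbarch_out"


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# comparison driver
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Aggregated pre/post comparison with provenance."""

    volumes: dict | None = None
    compartments: dict | None = None
    fascia: dict | None = None
    architecture: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(stage: str, value, what: str):
    if value is None:
        raise StageError(stage, f"missing required input: {what}")
    return value


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Run the enabled stages (volumetry, fascia, dti) on a pre/post pair.

    Outputs are written under ``config.out_dir`` along with a provenance
    block (config hash, seeds, package version); rerunning with the same
    config reproduces all deterministic outputs bitwise.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = ComparisonReport(
        provenance={
            "config_hash": _config_hash(config),
            "seeds": dict(config.seeds),
            "version": __version__,
        }
    )

    if config.run_volumetry:
        t0 = time.perf_counter()
        pre = lio.load_mask(
            _require("volumetry", config.pre_mask, "pre_mask"), label_path=config.label_sidecar
        )
        post = lio.load_mask(
            _require("volumetry", config.post_mask, "post_mask"), label_path=config.label_sidecar
        )
        try:
            pre_t, post_t = vol_mod.align_stacks_by_landmark(
                pre, post, config.landmark_pre, config.landmark_post
            )
            pre_v, post_v = vol_mod.label_volumes(pre_t), vol_mod.label_volumes(post_t)
            table = vol_mod.volume_report(pre_v, post_v)
            report.volumes = {
                r["name"]: {
                    "pre_cm3": r["pre_cm3"],
                    "post_cm3": r["post_cm3"],
                    "percent_change": r["percent_change"],
                }
                for r in table.to_dict("records")
            }
            if config.compartments:
                comp = vol_mod.group_compartments(pre_v, post_v, config.compartments)
                report.compartments = {
                    r["name"]: {
                        "pre_cm3": r["pre_cm3"],
                        "post_cm3": r["post_cm3"],
                        "percent_change": r["percent_change"],
                    }
                    for r in comp.to_dict("records")
                }
            table.to_csv(out_dir / "volumes.tsv", sep="\t", index=False)
        except (ValueError, KeyError) as exc:
            raise StageError("volumetry", str(exc)) from exc
        logger.info("volumetry stage done in %.2fs", time.perf_counter() - t0)

    if config.run_fascia:
        t0 = time.perf_counter()
        try:
            pre_m = lio.load_mask(_require("fascia", config.pre_fascia_mask, "pre_fascia_mask"))
            post_m = lio.load_mask(_require("fascia", config.post_fascia_mask, "post_fascia_mask"))
            pre_map = fascia_mod.thickness_map(
                pre_m, prune_px=config.fascia_prune_px, min_samples=config.fascia_min_samples
            )
            post_map = fascia_mod.thickness_map(
                post_m, prune_px=config.fascia_prune_px, min_samples=config.fascia_min_samples
            )
            shift = fascia_mod.compare_thickness(pre_map, post_map, config.fascia_bin_width_mm)
            report.fascia = {
                "pre_mean_mm": shift.pre_mean_mm,
                "post_mean_mm": shift.post_mean_mm,
                "mean_shift_pct": shift.mean_shift_pct,
                "median_shift_pct": shift.median_shift_pct,
                "pre_algebraic_mean_mm": fascia_mod.mean_thickness_algebraic(pre_m),
                "post_algebraic_mean_mm": fascia_mod.mean_thickness_algebraic(post_m),
            }
            pre_map.samples.to_csv(out_dir / "fascia_pre_samples.tsv", sep="\t", index=False)
            post_map.samples.to_csv(out_dir / "fascia_post_samples.tsv", sep="\t", index=False)
        except (ValueError, KeyError) as exc:
            raise StageError("fascia", str(exc)) from exc
        logger.info("fascia stage done in %.2fs", time.perf_counter() - t0)

    if config.run_dti:
        t0 = time.perf_counter()
        arch = {}
        for when in ("pre", "post"):
            paths = {k: getattr(config, f"{when}_{k}") for k in ("dwi", "bval", "bvec")}
            for k, v in paths.items():
                _require("dti", v, f"{when}_{k}")
            mask_path = _require("dti", getattr(config, f"{when}_mask"), f"{when}_mask")
            try:
                stack = lio.load_dwi(paths["dwi"], paths["bval"], paths["bvec"])
                mask = lio.load_mask(mask_path, label_path=config.label_sidecar)
                label = config.dti_muscle_label
                fg = mask.binary(label)
                tfield = dti_mod.fit_tensors(stack, fg)
                params = dti_mod.TrackingParams(**config.tracking)
                tracts = dti_mod.track_fibers(
                    tfield, fg, params, seed=config.seeds.get(f"tracking_{when}", 0)
                )
                from .core import LabeledMask3D

                sub = LabeledMask3D(fg.astype(np.int16), mask.spacing, {1: label or "muscle"})
                tracts = dti_mod.extrapolate_tracts(tracts, sub, poly_order=config.poly_order)
                tracts = dti_mod.filter_tracts(
                    tracts, min_length_mm=params.min_length_mm, max_length_mm=params.max_length_mm
                )
                loa = dti_mod.line_of_action(mask, label)
                vol_cm3 = vol_mod.label_volume(mask, label) if label else (
                    np.count_nonzero(fg) * mask.voxel_volume_mm3 / 1000.0
                )
                rep = dti_mod.architecture_metrics(tracts, loa, vol_cm3, muscle=label or "muscle")
                arch[when] = dataclasses.asdict(rep)
            except (ValueError, KeyError) as exc:
                raise StageError("dti", str(exc)) from exc
        deltas = {
            k: vol_mod.percent_change(arch["pre"][k], arch["post"][k])
            for k in ("mean_fascicle_length_cm", "pcsa_cm2")
            if arch["pre"][k] > 0
        }
        deltas["mean_pennation_delta_deg"] = (
            arch["post"]["mean_pennation_deg"] - arch["pre"]["mean_pennation_deg"]
        )
        report.architecture = {**arch, "deltas": deltas}
        logger.info("dti stage done in %.2fs", time.perf_counter() - t0)

    (out_dir / "comparison_report.json").write_text(report.to_json())
    return report
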