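"""DTI stage: tensor reconstruction, FA/MD closed forms, deterministic
tracking, polynomial boundary extrapolation, the inclusion filter, line of
action, and architecture metrics against the unipennate phantom."""

import numpy as np
import pytest

from limbarch import dti, phantoms
from limbarch.core import LabeledMask3D, TensorField
from limbarch.dti import FiberTract, TrackingParams, TractSet

from conftest import MUSCLE_EVALS


def _uniform_field(direction, evals, shape=(34, 14, 14), spacing=(2.0, 2.0, 2.0),
                   box=((4, 64), (4, 24), (4, 24))):
    """Axis-aligned box mask with one tensor everywhere inside."""
    e1 = np.asarray(direction, float)
    e1 = e1 / np.linalg.norm(e1)
    # complete an orthonormal frame
    helper = np.array([0.0, 1.0, 0.0]) if abs(e1[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    D = evals[0] * np.outer(e1, e1) + evals[1] * np.outer(e2, e2) + evals[2] * np.outer(e3, e3)
    vox = np.zeros(shape, np.int16)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    inx = [(c >= lo) & (c <= hi) for c, (lo, hi) in zip(coords, box)]
    vox[np.ix_(inx[0], inx[1], inx[2])] = 1
    tensors = np.zeros((*shape, 3, 3))
    tensors[vox > 0] = D
    mask = LabeledMask3D(vox, spacing, {1: "muscle"})
    return mask, TensorField(tensors, vox > 0, spacing)


class TestFitTensors:
    def test_too_few_volumes_rejected(self):
        sig = np.ones((2, 2, 2, 5))
        g = np.vstack([np.zeros(3), np.eye(3), [[0.577, 0.577, 0.577]]])
        stack = phantoms.DWIStack(sig, g, np.array([0, 500, 500, 500, 500.0]), (1, 1, 1))
        with pytest.raises(ValueError, match="at least 7"):
            dti.fit_tensors(stack, np.ones((2, 2, 2), bool))

    def test_isotropic_offdiagonals_vanish(self):
        _, tfield = _uniform_field([0, 0, 1], (1e-3, 1e-3, 1e-3), shape=(6, 6, 6),
                                   box=((0, 12), (0, 12), (0, 12)))
        stack = phantoms.simulate_dwi(tfield, phantoms.twenty_direction_table(), 500.0)
        fitted = dti.fit_tensors(stack, tfield.valid)
        off = fitted.tensors[fitted.valid][:, [0, 0, 1], [1, 2, 2]]
        assert np.max(np.abs(off)) < 1e-9 * 1e-3

    def test_zero_signal_voxel_flagged_invalid(self):
        _, tfield = _uniform_field([0, 0, 1], MUSCLE_EVALS, shape=(6, 6, 6),
                                   box=((0, 12), (0, 12), (0, 12)))
        stack = phantoms.simulate_dwi(tfield, phantoms.twenty_direction_table(), 500.0)
        stack.signal[3, 3, 3, 5] = 0.0
        fitted = dti.fit_tensors(stack, tfield.valid)
        assert not fitted.valid[3, 3, 3]
        assert fitted.valid.sum() == tfield.valid.sum() - 1


class TestFaMd:
    def test_isotropic_fa_zero(self):
        _, tfield = _uniform_field([0, 0, 1], (1e-3, 1e-3, 1e-3), shape=(4, 4, 4),
                                   box=((0, 8), (0, 8), (0, 8)))
        fa, md = dti.fa_md(tfield)
        assert fa[tfield.valid] == pytest.approx(0.0, abs=1e-9)
        assert md[tfield.valid] == pytest.approx(1e-3, rel=1e-12)

    def test_closed_form_prolate_case(self):
        """lambda = (1.5, 0.3, 0.3)e-3: MD = 0.7e-3 and FA ~ 0.770."""
        lam = np.array([1.5e-3, 0.3e-3, 0.3e-3])
        _, tfield = _uniform_field([1, 0, 0], lam, shape=(4, 4, 4),
                                   box=((0, 8), (0, 8), (0, 8)))
        fa, md = dti.fa_md(tfield)
        mean = lam.mean()
        fa_oracle = np.sqrt(1.5) * np.sqrt(((lam - mean) ** 2).sum()) / np.sqrt((lam**2).sum())
        assert fa_oracle == pytest.approx(0.770, abs=5e-4)
        assert fa[tfield.valid] == pytest.approx(fa_oracle, rel=1e-9)
        assert md[tfield.valid] == pytest.approx(0.7e-3, rel=1e-12)

    def test_degenerate_single_axis_fa_one(self):
        tensors = np.zeros((2, 2, 2, 3, 3))
        tensors[..., 0, 0] = 1e-3
        tfield = TensorField(tensors, np.ones((2, 2, 2), bool), (1, 1, 1))
        fa, _ = dti.fa_md(tfield)
        assert fa == pytest.approx(1.0, abs=1e-12)

    def test_negative_eigenvalue_flagged(self):
        tensors = np.zeros((2, 2, 2, 3, 3))
        tensors[..., 0, 0] = 1e-3
        tensors[0, 0, 0] = np.diag([1e-3, 1e-3, -1e-4])
        fa, md = dti.fa_md(TensorField(tensors, np.ones((2, 2, 2), bool), (1, 1, 1)))
        assert np.isnan(fa[0, 0, 0]) and np.isnan(md[0, 0, 0])


class TestTrackFibers:
    def test_straight_field_spans_box(self):
        """Uniform x-directed field in a 60 mm box: every tract is the
        analytic chord through its seed, length 60 +/- 1 mm."""
        mask, tfield = _uniform_field([1, 0, 0], MUSCLE_EVALS)
        ts = dti.track_fibers(tfield, mask.binary(), TrackingParams(target_count=100), seed=7)
        assert len(ts.tracts) == 100
        for t in ts.tracts:
            assert t.raw_length == pytest.approx(60.0, abs=1.0)
            chord = t.chord_unit()
            assert abs(abs(chord[0]) - 1.0) < 1e-9

    def test_thin_mask_yields_no_tracts(self):
        """Mask thinner than the 5 mm length floor along the field."""
        mask, tfield = _uniform_field([1, 0, 0], MUSCLE_EVALS, shape=(6, 10, 10),
                                      box=((4, 7), (0, 20), (0, 20)))
        params = TrackingParams(target_count=10, max_seed_attempts=200)
        ts = dti.track_fibers(tfield, mask.binary(), params, seed=1)
        assert len(ts.tracts) == 0

    def test_seeded_determinism_bitwise(self, pennate30):
        mask, tfield, *_ = pennate30
        params = TrackingParams(target_count=50)
        a = dti.track_fibers(tfield, mask.binary(), params, seed=42)
        b = dti.track_fibers(tfield, mask.binary(), params, seed=42)
        assert len(a.tracts) == len(b.tracts)
        for ta, tb in zip(a.tracts, b.tracts):
            assert ta.points.tobytes() == tb.points.tobytes()

    def test_consecutive_point_spacing_bounded(self, pennate30):
        *_, tracts = pennate30
        step = tracts.params.step_mm
        for t in tracts.tracts:
            gaps = np.linalg.norm(np.diff(t.points, axis=0), axis=1)
            assert np.all(gaps <= 2 * step + 1e-9)


class TestExtrapolate:
    def test_interior_segment_reaches_opposing_faces(self):
        """A straight interior stub must extend to the box faces at x=4, 64."""
        mask, _ = _uniform_field([1, 0, 0], MUSCLE_EVALS)
        pts = np.stack([np.linspace(24, 44, 21), np.full(21, 14.0), np.full(21, 14.0)], axis=1)
        tract = FiberTract(points=pts, raw_length=20.0)
        out = dti.extrapolate_tract(tract, mask, max_extension_frac=2.0)
        assert out.status == "extrapolated"
        assert out.extrapolated_length == pytest.approx(60.0, abs=0.5)
        assert out.points[0, 0] == pytest.approx(4.0, abs=1.0)
        assert out.points[-1, 0] == pytest.approx(64.0, abs=1.0)

    def test_boundary_touching_tract_unchanged(self):
        mask, _ = _uniform_field([1, 0, 0], MUSCLE_EVALS)
        pts = np.stack([np.linspace(4.05, 63.95, 60), np.full(60, 14.0), np.full(60, 14.0)], axis=1)
        tract = FiberTract(points=pts, raw_length=59.9)
        out = dti.extrapolate_tract(tract, mask)
        assert out.status == "extrapolated"
        assert out.extrapolated_length <= tract.raw_length * 1.02
        assert out.extrapolated_length >= tract.raw_length

    def test_two_point_tract_rejected_short(self):
        mask, _ = _uniform_field([1, 0, 0], MUSCLE_EVALS)
        tract = FiberTract(points=np.array([[20.0, 14, 14], [30.0, 14, 14]]), raw_length=10.0)
        out = dti.extrapolate_tract(tract, mask, poly_order=3)
        assert out.status == "rejected" and out.reason == "short"

    def test_raw_never_exceeds_extrapolated(self, pennate30):
        *_, tracts = pennate30
        for t in tracts.tracts:
            if t.extrapolated_length is not None:
                assert t.extrapolated_length >= t.raw_length - 1e-9


class TestFilter:
    @staticmethod
    def _tract(raw, ext, status="extrapolated"):
        pts = np.array([[0.0, 0, 0], [ext, 0, 0]])
        return FiberTract(points=pts, raw_length=raw, extrapolated_length=ext, status=status)

    def test_under_threshold_kept(self):
        ts = dti.filter_tracts(TractSet([self._tract(10.0, 12.9)]))
        assert ts.tracts[0].status == "accepted"

    def test_over_threshold_rejected(self):
        ts = dti.filter_tracts(TractSet([self._tract(10.0, 13.1)]))
        assert ts.tracts[0].status == "rejected"
        assert ts.tracts[0].reason == "overextended"

    def test_matches_bruteforce_predicates(self):
        """Filter must equal direct application of the three predicates."""
        rng = np.random.default_rng(12)
        raws = rng.uniform(3.0, 180.0, 100)
        ratios = rng.uniform(0.95, 1.6, 100)
        tracts = [self._tract(r, r * q) for r, q in zip(raws, ratios)]
        out = dti.filter_tracts(TractSet(tracts))
        kept = {i for i, t in enumerate(out.tracts) if t.status == "accepted"}
        oracle = {
            i
            for i in range(100)
            if ratios[i] * raws[i] <= 1.3 * raws[i]
            and 5.0 <= raws[i] * ratios[i] <= 200.0
        }
        assert kept == oracle

    def test_conservation_with_single_reason(self, pennate30):
        *_, tracts = pennate30
        n_acc = len(tracts.accepted)
        n_rej = len(tracts.with_status("rejected"))
        assert n_acc + n_rej == len(tracts.tracts)
        for t in tracts.with_status("rejected"):
            assert isinstance(t.reason, str) and t.reason


class TestLineOfAction:
    @staticmethod
    def _cylinder(rot_deg=0.0):
        shape, spacing = (30, 30, 40), (1.0, 1.0, 1.0)
        from limbarch.core import voxel_center_coords

        X, Y, Z = voxel_center_coords(shape, spacing)
        c = np.radians(rot_deg)
        # rotate about y: axis direction (sin, 0, cos)
        xr = (X - 15) * np.cos(c) - (Z - 20) * np.sin(c)
        zr = (X - 15) * np.sin(c) + (Z - 20) * np.cos(c)
        inside = (xr**2 + (Y - 15) ** 2 <= 36) & (np.abs(zr) <= 18)
        return LabeledMask3D(inside.astype(np.int16), spacing, {1: "m"})

    def test_axis_aligned_cylinder(self):
        loa = dti.line_of_action(self._cylinder())
        assert np.allclose(loa, [0, 0, 1], atol=1e-6)

    def test_rotated_cylinder_within_half_degree(self):
        loa = dti.line_of_action(self._cylinder(25.0))
        expected = np.array([np.sin(np.radians(25)), 0, np.cos(np.radians(25))])
        angle = np.degrees(np.arccos(np.clip(abs(loa @ expected), 0, 1)))
        assert angle < 0.5

    def test_single_voxel_rejected(self):
        vox = np.zeros((5, 5, 5), np.int16)
        vox[2, 2, 2] = 1
        with pytest.raises(ValueError):
            dti.line_of_action(LabeledMask3D(vox, (1, 1, 1), {1: "m"}))


class TestArchitectureMetrics:
    def test_pcsa_definitional(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        tract = FiberTract(pts, 100.0, 100.0, status="accepted")
        rep = dti.architecture_metrics(TractSet([tract]), np.array([1.0, 0, 0]), 100.0)
        assert rep.pcsa_cm2 == pytest.approx(10.0)
        assert rep.mean_pennation_deg == 0.0

    def test_pcsa_identity_exact(self, pennate30):
        mask, tfield, truth, _, _, tracts = pennate30
        rep = dti.architecture_metrics(
            tracts, truth.line_of_action, truth.muscle_volume_mm3 / 1000.0
        )
        assert rep.pcsa_cm2 * rep.mean_fascicle_length_cm == pytest.approx(
            rep.volume_cm3, rel=1e-9
        )

    def test_pennate_phantom_recovery(self, pennate30):
        mask, tfield, truth, _, _, tracts = pennate30
        rep = dti.architecture_metrics(
            tracts, truth.line_of_action, truth.muscle_volume_mm3 / 1000.0
        )
        assert abs(rep.mean_pennation_deg - 30.0) < 2.0
        assert rep.mean_fascicle_length_cm * 10 == pytest.approx(
            truth.fascicle_length_mm, rel=0.05
        )

    def test_antiparallel_folds_into_range(self):
        pts = np.array([[0.0, 0, 0], [0, 0, -50.0]])
        tract = FiberTract(pts, 50.0, 50.0, status="accepted")
        rep = dti.architecture_metrics(TractSet([tract]), np.array([0.0, 0, 1.0]), 10.0)
        assert rep.mean_pennation_deg == pytest.approx(0.0, abs=1e-9)

    def test_empty_accepted_set_rejected(self):
        with pytest.raises(ValueError, match="accepted"):
            dti.architecture_metrics(TractSet([]), np.array([0.0, 0, 1.0]), 10.0)


class TestNoiseRobustness:
    def test_pennation_within_five_degrees_at_snr30(self):
        """Rician noise at SNR 30: mean pennation within 5 degrees of 30."""
        mask, tfield, truth = phantoms.make_pennate_phantom(
            (20.0, 20.0, 30.0), 30.0, MUSCLE_EVALS, (2.0, 2.0, 2.0)
        )
        g = phantoms.twenty_direction_table()
        for seed in range(5):
            stack = phantoms.simulate_dwi(tfield, g, 500.0, S0=1000.0,
                                          noise_sigma=1000.0 / 30.0, seed=seed)
            fitted = dti.fit_tensors(stack, mask.binary())
            tracts = dti.track_fibers(fitted, mask.binary(),
                                      TrackingParams(target_count=80), seed=seed)
            tracts = dti.filter_tracts(dti.extrapolate_tracts(tracts, mask))
            rep = dti.architecture_metrics(
                tracts, truth.line_of_action, truth.muscle_volume_mm3 / 1000.0
            )
            assert abs(rep.mean_pennation_deg - 30.0) < 5.0
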