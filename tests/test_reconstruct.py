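"""Reconstruction stack: kyphosis, metamer increments, spine assembly,
two-block PLS prediction and the full protocol."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thoraxgm import (KyphosisModel, ThoraxParams, VertebralBodyHeights,
                      align_case, apply_pattern, assemble_spine,
                      builtin_patterns, centroid_size, estimate_kyphosis,
                      estimate_vertebra, fit_metamer_model, fit_pls,
                      generate_sample, one_factor_sample, predict_full,
                      reconstruct_fossil, splice_preserved, tvbhd_ratio)
from thoraxgm.reconstruct import polyline_turning_angle, preserved_levels
from thoraxgm.template import VERTEBRAL_CORNERS, VERTEBRAL_LEVELS
from tests.conftest import rigid_motion


def level_points(config, lvl):
    return np.array([config[f"{lvl}_{c}"] for c in VERTEBRAL_CORNERS])


def mask_levels(config, keep_levels):
    """Mask every vertebral level not in ``keep_levels`` (keep all else)."""
    coords = config.coords.copy()
    present = config.present.copy()
    for i, lab in enumerate(config.labels):
        if lab.startswith("T") and lab.split("_")[0] not in keep_levels:
            present[i] = False
    return config.with_coords(coords, present=present)


class TestKyphosis:
    def test_heights_from_corner_points(self, clean_sample):
        configs, _ = clean_sample
        h = VertebralBodyHeights.from_config(configs[0])
        # generator uses equal anterior/posterior body heights
        assert np.allclose(h.anterior, h.posterior)
        assert tvbhd_ratio(h) == pytest.approx(1.0, abs=1e-12)

    def test_ratio_arithmetic(self):
        h = VertebralBodyHeights(np.full(12, 18.0), np.full(12, 20.0))
        assert tvbhd_ratio(h) == pytest.approx(216.0 / 240.0, abs=1e-12)

    def test_random_heights_match_sum_divide_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(15, 25, 12)
        p = rng.uniform(15, 25, 12)
        assert tvbhd_ratio(VertebralBodyHeights(a, p)) == pytest.approx(
            sum(a) / sum(p), rel=1e-12)

    def test_regression_arithmetic_and_affinity(self):
        model = KyphosisModel(0.0, 45.0)
        assert estimate_kyphosis(1.0, model) == pytest.approx(45.0)
        assert estimate_kyphosis(0.8, KyphosisModel(30.0, 0.0)) == 30.0
        a1 = estimate_kyphosis(0.7, model)
        a2 = estimate_kyphosis(1.1, model)
        mid = estimate_kyphosis(0.9, model)
        assert a1 + a2 == pytest.approx(2 * mid, abs=1e-10)

    def test_unconfigured_model_refused(self):
        with pytest.raises(ValueError, match="coefficients are required"):
            estimate_kyphosis(1.0, None)

    def test_out_of_range_angle_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            estimate_kyphosis(1.0, KyphosisModel(100.0, 10.0))


class TestMetamerModel:
    def test_exact_under_constant_increment(self, clean_sample,
                                            full_template):
        configs, _ = clean_sample
        controls = [configs[0], configs[0].with_coords(
            configs[0].coords, specimen_id="copy")]
        model = fit_metamer_model(controls, full_template)
        expected = level_points(configs[0], "T2") - \
            level_points(configs[0], "T1")
        assert np.allclose(model.increments, expected[None, :, :],
                           atol=1e-10)

    def test_single_control_gives_its_own_differences(self, small_sample,
                                                      full_template):
        configs, _ = small_sample
        model = fit_metamer_model([configs[0]], full_template)
        for l in range(11):
            expected = level_points(configs[0], f"T{l + 2}") - \
                level_points(configs[0], f"T{l + 1}")
            assert np.allclose(model.increments[l], expected, atol=1e-10)

    def test_noisy_controls_match_independent_superimposition_oracle(
            self, small_sample, full_template):
        configs, _ = small_sample
        controls = configs[:6]
        model = fit_metamer_model(controls, full_template)
        # oracle: independent form-space alignment loop (scipy rotations)
        cols = [np.concatenate([level_points(c, lvl)
                                for lvl in VERTEBRAL_LEVELS])
                for c in controls]
        X = [a - a.mean(axis=0) for a in cols]
        consensus = X[0].copy()
        for _ in range(200):
            X = [Rotation.align_vectors(consensus, a)[0].apply(a)
                 for a in X]
            new = np.mean(X, axis=0)
            if np.sqrt(((new - consensus) ** 2).mean()) < 1e-13:
                consensus = new
                break
            consensus = new
        mean = np.mean(X, axis=0).reshape(12, 4, 3)
        assert np.allclose(model.increments, np.diff(mean, axis=0),
                           atol=1e-10)

    def test_empty_control_set_rejected(self, full_template):
        with pytest.raises(ValueError, match="at least one control"):
            fit_metamer_model([], full_template)


class TestEstimateVertebra:
    def test_walk_caudal_and_cranial_exact(self, clean_sample,
                                           full_template):
        configs, _ = clean_sample
        truth = configs[0]
        model = fit_metamer_model([truth], full_template)
        delta = level_points(truth, "T2") - level_points(truth, "T1")
        partial = mask_levels(truth, {"T5"})
        est6 = estimate_vertebra(partial, 6, model, full_template)
        assert np.allclose(level_points(est6, "T6"),
                           level_points(truth, "T5") + delta, atol=1e-9)
        est4 = estimate_vertebra(partial, 4, model, full_template)
        assert np.allclose(level_points(est4, "T4"),
                           level_points(truth, "T5") - delta, atol=1e-9)

    def test_chain_recovers_ground_truth(self, clean_sample,
                                         full_template):
        configs, _ = clean_sample
        truth = configs[0]
        model = fit_metamer_model([truth], full_template)
        partial = mask_levels(truth, {"T1", "T2", "T3", "T4", "T5"})
        est = estimate_vertebra(partial, 8, model, full_template)
        assert np.allclose(level_points(est, "T8"),
                           level_points(truth, "T8"), atol=1e-8)

    def test_preserved_levels_never_overwritten(self, small_sample,
                                                full_template):
        configs, _ = small_sample
        model = fit_metamer_model(configs[:5], full_template)
        partial = mask_levels(configs[5], {"T3", "T7"})
        out = estimate_vertebra(partial, 5, model, full_template)
        assert np.array_equal(level_points(out, "T3"),
                              level_points(configs[5], "T3"))
        assert preserved_levels(out) == [3, 5, 7]

    def test_no_preserved_level_rejected(self, small_sample,
                                         full_template):
        configs, _ = small_sample
        model = fit_metamer_model(configs[:3], full_template)
        partial = mask_levels(configs[4], set())
        with pytest.raises(ValueError, match="no vertebral level"):
            estimate_vertebra(partial, 6, model, full_template)


class TestAssembleSpine:
    @staticmethod
    def toy_levels(spacing=26.0):
        base = np.array([[0, 12.5, 10], [0, 12.5, -10],
                         [0, -12.5, 10], [0, -12.5, -10]], dtype=float)
        return [base + [0, 0, -spacing * i] for i in range(12)]

    def test_zero_kyphosis_collinear_centroids(self):
        placed, pos = assemble_spine(self.toy_levels(), 0.0)
        seg = np.diff(pos, axis=0)
        assert np.abs(np.cross(seg[:-1], seg[1:])).max() < 1e-12

    @pytest.mark.parametrize("angle", [15.0, 40.0, 70.0])
    def test_turning_angle_matches_request(self, angle):
        _, pos = assemble_spine(self.toy_levels(), angle)
        assert np.rad2deg(polyline_turning_angle(pos)) == pytest.approx(
            angle, abs=1e-6)

    def test_rigid_placement_preserves_internal_distances(self):
        levels = self.toy_levels()
        placed, _ = assemble_spine(levels, 35.0)
        for L, P in zip(levels, placed):
            dL = np.linalg.norm(L[:, None] - L[None, :], axis=2)
            dP = np.linalg.norm(P[:, None] - P[None, :], axis=2)
            assert np.abs(dL - dP).max() < 1e-9

    def test_chord_spacing_preserved(self):
        _, pos = assemble_spine(self.toy_levels(24.0), 30.0)
        chords = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(chords, 24.0, atol=1e-9)

    def test_non_positive_spacing_rejected(self):
        levels = self.toy_levels()
        levels[3] = levels[2]
        with pytest.raises(ValueError, match="non-positive"):
            assemble_spine(levels, 30.0)


@pytest.fixture(scope="module")
def ohalo_partial_labels(full_template):
    pats = {p.name: p for p in builtin_patterns(full_template)}
    return tuple(sorted(pats["ohalo_2"].retained_labels,
                        key=full_template.index_of))


class TestPLS:
    def test_one_factor_recovery_of_singular_pair(self, full_template,
                                                  ohalo_partial_labels):
        configs, scores, F = one_factor_sample(
            full_template, ohalo_partial_labels, 12, seed=21)
        model = fit_pls(configs, ohalo_partial_labels)
        pidx = np.array([full_template.index_of(lab)
                         for lab in ohalo_partial_labels])
        fp = F[pidx].ravel()
        cos_u = abs(model.u1 @ (fp / np.linalg.norm(fp)))
        cos_v = abs(model.v1 @ F.ravel())
        assert cos_u > 0.9999 and cos_v > 0.9999
        assert np.linalg.norm(model.u1) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(model.v1) == pytest.approx(1.0, abs=1e-12)
        # only one latent dimension: higher singular values vanish
        assert model.singular_values[1] < 1e-8 * model.singular_values[0]

    def test_leading_pair_matches_brute_force_svd(self, full_template):
        """Six noisy specimens: compare with an explicitly formed
        cross-covariance matrix decomposed by a dense SVD."""
        params = ThoraxParams(seed=31, n_per_group=2)
        configs, _ = generate_sample(params, full_template)
        configs = configs[:6]
        labels = [lab for lab in full_template.labels
                  if lab.startswith(("rib1_", "rib2_", "T"))]
        small = [c.restrict(labels) for c in configs]
        partial = [lab for lab in labels if lab.startswith("T")]
        model = fit_pls(small, partial)
        n = len(small)
        X = model.partial_fit.aligned.reshape(n, -1)
        Y = model.full_fit.aligned.reshape(n, -1)
        C = (X - X.mean(0)).T @ (Y - Y.mean(0)) / (n - 1)
        U, S, Vt = np.linalg.svd(C)
        assert abs(model.u1 @ U[:, 0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(model.v1 @ Vt[0]) == pytest.approx(1.0, abs=1e-8)
        assert model.singular_values[0] == pytest.approx(S[0], rel=1e-8)

    def test_mean_case_predicts_mean(self, small_sample, full_template,
                                     ohalo_partial_labels):
        configs, _ = small_sample
        model = fit_pls(configs[:10], ohalo_partial_labels)
        k = len(model.partial_labels)
        from thoraxgm import LandmarkConfiguration
        case = LandmarkConfiguration(
            "mean", model.partial_labels, model.partial_fit.consensus,
            np.ones(k, dtype=bool))
        pred = predict_full(model, case)
        assert np.abs(pred.coords - model.full_fit.consensus).max() < 1e-9

    def test_noise_free_holdout_recovered(self, full_template,
                                          ohalo_partial_labels):
        configs, scores, F = one_factor_sample(
            full_template, ohalo_partial_labels, 30, seed=22)
        held, ref = configs[-1], configs[:-1]
        model = fit_pls(ref, ohalo_partial_labels)
        pats = {p.name: p for p in builtin_patterns(full_template)}
        masked = apply_pattern(held, pats["ohalo_2"])
        pred = predict_full(model, masked)
        truth = align_case(held, model.full_fit)
        rms = np.sqrt(((pred.coords - truth.coords) ** 2).mean())
        assert rms < 1e-6 * centroid_size(held)

    def test_prediction_equivariant_under_rigid_motion(
            self, small_sample, full_template, ohalo_partial_labels):
        configs, _ = small_sample
        model = fit_pls(configs[:10], ohalo_partial_labels)
        case = apply_pattern(configs[12],
                             {p.name: p for p in
                              builtin_patterns(full_template)}["ohalo_2"])
        pred = predict_full(model, case)
        rng = np.random.default_rng(13)
        moved = case.with_coords(rigid_motion(case.coords, rng),
                                 present=case.present)
        pred2 = predict_full(model, moved)
        assert np.abs(pred.coords - pred2.coords).max() < 1e-8

    def test_beats_mean_substitution_on_noisy_fossils(self, full_template,
                                                      ohalo_partial_labels):
        """Paired comparison over replicates: PLS prediction error at the
        missing landmarks stays below the reference-mean baseline."""
        pats = {p.name: p for p in builtin_patterns(full_template)}
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            params = ThoraxParams(seed=100 + rep, n_per_group=7)
            configs, _ = generate_sample(params, full_template)
            held, ref = configs[-1], configs[:-1]
            model = fit_pls(ref, ohalo_partial_labels)
            masked = apply_pattern(held, pats["ohalo_2"])
            pred = predict_full(model, masked)
            truth = align_case(held, model.full_fit)
            miss = np.array([lab not in set(ohalo_partial_labels)
                             for lab in model.full_labels])
            err_pls = np.sqrt(((pred.coords - truth.coords)[miss] ** 2
                               ).mean())
            err_mean = np.sqrt(((model.full_fit.consensus
                                 - truth.coords)[miss] ** 2).mean())
            wins += err_pls < err_mean
        assert wins >= n_rep - 1

    def test_too_few_partial_points_rejected(self, small_sample):
        configs, _ = small_sample
        with pytest.raises(ValueError, match="at least 4|coplanar"):
            fit_pls(configs[:5], ("T1_as", "T1_ai", "T1_ps"))


class TestSplice:
    def test_observed_points_exact_after_alignment(self, small_sample,
                                                   full_template,
                                                   ohalo_partial_labels):
        configs, _ = small_sample
        pats = {p.name: p for p in builtin_patterns(full_template)}
        observed = apply_pattern(configs[3], pats["ohalo_2"])
        model = fit_pls(configs[4:14], ohalo_partial_labels)
        pred = predict_full(model, observed)
        out = splice_preserved(pred, observed)
        # spliced points are a rigid motion of the observed material
        obs_labels = observed.present_labels()
        O = np.array([observed[lab] for lab in obs_labels])
        S = np.array([out[lab] for lab in obs_labels])
        dO = np.linalg.norm(O[:, None] - O[None, :], axis=2)
        dS = np.linalg.norm(S[:, None] - S[None, :], axis=2)
        assert np.abs(dO - dS).max() < 1e-8
        # unobserved points keep their predicted positions
        for lab in out.labels:
            if lab not in set(obs_labels):
                assert np.array_equal(out[lab], pred[lab])
                assert out.provenance[lab] == "pls"
            else:
                assert out.provenance[lab] == "observed"

    def test_identity_when_observed_equals_prediction(self, small_sample,
                                                      full_template):
        configs, _ = small_sample
        pred = configs[0]
        observed = apply_pattern(
            pred, {p.name: p for p in
                   builtin_patterns(full_template)}["complete"])
        out = splice_preserved(pred, observed)
        assert np.allclose(out.coords, pred.coords, atol=1e-9)

    def test_rigid_motion_case_restores_exactly(self, small_sample,
                                                full_template):
        configs, _ = small_sample
        pred = configs[0]
        rng = np.random.default_rng(17)
        moved = pred.with_coords(rigid_motion(pred.coords, rng))
        observed = apply_pattern(
            moved, {p.name: p for p in
                    builtin_patterns(full_template)}["ohalo_2"])
        out = splice_preserved(pred, observed)
        for lab in observed.present_labels():
            assert np.allclose(out[lab], pred[lab], atol=1e-8)


class TestReconstructFossil:
    def test_complete_input_passthrough(self, small_sample, full_template):
        configs, _ = small_sample
        out, report = reconstruct_fossil(configs[0], configs[1:8],
                                         configs[1:8], None,
                                         full_template)
        assert np.array_equal(out.coords, configs[0].coords)
        assert report["n_estimated"] == 0

    def test_missing_kyphosis_model_is_hard_error(self, small_sample,
                                                  full_template):
        configs, _ = small_sample
        pats = {p.name: p for p in builtin_patterns(full_template)}
        masked = apply_pattern(configs[0], pats["ohalo_2"])
        with pytest.raises(ValueError, match="kyphosis"):
            reconstruct_fossil(masked, configs[1:8], configs[1:8], None,
                               full_template)

    def test_ohalo_end_to_end_with_provenance(self, small_sample,
                                              full_template):
        configs, _ = small_sample
        pats = {p.name: p for p in builtin_patterns(full_template)}
        truth = configs[0]
        masked = apply_pattern(truth, pats["ohalo_2"])
        out, report = reconstruct_fossil(
            masked, configs[1:], configs[1:],
            KyphosisModel(10.0, 30.0), full_template)
        assert out.is_complete
        prov = report["provenance"]
        assert set(prov.values()) <= {"observed", "pls", "metamer+spine",
                                      "spine"}
        for lab in masked.present_labels():
            assert prov[lab] == "observed"
        assert report["n_estimated"] == 526 - masked.n_present
        assert 0 < report["kyphosis_deg"] < 90

    def test_error_shrinks_with_preservation(self, full_template):
        """Average reconstruction error decreases over nested masks."""
        from thoraxgm.synthetic import PreservationPattern
        from thoraxgm.procrustes import optimal_rotation
        verts = {f"T{i}" for i in (1, 2, 3, 8)}
        vert_labels = {lab for lab in full_template.labels
                       if lab.split("_")[0] in verts}

        def rib_labels(numbers):
            return {lab for lab in full_template.labels
                    if lab.startswith("rib")
                    and int(lab.split("_")[0][3:]) in numbers}

        nested = [
            PreservationPattern("few", frozenset(vert_labels
                                                 | rib_labels({1, 7}))),
            PreservationPattern("more", frozenset(
                vert_labels | rib_labels({1, 4, 7, 9, 10}))),
            PreservationPattern("most", frozenset(
                vert_labels | rib_labels(set(range(1, 11))))),
        ]
        errs = {p.name: [] for p in nested}
        for rep in range(5):
            params = ThoraxParams(seed=300 + rep, n_per_group=7)
            configs, _ = generate_sample(params, full_template)
            truth, ref = configs[-1], configs[:-1]
            for pat in nested:
                masked = apply_pattern(truth, pat)
                out, _ = reconstruct_fossil(masked, ref, ref,
                                            KyphosisModel(10.0, 30.0),
                                            full_template)
                A = out.coords - out.coords.mean(0)
                B = truth.coords - truth.coords.mean(0)
                R = optimal_rotation(A, B)
                errs[pat.name].append(np.sqrt(((A @ R - B) ** 2).mean()))
        assert np.mean(errs["most"]) < np.mean(errs["more"]) \
            < np.mean(errs["few"])
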