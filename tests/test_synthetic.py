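"""Cohort generator, session QC filter, mesh/ground-truth construction,
tractogram sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vtcwm import synthetic as syn
from vtcwm import tractogeom as tg


class TestMakeCohort:
    def test_default_cohort_size_and_group_counts(self, default_cohort):
        assert len(default_cohort) == 88
        counts = default_cohort["age_group"].value_counts()
        assert (counts["newborn"], counts["3mo"], counts["6mo"], counts["adult"]) == (
            23, 23, 21, 21,
        )

    def test_longitudinal_subjects(self, default_cohort):
        per_subject = default_cohort.groupby("subject_id").size()
        assert (per_subject > 1).sum() >= 21

    def test_ages_strictly_increase_within_subject(self, default_cohort):
        for _, grp in default_cohort.groupby("subject_id"):
            ages = grp.sort_values("session_id")["age_days"].to_numpy()
            assert np.all(np.diff(ages) > 0)

    def test_adult_ages_are_in_days(self, default_cohort):
        adults = default_cohort[default_cohort["age_group"] == "adult"]
        assert adults["age_days"].min() > 6000

    def test_one_session_per_group_gives_four_distinct_subjects(self):
        cfg = syn.CohortConfig(n_newborn=1, n_3mo=1, n_6mo=1, n_adult=1)
        coh = syn.make_cohort(cfg, seed=0)
        assert len(coh) == 4
        assert coh["subject_id"].nunique() == 4

    def test_deterministic_given_seed(self):
        a = syn.make_cohort(seed=9)
        b = syn.make_cohort(seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = syn.make_cohort(seed=10)
        assert not a["age_days"].equals(c["age_days"])

    def test_non_positive_counts_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            syn.make_cohort(syn.CohortConfig(n_newborn=0), seed=0)


class TestFilterSessions:
    def test_strict_threshold_boundary(self):
        records = pd.DataFrame(
            {"session_id": ["a", "b", "c"], "outlier_fraction": [0.002, 0.051, 0.05]}
        )
        kept = syn.filter_sessions(records, 0.05)
        assert list(kept["session_id"]) == ["a", "c"]

    def test_all_zero_fractions_retained(self):
        records = pd.DataFrame({"outlier_fraction": np.zeros(5)})
        assert len(syn.filter_sessions(records, 0.05)) == 5

    def test_zero_threshold_keeps_only_exact_zero(self):
        records = pd.DataFrame({"outlier_fraction": [0.0, 1e-9, 0.0]})
        assert len(syn.filter_sessions(records, 0.0)) == 2

    def test_threshold_outside_unit_interval_rejected(self):
        records = pd.DataFrame({"outlier_fraction": [0.0]})
        with pytest.raises(ValueError):
            syn.filter_sessions(records, 1.5)

    def test_default_cohort_passes_qc_intact(self, default_cohort):
        assert len(syn.filter_sessions(default_cohort, 0.05)) == 88


class TestMakeLabeledMesh:
    def test_default_usable_parcel_count(self, default_mesh_truth):
        mesh, truth = default_mesh_truth
        parcels = np.asarray(mesh.labels["parcel"])
        excluded = np.asarray(mesh.labels["excluded"], dtype=bool)
        for hemi in ("L", "R"):
            sel = np.asarray(mesh.labels["hemisphere"]).astype(str) == hemi
            assert np.unique(parcels[sel & ~excluded]).size == 169
        assert truth.n_retained == 169

    def test_small_config_usable_count(self):
        mesh, truth = syn.make_labeled_mesh(
            syn.MeshConfig(n_parcels=10, n_excluded=0), seed=0
        )
        parcels = np.asarray(mesh.labels["parcel"])
        assert np.unique(parcels).size == 10
        assert truth.n_retained == 10

    def test_froi_assignment_matches_standard_layout(self, default_mesh_truth):
        mesh, _ = default_mesh_truth
        froi = np.asarray(mesh.labels["froi"]).astype(str)
        hemi = np.asarray(mesh.labels["hemisphere"]).astype(str)
        present = {
            (h, f) for h, f in zip(hemi, froi) if f
        }
        left = {f for h, f in present if h == "L"}
        right = {f for h, f in present if h == "R"}
        assert left == {n for n, _, _ in syn.FROIS}
        assert right == {n for n, c, _ in syn.FROIS if c != "words"}

    def test_froi_vertex_sets_pairwise_disjoint(self, default_mesh_truth):
        mesh, _ = default_mesh_truth
        froi = np.asarray(mesh.labels["froi"]).astype(str)
        # disjoint by construction: each vertex carries at most one froi label,
        # and every labeled patch has the full patch size
        hemi = np.asarray(mesh.labels["hemisphere"]).astype(str)
        sizes = pd.Series([f"{h}_{f}" for h, f in zip(hemi, froi) if f]).value_counts()
        assert len(sizes) == 10 and (sizes == 9).all()

    def test_ground_truth_simplex_and_slope_conservation(self, default_mesh_truth):
        _, truth = default_mesh_truth
        for p in truth.mean_profile.values():
            assert abs(p.sum() - 1.0) < 1e-12 and p.min() >= 0
        for b in truth.band_props.values():
            assert abs(b.sum() - 1.0) < 1e-12
        for s in truth.age_slope.values():
            assert abs(s.sum()) < 1e-12

    def test_adjusted_profile_stays_on_simplex_across_age_range(self, default_mesh_truth):
        _, truth = default_mesh_truth
        for age in (10.0, 30.0, 200.0, 10300.0, 14000.0):
            for name, _, _ in syn.FROIS:
                p = syn.adjusted_profile(truth, name, age)
                assert abs(p.sum() - 1.0) < 1e-12 and p.min() >= 0

    def test_planted_separation_ordering(self, default_mesh_truth):
        _, truth = default_mesh_truth
        sep = syn.planted_separation(truth)
        assert sep["cytoarchitecture"] > sep["category"] > sep["age"]

    def test_ground_truth_json_round_trip(self, default_mesh_truth, tmp_path):
        _, truth = default_mesh_truth
        truth.to_json(tmp_path / "t.json")
        back = syn.GroundTruth.from_json(tmp_path / "t.json")
        for key in truth.mean_profile:
            assert np.allclose(back.mean_profile[key], truth.mean_profile[key])
        for f in truth.age_slope:
            assert np.allclose(back.age_slope[f], truth.age_slope[f])


class TestSampleTractogram:
    @pytest.fixture()
    def mesh_truth(self, default_mesh_truth):
        return default_mesh_truth

    @staticmethod
    def _target_parcels(tractogram, mesh, n_seed_parcels=11):
        """Parcel ordinal of the non-seed endpoint of every streamline."""
        parcels = np.asarray(mesh.labels["parcel"])
        ends = tractogram.endpoints()
        out = []
        for e in ends:
            # the endpoint farther from every excluded parcel is the target
            d, idx = tg.nearest_vertex(e, mesh.vertices)
            excl = np.asarray(mesh.labels["excluded"], dtype=bool)[idx]
            target = idx[~excl]
            assert target.size == 1  # exactly one endpoint in a retained parcel
            out.append(parcels[target[0]])
        return np.asarray(out)

    def test_degenerate_truth_puts_all_endpoints_in_one_parcel(self, mesh_truth):
        mesh, truth = mesh_truth
        degenerate = {k: np.zeros_like(v) for k, v in truth.mean_profile.items()}
        for v in degenerate.values():
            v[42] = 1.0
        truth2 = syn.GroundTruth(
            mean_profile=degenerate,
            age_slope={f: np.zeros_like(s) for f, s in truth.age_slope.items()},
            band_props=truth.band_props,
            effect_scales=truth.effect_scales,
            log_age_center=truth.log_age_center,
            log_age_halfrange=truth.log_age_halfrange,
            n_retained=truth.n_retained,
        )
        ses = {"age_days": 100.0}
        tr = syn.sample_tractogram(mesh, truth2, ses, n_streamlines_per_froi=10, seed=0)
        targets = self._target_parcels(tr, mesh)
        assert np.all(targets == 42 + 11)  # retained ordinal 42 -> parcel 53

    def test_even_split_within_binomial_interval(self, mesh_truth):
        mesh, truth = mesh_truth
        half = {k: np.zeros_like(v) for k, v in truth.mean_profile.items()}
        for v in half.values():
            v[10], v[20] = 0.5, 0.5
        truth2 = syn.GroundTruth(
            mean_profile=half,
            age_slope={f: np.zeros_like(s) for f, s in truth.age_slope.items()},
            band_props=truth.band_props,
            effect_scales=truth.effect_scales,
            log_age_center=truth.log_age_center,
            log_age_halfrange=truth.log_age_halfrange,
            n_retained=truth.n_retained,
        )
        rng = np.random.default_rng(2)
        counts = syn.sample_parcel_counts(truth2, "pFus-faces", 100.0, 2000, rng)
        halfwidth = 2.576 * np.sqrt(0.5 * 0.5 / 2000)
        assert abs(counts[10] / 2000 - 0.5) <= halfwidth
        assert counts[10] + counts[20] == 2000

    def test_zero_age_slope_distributions_age_invariant(self, mesh_truth):
        # newborn vs adult multinomial counts: chi-square n.s. at alpha=0.01
        # in >= 19 of 20 seeds when no age slope is planted
        _, truth = mesh_truth
        truth0 = syn.GroundTruth(
            mean_profile=truth.mean_profile,
            age_slope={f: np.zeros_like(s) for f, s in truth.age_slope.items()},
            band_props=truth.band_props,
            effect_scales=truth.effect_scales,
            log_age_center=truth.log_age_center,
            log_age_halfrange=truth.log_age_halfrange,
            n_retained=truth.n_retained,
        )
        n_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c1 = syn.sample_parcel_counts(truth0, "CoS-places", 28.0, 4000, rng)
            c2 = syn.sample_parcel_counts(truth0, "CoS-places", 10300.0, 4000, rng)
            keep = (c1 + c2) > 5
            _, p, _, _ = stats.chi2_contingency(np.vstack([c1[keep], c2[keep]]))
            n_sig += p < 0.01
        assert n_sig <= 1

    def test_deterministic_given_seed(self, mesh_truth):
        mesh, truth = mesh_truth
        ses = {"age_days": 50.0}
        t1 = syn.sample_tractogram(mesh, truth, ses, n_streamlines_per_froi=20, seed=5)
        t2 = syn.sample_tractogram(mesh, truth, ses, n_streamlines_per_froi=20, seed=5)
        assert t1.count == t2.count
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert np.array_equal(a, b)

    def test_streamline_count_and_shape(self, mesh_truth):
        mesh, truth = mesh_truth
        tr = syn.sample_tractogram(mesh, truth, {"age_days": 80.0}, 7, seed=1)
        assert tr.count == 7 * 10  # 10 fROIs
        assert all(s.shape == (3, 3) for s in tr.streamlines)

    def test_invalid_n_rejected(self, mesh_truth):
        mesh, truth = mesh_truth
        with pytest.raises(ValueError):
            syn.sample_tractogram(mesh, truth, {"age_days": 80.0}, 0, seed=1)
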