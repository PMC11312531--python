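"""Eccentricity-band counting, factorial design, post-hoc tests, mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from vtcwm import eccentricity as ecc
from vtcwm import statcore
from vtcwm import synthetic as syn
from vtcwm import tractogeom as tg


@pytest.fixture(scope="module")
def mesh_truth():
    return syn.make_labeled_mesh(syn.MeshConfig(), seed=11)


def _froi_point(mesh, froi_id):
    hemi, name = froi_id.split("_", 1)
    lab = np.asarray(mesh.labels["froi"]).astype(str)
    hem = np.asarray(mesh.labels["hemisphere"]).astype(str)
    return mesh.vertices[np.flatnonzero((lab == name) & (hem == hemi))[0]]


def _band_point(mesh, band):
    lab = np.asarray(mesh.labels["eccentricity_band"], dtype=int)
    return mesh.vertices[np.flatnonzero(lab == band)[0]]


class TestBandProfile:
    def test_all_endpoints_in_first_band(self, mesh_truth):
        mesh, _ = mesh_truth
        a = _froi_point(mesh, "L_pFus-faces")
        b = _band_point(mesh, 1)
        tr = tg.Tractogram([np.vstack([a, (a + b) / 2 + [0, 0, 30], b]) for _ in range(5)])
        prof = ecc.band_profile(tr, mesh, "L_pFus-faces")
        assert np.allclose(prof.percentages, [100.0, 0.0, 0.0])
        assert prof.total == 5

    def test_streamlines_outside_evc_not_counted(self, mesh_truth):
        mesh, _ = mesh_truth
        a = _froi_point(mesh, "L_pFus-faces")
        far = a + np.array([0.0, 1000.0, 0.0])
        tr = tg.Tractogram([np.vstack([a, far])])
        prof = ecc.band_profile(tr, mesh, "L_pFus-faces")
        assert prof.total == 0 and np.all(np.isnan(prof.percentages))

    def test_planted_band_proportions_within_multinomial_interval(self, mesh_truth):
        # session at the age where the adjusted profile equals the planted
        # mean, so the EVC-conditional proportions are exactly band_props
        mesh, truth = mesh_truth
        ses = {"age_days": float(10**truth.log_age_center)}
        tr = syn.sample_tractogram(mesh, truth, ses, n_streamlines_per_froi=10000, seed=4)
        prof = ecc.band_profile(tr, mesh, "L_pFus-faces")
        planted = truth.band_props["FG2"]
        n = prof.total
        assert n > 500
        for b in range(3):
            halfwidth = 2.576 * np.sqrt(planted[b] * (1 - planted[b]) / n)
            assert abs(prof.counts[b] / n - planted[b]) <= halfwidth

    def test_band_assignment_matches_brute_force(self, mesh_truth):
        mesh, truth = mesh_truth
        rng = np.random.default_rng(9)
        a = _froi_point(mesh, "L_CoS-places")
        band_lab = np.asarray(mesh.labels["eccentricity_band"], dtype=int)
        band_pts = mesh.vertices[band_lab > 0]
        picks = rng.choice(len(band_pts), size=30)
        tr = tg.Tractogram(
            [
                np.vstack([a, band_pts[i] + rng.uniform(-0.5, 0.5, 3) * [1, 1, 0]])
                for i in picks
            ]
        )
        prof = ecc.band_profile(tr, mesh, "L_CoS-places")
        # brute force: nearest labeled band vertex of the non-fROI endpoint
        expect = np.zeros(3, dtype=int)
        labels_nz = band_lab[band_lab > 0]
        for s in tr.streamlines:
            d = np.linalg.norm(band_pts - s[-1], axis=1)
            expect[labels_nz[np.argmin(d)] - 1] += 1
        assert np.array_equal(prof.counts, expect)

    def test_percentages_sum_to_100(self, mesh_truth):
        mesh, truth = mesh_truth
        tr = syn.sample_tractogram(mesh, truth, {"age_days": 100.0}, 2000, seed=0)
        prof = ecc.band_profile(tr, mesh, "L_mFus-faces")
        assert prof.percentages.sum() == pytest.approx(100.0, abs=1e-9)


def replica_band_table(rng=None) -> pd.DataFrame:
    """Left-hemisphere replica design: 6 fROIs x 88 sessions, random response."""
    rng = rng or np.random.default_rng(0)
    cohort = syn.make_cohort(seed=1)
    rows = []
    for _, ses in cohort.iterrows():
        for name, cat, cyto in syn.FROIS:
            rows.append(
                {
                    "froi": name,
                    "hemisphere": "L",
                    "category": cat,
                    "cytoarchitecture": cyto,
                    "subject_id": ses["subject_id"],
                    "session_id": ses["session_id"],
                    "age_days": ses["age_days"],
                    "age_group": ses["age_group"],
                    "band_0_5": float(rng.normal(50, 10)),
                }
            )
    return pd.DataFrame(rows)


class TestFactorialModel:
    def test_replica_design_degrees_of_freedom(self):
        # the fROI->(cytoarchitecture, category) assignment plus 4 age groups
        # force the df vector (2, 2, 3, 1, 6, 6, 3) with residual 504
        table = ecc.factorial_model(replica_band_table())
        df = table["df"]
        assert df["cytoarchitecture"] == 2
        assert df["category"] == 2  # places aliased with FG3
        assert df["age_group"] == 3
        assert df["cytoarchitecture:category"] == 1
        assert df["cytoarchitecture:age_group"] == 6
        assert df["category:age_group"] == 6
        assert df["cytoarchitecture:category:age_group"] == 3
        assert df["Residual"] == 504

    def test_f_matches_nested_rss_oracle(self):
        tab = replica_band_table(np.random.default_rng(3))
        out = ecc.factorial_model(tab)
        # recompute the first F by explicit nested lstsq fits
        y = tab["band_0_5"].to_numpy()
        cy = np.column_stack([(tab["cytoarchitecture"] == c).to_numpy(float)
                              for c in ("FG3", "FG4")])
        X0 = np.ones((len(y), 1))
        X1 = np.hstack([X0, cy])
        r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
        ss = r0 @ r0 - r1 @ r1
        ms_resid = out.loc["Residual", "sum_sq"] / out.loc["Residual", "df"]
        assert out.loc["cytoarchitecture", "F"] == pytest.approx(
            (ss / 2) / ms_resid, rel=1e-8
        )

    def test_eta_squared_sums_below_one(self):
        out = ecc.factorial_model(replica_band_table())
        assert out["eta_sq"].dropna().sum() <= 1.0 + 1e-12


class TestPosthocPairedT:
    def test_identical_vectors_give_zero_t_unit_p(self):
        tab = replica_band_table()
        tab.loc[tab["froi"] == "pOTS-words", "band_0_5"] = (
            tab.loc[tab["froi"] == "pFus-faces", "band_0_5"].to_numpy()
        )
        out = ecc.posthoc_paired_t(tab, pairs=[("pFus-faces", "pOTS-words")])
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p_adj"] == 1.0

    def test_session_matched_df(self):
        out = ecc.posthoc_paired_t(replica_band_table())
        assert (out["df"] == 87).all()
        assert (out["n"] == 88).all()

    def test_bonferroni_multiplication(self):
        tab = replica_band_table(np.random.default_rng(5))
        raw = statcore.paired_t(
            tab.loc[tab["froi"] == "mFus-faces", "band_0_5"].to_numpy(),
            tab.loc[tab["froi"] == "OTS-bodies", "band_0_5"].to_numpy(),
        )
        out = ecc.posthoc_paired_t(tab, pairs=[("mFus-faces", "OTS-bodies")], m=4)
        assert out.loc[0, "p_adj"] == pytest.approx(min(1.0, raw.p * 4), abs=1e-12)


class TestLmmRandomIntercept:
    @staticmethod
    def _cohort_xy(seed=0, sigma_u=3.0, sigma_e=5.0, beta=-2.75):
        cohort = syn.make_cohort(seed=1)
        rng = np.random.default_rng(seed)
        subs = cohort["subject_id"].to_numpy()
        x = np.log10(cohort["age_days"].to_numpy())
        u = {s: rng.normal(0, sigma_u) for s in np.unique(subs)}
        y = 10 + beta * x + np.array([u[s] for s in subs]) + rng.normal(0, sigma_e, len(x))
        return y, cohort["age_days"].to_numpy(), subs, x

    def test_zero_between_subject_variance_matches_ols(self):
        y, age, subs, x = self._cohort_xy(seed=1, sigma_u=0.0)
        fit = ecc.lmm_random_intercept(y, age, subs)
        ols_fit = statcore.ols(np.column_stack([np.ones_like(x), x]), y, ["c", "x"])
        if fit.boundary:
            assert fit.beta == pytest.approx(ols_fit.params["x"], abs=1e-6)
        else:
            # small positive variance estimate: slope still close to OLS
            assert fit.beta == pytest.approx(ols_fit.params["x"], abs=0.05)

    def test_matches_statsmodels_mixedlm(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        y, age, subs, x = self._cohort_xy(seed=0)
        fit = ecc.lmm_random_intercept(y, age, subs)
        m = MixedLM(y, np.column_stack([np.ones_like(x), x]), groups=subs).fit(reml=True)
        assert fit.beta == pytest.approx(m.params[1], abs=1e-3)
        assert fit.se == pytest.approx(m.bse[1], rel=1e-2)
        assert fit.sigma_e == pytest.approx(np.sqrt(m.scale), rel=1e-2)

    def test_reml_optimum_beats_grid(self):
        y, age, subs, x = self._cohort_xy(seed=2)
        fit = ecc.lmm_random_intercept(y, age, subs)
        X = np.column_stack([np.ones_like(x), x])
        gidx = [np.flatnonzero(subs == g) for g in pd.unique(pd.Series(subs))]
        grid = np.linspace(0.0, 5.0, 50)
        best_grid = min(ecc.reml_criterion(l, y, X, gidx) for l in grid)
        assert ecc.reml_criterion(fit.lam, y, X, gidx) <= best_grid + 1e-9

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            ecc.lmm_random_intercept([1.0, 2.0], [10.0, 20.0], ["a", "a"])

    def test_no_repeated_subject_rejected(self):
        with pytest.raises(ValueError, match=">= 2 sessions"):
            ecc.lmm_random_intercept([1.0, 2.0], [10.0, 20.0], ["a", "b"])
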