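"""Shared fixtures: default synthetic inputs and the full-scale cohort run.

The expensive fixtures are session-scoped and built once: the default mesh +
ground truth, the 88-session cohort, the full profile matrix and band table
produced by the real streaming pipeline at 2000 streamlines per
(fROI, session), and the three leave-one-subject-out classification results.
Fast statistical tests use the multinomial shortcut matrix instead (same
sampling law as the tractogram path, no geometry).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vtcwm import classify as clf
from vtcwm import synthetic as syn
from vtcwm.config import RunConfig
from vtcwm.pipeline import profile_stage, simulate_inputs
from vtcwm.profiles import META_COLUMNS, ProfileMatrix

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def full_run(run_config, tmp_path_factory):
    """(sessions, mesh, truth, matrix, bands) from the real pipeline."""
    outdir = tmp_path_factory.mktemp("full_run")
    sessions, mesh, truth = simulate_inputs(run_config, outdir)
    matrix, bands = profile_stage(run_config, sessions, mesh, truth, outdir)
    return sessions, mesh, truth, matrix, bands


@pytest.fixture(scope="session")
def full_matrix(full_run) -> ProfileMatrix:
    return full_run[3]


@pytest.fixture(scope="session")
def full_bands(full_run) -> pd.DataFrame:
    return full_run[4]


@pytest.fixture(scope="session")
def default_mesh_truth():
    return syn.make_labeled_mesh(syn.MeshConfig(), seed=11)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return syn.make_cohort(seed=DEFAULT_SEED)


def build_shortcut_matrix(
    truth: syn.GroundTruth,
    cohort: pd.DataFrame,
    n: int = 2000,
    seed: int = 1,
) -> ProfileMatrix:
    """Profile matrix drawn directly from the planted multinomials.

    Statistically identical to the tractogram path: the retained profile of a
    sub-bundle with n streamlines is counts/(2n) (the seed-side half of the
    endpoints lands in the excluded seed parcel).
    """
    rng = np.random.default_rng(seed)
    meta, vals = [], []
    for _, ses in cohort.iterrows():
        for froi_id in syn.froi_ids():
            hemi, name = froi_id.split("_", 1)
            counts = syn.sample_parcel_counts(truth, name, ses["age_days"], n, rng)
            meta.append(
                {
                    "froi_id": froi_id,
                    "froi": name,
                    "hemisphere": hemi,
                    "category": syn.FROI_CATEGORY[name],
                    "cytoarchitecture": syn.FROI_CYTO[name],
                    "subject_id": ses["subject_id"],
                    "session_id": ses["session_id"],
                    "age_days": float(ses["age_days"]),
                    "age_group": ses["age_group"],
                }
            )
            vals.append(counts / (2.0 * n))
    return ProfileMatrix(
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
        values=np.asarray(vals),
        parcel_names=[f"parcel_{i:03d}" for i in range(truth.n_retained)],
    )


@pytest.fixture(scope="session")
def shortcut_matrix(default_mesh_truth, default_cohort) -> ProfileMatrix:
    _, truth = default_mesh_truth
    return build_shortcut_matrix(truth, default_cohort, n=2000, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def loo_results(full_matrix) -> dict[str, clf.ClassificationResult]:
    """LOO classification of the three tasks on the full-scale matrix."""
    return {
        task: clf.loo_classify(full_matrix, task, seed=DEFAULT_SEED)
        for task in ("cytoarchitecture", "category", "age_group")
    }
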