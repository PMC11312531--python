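"""End-to-end pipeline: simulate -> extract -> profile -> classify ->
eccentricity -> develop -> report.

Each stage writes TSV/JSON outputs into a results directory and the run ends
with a manifest (config, per-stage seeds, output hashes), so a rerun with
the same config reproduces every output bit-identically.  Tractograms are
streamed one session at a time: a session's streamlines are sampled,
intersected with every fROI, reduced to profile and band rows, and dropped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import development as dev
from . import eccentricity as ecc
from . import profiles as prof
from . import synthetic as syn
from .config import RunConfig, stage_seed
from .tractogeom import save_mesh

__all__ = ["run_pipeline", "report", "simulate_inputs", "profile_stage"]


def _write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, sort_keys=True)


def simulate_inputs(config: RunConfig, outdir: Path):
    """Stage 1: cohort table, labeled mesh, planted ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = syn.make_cohort(config.cohort, seed=stage_seed(config.seed, "cohort"))
    retained = syn.filter_sessions(cohort, config.qc_threshold)
    mesh, truth = syn.make_labeled_mesh(config.mesh, seed=stage_seed(config.seed, "mesh"))
    cohort.to_csv(outdir / "sessions.tsv", sep="\t", index=False)
    retained.to_csv(outdir / "sessions_retained.tsv", sep="\t", index=False)
    save_mesh(mesh, outdir / "mesh.ply", outdir / "mesh_labels.tsv")
    truth.to_json(outdir / "ground_truth.json")
    return retained, mesh, truth


def profile_stage(config: RunConfig, sessions: pd.DataFrame, mesh, truth, outdir: Path):
    """Stage 2+3: stream per-session tractograms into profiles and band rows."""
    meta_rows, value_rows, band_rows = [], [], []
    ret = prof.retained_parcels(mesh)
    parcel_names = [f"parcel_{p:03d}" for p in ret]
    for s_idx, (_, ses) in enumerate(sessions.iterrows()):
        tr = syn.sample_tractogram(
            mesh,
            truth,
            ses,
            n_streamlines_per_froi=config.n_streamlines_per_froi,
            seed=stage_seed(config.seed, "tractogram", s_idx),
        )
        ends = tr.endpoints()
        per_froi = prof.session_profiles(mesh, tr, radius_mm=config.radius_mm,
                                         renormalize=config.renormalize_profiles)
        for froi_id, values in per_froi.items():
            hemi, name = froi_id.split("_", 1)
            common = {
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
            meta_rows.append(common)
            value_rows.append(values)
            bp = ecc.band_profile(tr, mesh, froi_id, radius_mm=config.radius_mm, endpoints=ends)
            band_rows.append(
                {
                    **common,
                    "n_evc_streamlines": bp.total,
                    **{ecc.BAND_NAMES[b]: bp.percentages[b] for b in range(3)},
                }
            )
    matrix = prof.ProfileMatrix(
        meta=pd.DataFrame(meta_rows, columns=prof.META_COLUMNS),
        values=np.asarray(value_rows),
        parcel_names=parcel_names,
    )
    bands = pd.DataFrame(band_rows)
    matrix.to_tsv(outdir / "profiles.tsv")
    bands.to_csv(outdir / "bands.tsv", sep="\t", index=False)
    return matrix, bands


def classify_stage(config: RunConfig, matrix: prof.ProfileMatrix, outdir: Path):
    results = {}
    all_preds = []
    for task in ("cytoarchitecture", "category", "age_group"):
        res = clf.loo_classify(
            matrix,
            task,
            n_components=config.n_components,
            balanced=config.balanced,
            n_resample_per_label=config.n_resample_per_label,
            seed=stage_seed(config.seed, "classify"),
            ridge=config.ridge,
        )
        res.per_session_accuracy.rename("accuracy").to_csv(
            outdir / f"accuracy_{task}.tsv", sep="\t"
        )
        res.confusion.to_csv(outdir / f"confusion_{task}.tsv", sep="\t")
        t = res.accuracy_test()
        results[task] = {
            "mean_accuracy": res.overall_mean,
            "sd_accuracy": res.overall_sd,
            "chance": res.chance,
            "t": t.t,
            "df": t.df,
            "p": t.p,
            "cohens_d": t.cohens_d,
            "ci": list(t.ci),
        }
        preds = res.predictions.copy()
        preds["task"] = task
        all_preds.append(preds)
    correctness = pd.concat(all_preds, ignore_index=True)
    ors = clf.compare_tasks(correctness)
    ors.to_csv(outdir / "task_odds_ratios.tsv", sep="\t", index=False)
    pca = clf.fit_pca(matrix.values)
    results["pca"] = {
        "n_components_elbow": pca.n_components_elbow,
        "variance_explained_top10": pca.variance_explained[:10].tolist(),
        "cumulative_top10": float(pca.variance_explained[:10].sum()),
    }
    _write_json(results, outdir / "classification.json")
    return results, correctness


def eccentricity_stage(config: RunConfig, bands: pd.DataFrame, outdir: Path):
    left = bands[bands["hemisphere"] == "L"].reset_index(drop=True)
    anova = ecc.factorial_model(left)
    anova.to_csv(outdir / "eccentricity_anova.tsv", sep="\t")
    posthoc = ecc.posthoc_paired_t(bands)
    posthoc.to_csv(outdir / "eccentricity_posthoc.tsv", sep="\t", index=False)
    lmm = {}
    for cyto in syn.CYTO_ORDER:
        sub = left[left["cytoarchitecture"] == cyto]
        fit = ecc.lmm_random_intercept(
            sub["band_0_5"].to_numpy(), sub["age_days"].to_numpy(), sub["subject_id"].to_numpy()
        )
        lmm[cyto] = {
            "beta": fit.beta, "se": fit.se, "df": fit.df, "t": fit.t, "p": fit.p,
            "ci": list(fit.ci), "sigma_u": fit.sigma_u, "sigma_e": fit.sigma_e,
            "boundary": fit.boundary,
        }
    summary = {
        "anova": {
            term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for term, row in anova.iterrows()
        },
        "central5_by_cyto": {
            c: {
                "mean": float(left.loc[left.cytoarchitecture == c, "band_0_5"].mean()),
                "sd": float(left.loc[left.cytoarchitecture == c, "band_0_5"].std(ddof=1)),
            }
            for c in syn.CYTO_ORDER
        },
        "lmm_by_cyto": lmm,
    }
    _write_json(summary, outdir / "eccentricity.json")
    return summary


def develop_stage(config: RunConfig, matrix: prof.ProfileMatrix, outdir: Path):
    froi_list = [
        f for f in syn.froi_ids() if f.startswith(config.similarity_hemisphere + "_")
    ]
    n = matrix.for_froi(froi_list[0]).n_rows
    indices = dev.bootstrap_indices(
        n, n_iter=config.n_iter, fraction=config.fraction,
        seed=stage_seed(config.seed, "bootstrap"),
    )
    boot = {}
    interaction = {}
    for froi_id in syn.froi_ids():
        sm = dev.slope_map(matrix, froi_id)
        sm.to_tsv(outdir / f"slopes_{froi_id}.tsv")
        table = dev.age_by_parcel_model(matrix, froi_id)
        interaction[froi_id] = {
            "F_parcel": float(table.loc["parcel", "F"]),
            "F_interaction": float(table.loc["log10_age:parcel", "F"]),
            "p_interaction": float(table.loc["log10_age:parcel", "p"]),
            "df_interaction": int(table.loc["log10_age:parcel", "df"]),
            "df_resid": int(table.loc["Residual", "df"]),
        }
        if froi_id in froi_list:
            boot[froi_id] = dev.bootstrap_slopes(matrix, froi_id, indices=indices)
    sim_table, sim_fit = dev.slope_similarity(boot)
    sim_table.to_csv(outdir / "slope_similarity.tsv", sep="\t", index=False)
    summary = {
        "interaction": interaction,
        "subsample_size": int(indices.shape[1]),
        "n_pairs": int(sim_table["froi_pair"].nunique()),
        "n_rows": int(len(sim_table)),
        "similarity_model": sim_fit.to_dict(),
        "mean_r_same_cyto": float(
            sim_table.loc[sim_table.same_cytoarchitecture == 1, "r"].mean()
        ),
        "mean_r_diff_cyto": float(
            sim_table.loc[sim_table.same_cytoarchitecture == 0, "r"].mean()
        ),
    }
    _write_json(summary, outdir / "development.json")
    return summary


def area_stage(matrix: prof.ProfileMatrix, mesh, outdir: Path):
    froi_areas, hemi_areas = prof.froi_surface_areas(mesh)
    meta = matrix.meta
    fa = meta["froi_id"].map(froi_areas).to_numpy(float)
    ha = meta["hemisphere"].map(hemi_areas).to_numpy(float)
    fit = prof.relative_area_model(fa, ha, meta["age_days"].to_numpy(float))
    out = fit.to_dict()
    _write_json(out, outdir / "area_model.json")
    return out


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage into ``outdir`` and write the manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    sessions, mesh, truth = simulate_inputs(config, outdir)
    matrix, bands = profile_stage(config, sessions, mesh, truth, outdir)
    classify_stage(config, matrix, outdir)
    eccentricity_stage(config, bands, outdir)
    develop_stage(config, matrix, outdir)
    area_stage(matrix, mesh, outdir)
    report(outdir)
    manifest = {
        "seed": config.seed,
        "stage_seeds": {
            "cohort": stage_seed(config.seed, "cohort"),
            "mesh": stage_seed(config.seed, "mesh"),
            "classify": stage_seed(config.seed, "classify"),
            "bootstrap": stage_seed(config.seed, "bootstrap"),
        },
        "outputs": {
            p.name: _hash_file(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return outdir


def report(outdir) -> dict:
    """Summarize a results directory into summary.json and summary.md."""
    outdir = Path(outdir)
    summary: dict = {}
    for name in ("classification", "eccentricity", "development", "area_model"):
        path = outdir / f"{name}.json"
        if path.exists():
            with open(path) as fh:
                summary[name] = json.load(fh)
    profiles_path = outdir / "profiles.tsv"
    if profiles_path.exists():
        n_rows = sum(1 for _ in open(profiles_path)) - 1
        summary["n_profiles"] = n_rows
    _write_json(summary, outdir / "summary.json")

    lines = ["# Pipeline summary", ""]
    if "n_profiles" in summary:
        lines.append(f"- connectivity profiles: {summary['n_profiles']}")
    cls = summary.get("classification", {})
    for task in ("cytoarchitecture", "category", "age_group"):
        if task in cls:
            r = cls[task]
            lines.append(
                f"- {task} LOO accuracy: {100 * r['mean_accuracy']:.1f}% "
                f"(chance {100 * r['chance']:.1f}%, t({r['df']}) = {r['t']:.2f})"
            )
    eccs = summary.get("eccentricity", {})
    if "central5_by_cyto" in eccs:
        parts = [
            f"{c}: {v['mean']:.2f}%" for c, v in eccs["central5_by_cyto"].items()
        ]
        lines.append("- central 0-5 deg connections " + ", ".join(parts))
    devs = summary.get("development", {})
    if devs:
        lines.append(
            f"- slope similarity: same-area mean r = {devs['mean_r_same_cyto']:.2f}, "
            f"different-area mean r = {devs['mean_r_diff_cyto']:.2f}"
        )
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return summary
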