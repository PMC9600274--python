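"""Baseline-vs-radiomics comparison on both regimes and both tasks.

The headline experiment: does the 95-feature panel improve out-of-bag
classification of tumor differentiation over the mean ADC / mean VE
baseline?  Runs the two-class (well vs moderate+poor) and multi-class
tasks on both pre-registered regimes at a realistic clinical cohort
scale, and writes the comparison table plus the top-5 minimal-depth
predictors of each full model.
"""

from pathlib import Path

import pandas as pd

from hcc_radiomics.study import compare_on_regime

ROOT = Path(__file__).resolve().parents[1]
SEED = 20240903


def main() -> None:
    rows, importance_rows = [], []
    for regime, n_per_class in (("mean+texture", 57), ("texture-only", 60)):
        for task in ("two_class", "multi_class"):
            comp, reports = compare_on_regime(regime, n_per_class=n_per_class,
                                              seed=SEED, task=task)
            rows.append({"regime": regime, "task": task, **{
                k: comp[k] for k in ("oob_error_baseline", "oob_error_full",
                                     "auc_baseline", "auc_full", "p_auc",
                                     "p_chi2", "n")}})
            for rank, (name, depth) in enumerate(
                    reports["full"].importance.head(5).items(), start=1):
                importance_rows.append({"regime": regime, "task": task,
                                        "rank": rank, "predictor": name,
                                        "mean_minimal_depth": depth})
            print(f"{regime} / {task} (n={comp['n']}): "
                  f"OOB error {comp['oob_error_baseline']:.3f} -> "
                  f"{comp['oob_error_full']:.3f}, "
                  f"AUC {comp['auc_baseline']:.3f} -> {comp['auc_full']:.3f} "
                  f"(DeLong p={comp['p_auc']:.3g})")

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out_dir / "model_comparison.csv", index=False)
    pd.DataFrame(importance_rows).to_csv(out_dir / "top_predictors.csv",
                                         index=False)
    print(f"\nwrote {out_dir / 'model_comparison.csv'} and top_predictors.csv")


if __name__ == "__main__":
    main()
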