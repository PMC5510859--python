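"""Run the statistical layer on the extracted feature table.

Produces the three study-style tables under results/: per-feature group
comparison (means +/- SD, KS normality, Student t-test, ANCOVA adjusted
for age/sex/volume), ROC summaries with Youden-optimal cutoffs for the
ANCOVA-significant features, and pairwise DeLong AUC comparisons with
Bonferroni correction.
"""

from pathlib import Path

import pandas as pd

from myxtex import group_comparison_table, pairwise_auc_table, roc_table
from myxtex.texture import FEATURE_NAMES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    feats_path = ROOT / "results" / "features.csv"
    if not feats_path.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    table = pd.read_csv(feats_path)
    out = ROOT / "results"

    comparison = group_comparison_table(table, list(FEATURE_NAMES))
    comparison.to_csv(out / "group_comparison.csv", index=False)
    significant = comparison.loc[comparison["adjusted_p"] < 0.05, "feature"]
    print("features significant after age/sex/volume adjustment:")
    print("  " + ", ".join(significant) if len(significant) else "  none")

    roc_features = list(significant) if len(significant) else list(FEATURE_NAMES)
    rt = roc_table(table, roc_features)
    rt.to_csv(out / "roc.csv", index=False)
    best = rt.loc[rt["auc"].idxmax()]
    print(f"best discriminator: {best['feature']} "
          f"(AUC {best['auc']:.3f}, {best['power']}; "
          f"sens {best['sensitivity_pct']:.1f}%, "
          f"spec {best['specificity_pct']:.1f}%)")

    if len(roc_features) >= 2:
        pw = pairwise_auc_table(table, roc_features)
        pw.to_csv(out / "pairwise_auc.csv", index=False)
        n_sig = (pw["bonferroni_p"] < 0.05).sum()
        print(f"pairwise AUC comparisons: {len(pw)} pairs, "
              f"{n_sig} significant after Bonferroni")


if __name__ == "__main__":
    main()
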