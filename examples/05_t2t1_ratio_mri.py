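"""T2w/T1w ratio mapping, ROI Dunnett statistics and LDA classification.

Generates aligned synthetic volume pairs (ratio decreased in GPi/SN,
increased in LPut/white matter for TT), computes per-subject ROI means,
compares genotypes with ANOVA + Dunnett (CC control) and classifies
CC vs TT from the three ROI ratios.
"""

import pandas as pd

from glycomn import (
    anova_dunnett, default_label_map, generate_cohort, generate_volume_pairs,
    lda_classify, ratio_map, roi_summary,
)

label_map = default_label_map(64)
cohort = generate_cohort({"CC": 30, "CT": 30, "TT": 30}, seed=31)
pairs, truth = generate_volume_pairs(cohort, label_map, seed=32)

ratios = {pair.subject_id: ratio_map(pair)[0] for pair in pairs}
rois = roi_summary(ratios, label_map, rois=["GPi", "SN", "LPut"])
genotypes = cohort.loc[rois.index, "genotype"]

print("mean T2w/T1w ratio by genotype:")
print(rois.groupby(genotypes).mean().round(4).to_string())

for roi in rois.columns:
    res = anova_dunnett(rois[roi], genotypes, control="CC", seed=33)
    tt = res.comparisons.loc["TT"]
    print(f"{roi:5s} ANOVA F={res.anova_F:6.2f} p={res.anova_p:.2e}  "
          f"CC-vs-TT t={tt['t']:+.2f} Dunnett p={tt['p_adjusted']:.4f}")

two = rois[genotypes.isin(["CC", "TT"])]
lda = lda_classify(two, genotypes.loc[two.index], positive="TT", loo=True)
print(f"\nLDA (GPi, SN, LPut; leave-one-out) AUC = {lda.auc:.3f}")
# The ratio drops in GPi/SN and rises in LPut for TT carriers; the three
# ROI ratios alone separate CC from TT with a high held-out AUC.
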