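"""Genotype comparison of N-glycome branching on a synthetic cohort.

Generates study-scale glycome profiles (bi-antennary up, tri-/tetra-
antennary down in carriers), aggregates them into antennarity categories
and runs the ANOVA + pairwise-Welch comparison against the CC reference.
"""

import pandas as pd

from glycomn import (
    aggregate_table, build_default_panel, generate_cohort,
    generate_glycome_profiles, group_compare,
)

panel = build_default_panel()
cohort = generate_cohort({"CC": 33, "CT": 31, "TT": 25}, seed=11)
profiles, truth = generate_glycome_profiles(cohort, panel, seed=12)

table = aggregate_table(profiles, panel)
genotypes = cohort.loc[table.index, "genotype"]
res = group_compare(
    table[["mono-antennary", "bi-antennary", "tri-antennary", "tetra-antennary"]],
    genotypes, reference="CC",
)
cols = ["mean_CC", "mean_CT", "mean_TT", "anova_p", "welch_p_CC_CT",
        "welch_p_CC_TT", "stars_CT", "stars_TT"]
with pd.option_context("display.width", 120):
    print(res[cols].round(4).to_string())
print("\nconfigured CC means:",
      {k: round(v, 2) for k, v in truth["category_means"]["CC"].items()})
# Bi-antennary rises and tri-antennary falls in CT/TT with small p-values;
# the tetra shift points down but is not sign-stable at these group sizes,
# mirroring the weak tetra signal at study scale.
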