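"""Category aggregation, monosaccharide contribution and genotype stats."""

import numpy as np
import pandas as pd
import pytest

from glycomn import (
    GlycomeProfile,
    aggregate_by_category,
    aggregate_table,
    generate_cohort,
    generate_glycome_profiles,
    group_compare,
    monosaccharide_contribution,
    paired_change_table,
    relative_change_matrix,
)
from glycomn.glycome_stats import antennarity_categories, stars
from glycomn.synthetic_cohort import GlycomeEffectConfig, generate_cdg_pair


def profile_on(panel, weights):
    ab = {n: 0.0 for n in panel.short_names}
    ab.update(weights)
    top = max(ab, key=ab.get)
    ab[top] += 100.0 - sum(ab.values())
    return GlycomeProfile(sample_id="p", abundance=ab)


# ---------------------------------------------------------------------------
# aggregation

def test_single_biantennary_species_fills_its_category(panel):
    prof = profile_on(panel, {"A2G2S2": 100.0})
    agg = aggregate_by_category(prof, panel, antennarity_categories())
    assert agg["bi-antennary"] == pytest.approx(100.0)
    assert sum(v for k, v in agg.items() if k != "bi-antennary") == 0.0


def test_antennarity_partition_sums_to_100(panel, rng):
    from conftest import random_profile

    for _ in range(5):
        prof = random_profile(panel, rng)
        agg = aggregate_by_category(prof, panel, antennarity_categories())
        assert sum(agg.values()) == pytest.approx(100.0, abs=1e-9)


def test_three_species_profile_matches_hand_summation(panel):
    # hand-built profile: 20% A2G2S2 (bi), 30% A3G3S3 (tri), 50% M5 (HM)
    prof = profile_on(panel, {"A2G2S2": 20.0, "A3G3S3": 30.0, "M5": 50.0})
    agg = aggregate_by_category(prof, panel, antennarity_categories())
    assert agg["bi-antennary"] == pytest.approx(20.0)
    assert agg["tri-antennary"] == pytest.approx(30.0)
    assert agg["high-mannose"] == pytest.approx(50.0)
    assert agg["tetra-antennary"] == 0.0


def test_unknown_profile_species_rejected(panel):
    prof = profile_on(panel, {"A2G2S2": 100.0})
    prof.abundance["NOT_A_GLYCAN"] = 0.0
    with pytest.raises(ValueError):
        aggregate_by_category(prof, panel)


# ---------------------------------------------------------------------------
# monosaccharide contribution

def test_man5_contribution_single_glycan(panel):
    prof = profile_on(panel, {"M5": 100.0})
    contrib = monosaccharide_contribution(prof, panel)
    assert contrib["GlcNAc"] == pytest.approx(100 * 2 / 7, abs=1e-9)
    assert contrib["Man"] == pytest.approx(100 * 5 / 7, abs=1e-9)
    assert contrib["Gal"] == 0.0


def test_contributions_sum_to_100(panel, rng):
    from conftest import random_profile

    prof = random_profile(panel, rng)
    for basis in ("count", "mass"):
        contrib = monosaccharide_contribution(prof, panel, basis=basis)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)


def test_mixture_contribution_is_weighted_average(panel):
    # 50/50 Man5 (2 GlcNAc / 5 Man of 7) and A2G1S1 (4 GlcNAc, 3 Man, 1 Gal,
    # 1 NeuAc of 9): hand-computed weighted average of per-glycan fractions
    prof = profile_on(panel, {"M5": 50.0, "A2G1S1": 50.0})
    contrib = monosaccharide_contribution(prof, panel)
    assert contrib["GlcNAc"] == pytest.approx(50 * 2 / 7 + 50 * 4 / 9, abs=1e-9)
    assert contrib["Man"] == pytest.approx(50 * 5 / 7 + 50 * 3 / 9, abs=1e-9)
    assert contrib["Gal"] == pytest.approx(50 * 1 / 9, abs=1e-9)
    assert contrib["NeuAc"] == pytest.approx(50 * 1 / 9, abs=1e-9)


# ---------------------------------------------------------------------------
# group comparison

def _toy_table(groups):
    rows, labels = [], []
    for gname, values in groups.items():
        for v in values:
            rows.append({"f": v})
            labels.append(gname)
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
    return df, pd.Series(labels, index=df.index)


def test_identical_groups_give_f0_p1():
    df, g = _toy_table({"CC": [5.0, 5.0, 5.0], "CT": [5.0, 5.0], "TT": [5.0, 5.0]})
    res = group_compare(df, g, reference="CC")
    assert res.loc["f", "anova_F"] == 0.0
    assert res.loc["f", "anova_p"] == 1.0
    assert res.loc["f", "welch_p_CC_CT"] == 1.0
    assert res.loc["f", "relchange_CT"] == 0.0


def test_welch_t_matches_hand_formula():
    """3-vs-3 Welch t and p recomputed from the textbook formulas."""
    a = np.array([1.0, 2.0, 3.5])
    b = np.array([2.5, 4.0, 6.0])
    df_, g = _toy_table({"CC": a, "CT": b})
    res = group_compare(df_, g, reference="CC")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / 3 + vb / 3
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    nu = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    from scipy.stats import t as tdist

    p_hand = 2 * tdist.sf(abs(t), nu)
    assert res.loc["f", "welch_p_CC_CT"] == pytest.approx(p_hand, abs=1e-10)


def test_anova_df_is_groups_minus_one():
    df, g = _toy_table({"CC": [1, 2, 3], "CT": [2, 3, 4], "TT": [3, 4, 5]})
    res = group_compare(df, g, reference="CC")
    assert res.loc["f", "anova_df"] == 2


def test_pvalues_invariant_under_nonreference_relabeling():
    rng = np.random.default_rng(5)
    df, g = _toy_table(
        {"CC": rng.normal(0, 1, 8), "CT": rng.normal(0.5, 1, 8), "TT": rng.normal(1, 1, 8)}
    )
    res1 = group_compare(df, g, reference="CC")
    swapped = g.replace({"CT": "TT", "TT": "CT"})
    res2 = group_compare(df, swapped, reference="CC")
    assert res1.loc["f", "anova_p"] == pytest.approx(res2.loc["f", "anova_p"])
    assert res1.loc["f", "welch_p_CC_CT"] == pytest.approx(res2.loc["f", "welch_p_CC_TT"])


def test_small_group_rejected():
    df, g = _toy_table({"CC": [1, 2], "CT": [3]})
    with pytest.raises(ValueError):
        group_compare(df, g, reference="CC")


def test_star_thresholds():
    assert stars(0.04) == "*" and stars(0.009) == "**" and stars(0.0009) == "***"
    assert stars(0.2) == ""


# ---------------------------------------------------------------------------
# relative change matrix

def test_relative_change_reference_column_zero_and_clipping():
    rng = np.random.default_rng(2)
    df, g = _toy_table({"CC": [1.0, 1.2, 0.8], "CT": [2.4, 2.6, 2.2]})
    res = group_compare(df, g, reference="CC")
    mat, display = relative_change_matrix(res, reference="CC")
    assert mat.loc["f", "CC"] == 0.0
    assert mat.loc["f", "CT"] > 100.0  # mean more than doubled: data retained
    assert display.loc["f", "CT"] == 50.0  # display clipped
    _, disp_abs = relative_change_matrix(res, reference="CC", kind="absolute")
    assert disp_abs.loc["f", "CT"] <= 5.0


# ---------------------------------------------------------------------------
# paired (pre/post Mn) comparison

def test_pre_equals_post_gives_zero_changes(panel):
    prof = profile_on(panel, {"A2G2S2": 60.0, "A3G3S3": 40.0})
    table = paired_change_table(prof, prof, panel=panel)
    assert (table["abs_change"] == 0).all()


def test_cdg_pair_sign_pattern_matches_injection(panel):
    """Mn supplementation reverses the CDG signature by construction."""
    pre, post = generate_cdg_pair("A", panel)
    table = paired_change_table(pre, post, panel=panel)
    assert table.loc["A2G1S1", "abs_change"] < 0  # precursor falls with Mn
    assert table.loc["tri-antennary", "abs_change"] > 0
    assert table.loc["tetra-antennary", "abs_change"] > 0
    assert table.loc["high-mannose", "abs_change"] < 0


def test_comparator_column_echoes_supplied_means(panel):
    pre, post = generate_cdg_pair("B", panel)
    comparator = {"A2G1S1": 0.439, "tri-antennary": 6.77}
    table = paired_change_table(pre, post, comparator=comparator, panel=panel)
    assert table.loc["A2G1S1", "comparator"] == 0.439
    assert table.loc["tri-antennary", "comparator"] == 6.77


# ---------------------------------------------------------------------------
# calibration and recovery under the generator

def _category_matrix(profiles, panel, categories):
    members = {c.name: c.members(panel) for c in categories}
    frame = pd.DataFrame(
        {p.sample_id: p.abundance for p in profiles}
    ).T
    return pd.DataFrame(
        {name: frame[m].sum(axis=1) for name, m in members.items()}
    )


def test_null_generator_keeps_false_positive_rate_nominal(panel):
    """No-effect config: category Welch p < 0.05 at ~5% across seeded reps."""
    cats = antennarity_categories()
    config = GlycomeEffectConfig().null()
    n_reps = 200
    hits = total = 0
    root = np.random.SeedSequence(1115)
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        cohort = generate_cohort({"CC": 30, "CT": 30, "TT": 30}, seed=rng)
        profiles, _ = generate_glycome_profiles(cohort, panel, config, seed=rng)
        table = _category_matrix(profiles, panel, cats)
        geno = pd.Series(
            [sid[:2] for sid in table.index], index=table.index
        )
        res = group_compare(table, geno, reference="CC")
        for col in ("welch_p_CC_CT", "welch_p_CC_TT"):
            hits += int((res[col] < 0.05).sum())
            total += len(res)
    rate = hits / total
    # 99% binomial band around 0.05 for the realized number of tests
    slack = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) < slack


def test_branching_effect_sign_recovered_in_95pct_of_reps(panel):
    """Configured bi-up / tri-down carrier shift is recovered at n=30/group."""
    n_reps = 20
    ok = 0
    root = np.random.SeedSequence(2226)
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        cohort = generate_cohort({"CC": 30, "CT": 30, "TT": 30}, seed=rng)
        profiles, _ = generate_glycome_profiles(cohort, panel, seed=rng)
        table = _category_matrix(profiles, panel, antennarity_categories())
        geno = pd.Series([sid[:2] for sid in table.index], index=table.index)
        res = group_compare(table, geno, reference="CC")
        signs_ok = (
            res.loc["bi-antennary", "relchange_CT"] > 0
            and res.loc["bi-antennary", "relchange_TT"] > 0
            and res.loc["tri-antennary", "relchange_CT"] < 0
            and res.loc["tri-antennary", "relchange_TT"] < 0
        )
        ok += int(signs_ok)
    assert ok >= int(np.ceil(0.95 * n_reps))


def test_category_mean_linearity(panel, rng):
    """Category mean over samples equals mean of per-sample category values."""
    from conftest import random_profile

    profiles = [random_profile(panel, rng, f"s{i}") for i in range(6)]
    table = aggregate_table(profiles, panel, antennarity_categories())
    by_sample = table.mean(axis=0)
    stacked = _category_matrix(profiles, panel, antennarity_categories()).mean(axis=0)
    for k in by_sample.index:
        assert by_sample[k] == pytest.approx(stacked[k], abs=1e-9)
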