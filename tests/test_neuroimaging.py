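"""Ratio maps, voxel-wise FDR contrasts, ROI stats, Dunnett and LDA."""

import numpy as np
import pandas as pd
import pytest

from glycomn import (
    RoiLabelMap,
    VolumePair,
    anova_dunnett,
    default_label_map,
    generate_cohort,
    generate_volume_pairs,
    lda_classify,
    ratio_map,
    roi_summary,
    voxelwise_contrast,
)
from glycomn.neuroimaging import dunnett_critical_value
from glycomn.synthetic_cohort import MriEffectConfig


def make_pair(t1, t2, mask=None, sid="s"):
    t1 = np.asarray(t1, dtype=float)
    mask = np.ones(t1.shape, bool) if mask is None else mask
    return VolumePair(t1w=t1, t2w=np.asarray(t2, dtype=float), mask=mask, subject_id=sid)


# ---------------------------------------------------------------------------
# ratio maps

def test_constant_volumes_give_constant_ratio():
    shape = (4, 4, 4)
    r, valid = ratio_map(make_pair(np.full(shape, 5.0), np.full(shape, 2.0)))
    assert np.allclose(r[valid], 0.4)


def test_global_scaling_leaves_ratio_unchanged():
    rng = np.random.default_rng(0)
    t1 = rng.uniform(500, 1500, (6, 6, 6))
    t2 = rng.uniform(100, 600, (6, 6, 6))
    r1, v1 = ratio_map(make_pair(t1, t2))
    r2, v2 = ratio_map(make_pair(t1 * 1.37, t2 * 1.37))
    assert np.allclose(r1[v1], r2[v2])


def test_zero_t1_voxels_dropped_from_mask():
    t1 = np.ones((3, 3, 3))
    t1[1, 1, 1] = 0.0
    r, valid = ratio_map(make_pair(t1, np.ones((3, 3, 3))))
    assert not valid[1, 1, 1]
    assert np.isnan(r[1, 1, 1])


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        make_pair(np.ones((3, 3, 3)), np.ones((4, 3, 3)))


# ---------------------------------------------------------------------------
# voxelwise contrast

def test_identical_groups_give_empty_significance_mask():
    rng = np.random.default_rng(1)
    vols = [rng.uniform(0.2, 0.5, (8, 8, 8)) for _ in range(4)]
    mask = np.ones((8, 8, 8), bool)
    res = voxelwise_contrast(vols, [v.copy() for v in vols], mask)
    assert not res.sig_mask.any()


def test_contrast_antisymmetry():
    rng = np.random.default_rng(2)
    a = [rng.normal(0.3, 0.02, (6, 6, 6)) for _ in range(5)]
    b = [rng.normal(0.33, 0.02, (6, 6, 6)) for _ in range(5)]
    mask = np.ones((6, 6, 6), bool)
    ab = voxelwise_contrast(a, b, mask)
    ba = voxelwise_contrast(b, a, mask)
    assert np.allclose(ab.t_map[mask], -ba.t_map[mask])
    assert np.array_equal(ab.sig_mask[mask], -ba.sig_mask[mask])


def test_group_of_one_rejected():
    mask = np.ones((4, 4, 4), bool)
    v = np.ones((4, 4, 4))
    with pytest.raises(ValueError):
        voxelwise_contrast([v], [v, v], mask)


def test_injected_gpi_decrease_found_with_negative_sign():
    """A TT-style GPi/SN ratio decrease yields a negative significant
    cluster overlapping the injected region (Dice > 0.5) at study-scale
    group sizes."""
    lm = default_label_map(64)
    cohort = generate_cohort({"CC": 45, "CT": 2, "TT": 45}, seed=31)
    pairs, _ = generate_volume_pairs(cohort, lm, seed=32)
    groups = {"CC": [], "TT": []}
    for pair in pairs:
        g = pair.subject_id[:2]
        if g in groups:
            r, _ = ratio_map(pair)
            groups[g].append(r)
    res = voxelwise_contrast(groups["TT"], groups["CC"], lm.mask)
    injected = lm.region("GPi") | lm.region("SN")
    negative = res.sig_mask == -1
    dice = 2 * (negative & injected).sum() / (negative.sum() + injected.sum())
    assert dice > 0.5
    # LPut effect is positive in TT
    pos_overlap = (res.sig_mask == 1) & lm.region("LPut")
    assert pos_overlap.sum() > 0.5 * lm.region("LPut").sum()


# ---------------------------------------------------------------------------
# ROI summaries

def test_constant_ratio_gives_constant_roi_means():
    lm = default_label_map(32)
    vol = np.full(lm.labels.shape, 0.7)
    df = roi_summary({"s1": vol}, lm)
    assert np.allclose(df.loc["s1"], 0.7)


def test_checkerboard_roi_mean_is_half():
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    labels[:2] = 1
    lm = RoiLabelMap(labels=labels, names={1: "GPi"})
    idx = np.indices((4, 4, 4)).sum(axis=0)
    vol = (idx % 2).astype(float)
    df = roi_summary({"s": vol}, lm)
    assert df.loc["s", "GPi"] == pytest.approx(0.5)


def test_three_voxel_roi_matches_hand_mean():
    labels = np.zeros((3, 3, 3), dtype=np.int16)
    labels[0, 0, 0] = labels[1, 1, 1] = labels[2, 2, 2] = 1
    lm = RoiLabelMap(labels=labels, names={1: "SN"})
    vol = np.zeros((3, 3, 3))
    vol[0, 0, 0], vol[1, 1, 1], vol[2, 2, 2] = 0.2, 0.3, 0.7
    df = roi_summary({"s": vol}, lm)
    assert df.loc["s", "SN"] == pytest.approx((0.2 + 0.3 + 0.7) / 3)


def test_roi_means_invariant_to_subject_order():
    lm = default_label_map(32)
    rng = np.random.default_rng(5)
    vols = {f"s{i}": rng.uniform(0.2, 0.5, lm.labels.shape) for i in range(4)}
    a = roi_summary(vols, lm)
    b = roi_summary(dict(reversed(list(vols.items()))), lm)
    assert a.sort_index().equals(b.sort_index())


def test_empty_roi_named_in_error():
    labels = np.zeros((3, 3, 3), dtype=np.int16)
    lm = RoiLabelMap(labels=labels, names={1: "GPi"})
    with pytest.raises(ValueError, match="GPi"):
        roi_summary({"s": np.ones((3, 3, 3))}, lm)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett

def _two_group_data(seed=8, n=11, shift=0.8):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)]))
    g = pd.Series(["CC"] * n + ["TT"] * n)
    return y, g


def test_single_comparison_reduces_to_pooled_t_test():
    from scipy.stats import ttest_ind

    y, g = _two_group_data()
    res = anova_dunnett(y, g, control="CC", seed=7)
    t_ref, p_ref = ttest_ind(y[g == "TT"], y[g == "CC"], equal_var=True)
    assert res.comparisons.loc["TT", "t"] == pytest.approx(t_ref, abs=1e-10)
    assert res.comparisons.loc["TT", "p_adjusted"] == pytest.approx(p_ref, abs=0.01)


def test_adjusted_p_never_below_unadjusted():
    rng = np.random.default_rng(9)
    y = pd.Series(rng.normal(0, 1, 30))
    g = pd.Series(["CC"] * 10 + ["CT"] * 10 + ["TT"] * 10)
    res = anova_dunnett(y, g, control="CC", seed=3)
    assert (res.comparisons["p_adjusted"] >= res.comparisons["p_unadjusted"] - 1e-12).all()


def test_dunnett_matches_scipy_oracle():
    from scipy.stats import dunnett as scipy_dunnett

    rng = np.random.default_rng(11)
    a, b, c = rng.normal(0, 1, 12), rng.normal(0.6, 1, 12), rng.normal(1.1, 1, 12)
    y = pd.Series(np.concatenate([a, b, c]))
    g = pd.Series(["CC"] * 12 + ["CT"] * 12 + ["TT"] * 12)
    mine = anova_dunnett(y, g, control="CC", seed=3)
    ref = scipy_dunnett(b, c, control=a)
    assert mine.comparisons["p_adjusted"].to_numpy() == pytest.approx(
        ref.pvalue, abs=0.01
    )


def test_dunnett_critical_value_matches_published_table():
    """Two-sided Dunnett table: k=2 comparisons, df=20, alpha=0.05 -> 2.38."""
    crit = dunnett_critical_value(7, [7, 7], alpha=0.05, draws=400_000, seed=5)
    assert crit == pytest.approx(2.38, abs=0.03)


def test_missing_control_rejected():
    y, g = _two_group_data()
    with pytest.raises(ValueError):
        anova_dunnett(y, g, control="ZZ")


def test_roi_effects_recovered_by_dunnett_at_study_scale():
    """TT-vs-CC differences in GPi/SN (down) and LPut (up) reach adjusted
    p < 0.05 with the configured signs in >= 90% of seeded reps, n=45."""
    lm = default_label_map(64)
    n_reps = 5
    ok = 0
    for child in np.random.SeedSequence(6667).spawn(n_reps):
        rng = np.random.default_rng(child)
        cohort = generate_cohort({"CC": 45, "CT": 45, "TT": 45}, seed=rng)
        pairs, truth = generate_volume_pairs(cohort, lm, seed=rng)
        ratios = {}
        for pair in pairs:
            r, _ = ratio_map(pair)
            ratios[pair.subject_id] = r
        rois = roi_summary(ratios, lm, rois=["GPi", "SN", "LPut"])
        geno = pd.Series([s[:2] for s in rois.index], index=rois.index)
        hit = True
        for roi, direction in (("GPi", -1), ("SN", -1), ("LPut", +1)):
            res = anova_dunnett(rois[roi], geno, control="CC", seed=99)
            row = res.comparisons.loc["TT"]
            hit &= row["p_adjusted"] < 0.05 and np.sign(row["t"]) == direction
        ok += int(hit)
    assert ok >= int(np.ceil(0.9 * n_reps))


# ---------------------------------------------------------------------------
# LDA

def _roi_features(seed=13, n=30, sep=3.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "GPi": np.concatenate([rng.normal(0, 1, n), rng.normal(sep, 1, n)]),
            "SN": np.concatenate([rng.normal(0, 1, n), rng.normal(sep, 1, n)]),
            "LPut": rng.normal(0, 1, 2 * n),
        }
    )
    y = pd.Series(["CC"] * n + ["TT"] * n)
    return X, y


def test_perfect_separation_gives_auc_one():
    X, y = _roi_features(sep=10.0)
    res = lda_classify(X, y, positive="TT")
    assert res.auc == 1.0


def test_auc_matches_brute_force_pair_counting():
    X, y = _roi_features(sep=1.0)
    res = lda_classify(X, y, positive="TT")
    pos = res.scores[y.to_numpy() == "TT"].to_numpy()
    neg = res.scores[y.to_numpy() == "CC"].to_numpy()
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


def test_permuted_labels_give_chance_auc():
    """Split-sample AUC under label permutation averages ~0.5.

    The discriminant is fit on one half and scored on the held-out half:
    resubstitution AUC is optimistically biased under the null and
    leave-one-out pessimistically, but held-out scoring is unbiased.
    """
    X, y = _roi_features(sep=1.5)
    rng = np.random.default_rng(17)
    half = len(y) // 2
    order = rng.permutation(len(y))
    train, test = order[:half], order[half:]
    aucs = []
    for _ in range(100):
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        fitted = lda_classify(X.iloc[train], perm.iloc[train], positive="TT")
        z = (X.iloc[test] - X.iloc[train].mean()) / X.iloc[train].std(ddof=0)
        scores = z.to_numpy() @ fitted.weights.to_numpy()
        pos = (perm.iloc[test] == "TT").to_numpy()
        if pos.all() or not pos.any():
            continue
        from scipy.stats import rankdata

        r = rankdata(scores)
        u = r[pos].sum() - pos.sum() * (pos.sum() + 1) / 2
        aucs.append(u / (pos.sum() * (~pos).sum()))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def test_loo_scores_do_not_exceed_resubstitution():
    X, y = _roi_features(sep=1.0)
    plain = lda_classify(X, y, positive="TT")
    loo = lda_classify(X, y, positive="TT", loo=True)
    assert loo.auc <= plain.auc + 0.05  # honest evaluation cannot be optimistic


def test_two_classes_required():
    X, y = _roi_features()
    with pytest.raises(ValueError):
        lda_classify(X, pd.Series(["CC"] * len(y)), positive="CC")
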