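"""Category aggregation and genotype statistics for glycome profiles.

Per-sample profiles (percent abundances over the reference panel) are
aggregated into structural categories (antennarity, class, bisection,
fucosylation, terminal residues), then compared between genotype groups
with a one-way ANOVA followed by pairwise Welch t-tests, the convention of
the underlying study design: raw p-values with star thresholds at
0.05/0.01/0.001, no multiple-testing correction across features (a
Benjamini-Hochberg column is emitted additionally for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glycan_core import GlycanPanel, StructuralAnnotation, PERMETHYLATED_RESIDUE_MASS
from .spectra import GlycomeProfile

__all__ = [
    "CategoryDefinition",
    "default_categories",
    "antennarity_categories",
    "aggregate_by_category",
    "aggregate_table",
    "monosaccharide_contribution",
    "group_compare",
    "relative_change_matrix",
    "paired_change_table",
    "stars",
]

#: display clip bounds used for heat-map scaling
RELATIVE_CLIP = 50.0
ABSOLUTE_CLIP = 5.0


@dataclass(frozen=True)
class CategoryDefinition:
    """A named structural category with a membership predicate."""

    name: str
    predicate: Callable[[StructuralAnnotation], bool]

    def members(self, panel: GlycanPanel) -> list:
        return [s.short_name for s in panel if self.predicate(s.annotation)]


def antennarity_categories() -> list:
    """Mutually exclusive antennarity/class partition covering any panel."""
    cats = [
        CategoryDefinition(
            f"{label}-antennary",
            (lambda k: lambda a: a.glycan_class == "complex" and a.antennae == k)(k),
        )
        for k, label in ((1, "mono"), (2, "bi"), (3, "tri"), (4, "tetra"))
    ]
    cats.append(CategoryDefinition("high-mannose", lambda a: a.glycan_class == "high-mannose"))
    cats.append(CategoryDefinition("hybrid", lambda a: a.glycan_class == "hybrid"))
    return cats


def default_categories() -> list:
    """Antennarity partition plus the overlapping structural categories."""
    return antennarity_categories() + [
        CategoryDefinition("bisecting", lambda a: a.bisecting),
        CategoryDefinition("core-fucosylated", lambda a: a.core_fucose > 0),
        CategoryDefinition("antenna-fucosylated", lambda a: a.antenna_fucose > 0),
        CategoryDefinition("sialylated", lambda a: a.sialyl > 0),
        CategoryDefinition("terminal-gal", lambda a: a.terminal_gal > 0),
        CategoryDefinition("terminal-glcnac", lambda a: a.terminal_glcnac > 0),
    ]


def aggregate_by_category(
    profile: GlycomeProfile,
    panel: GlycanPanel,
    categories: Sequence[CategoryDefinition] | None = None,
) -> dict:
    """Sum member-species abundances per category for one sample."""
    categories = list(categories) if categories is not None else default_categories()
    known = set(panel.short_names)
    missing = set(profile.abundance) - known
    if missing:
        raise ValueError(f"profile species not in panel: {sorted(missing)}")
    out = {}
    for cat in categories:
        members = cat.members(panel)
        unknown = set(members) - known
        if unknown:
            raise ValueError(f"category {cat.name!r} references unknown species: {sorted(unknown)}")
        out[cat.name] = float(sum(profile.abundance.get(m, 0.0) for m in members))
    return out


def aggregate_table(
    profiles: Iterable[GlycomeProfile],
    panel: GlycanPanel,
    categories: Sequence[CategoryDefinition] | None = None,
) -> pd.DataFrame:
    """Samples x categories table of aggregated percent abundances."""
    rows = {}
    for p in profiles:
        rows[p.sample_id] = aggregate_by_category(p, panel, categories)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def monosaccharide_contribution(
    profile: GlycomeProfile,
    panel: GlycanPanel,
    basis: str = "count",
    split_hex: bool = True,
) -> dict:
    """Abundance-weighted monosaccharide composition of the glycome.

    For each glycan the fractional share of every monosaccharide (by residue
    ``count``, or by permethylated residue ``mass``) is multiplied by the
    glycan's percent abundance and summed over the panel.  The pooled Hex
    count is split into Man/Gal using curated Gal labels when ``split_hex``;
    contributions sum to 100 either way.
    """
    if basis not in ("count", "mass"):
        raise ValueError("basis must be 'count' or 'mass'")
    keys = ["GlcNAc", "Man", "Gal", "Fuc", "NeuAc"] if split_hex else ["GlcNAc", "Hex", "Fuc", "NeuAc"]
    out = dict.fromkeys(keys, 0.0)
    for sp in panel:
        abund = profile.abundance.get(sp.short_name, 0.0)
        if abund == 0.0:
            continue
        c = sp.composition
        gal = min(sp.annotation.gal, c.hex)
        if split_hex:
            counts = {
                "GlcNAc": c.hexnac,
                "Man": c.hex - gal,
                "Gal": gal,
                "Fuc": c.dhex,
                "NeuAc": c.neuac,
            }
        else:
            counts = {"GlcNAc": c.hexnac, "Hex": c.hex, "Fuc": c.dhex, "NeuAc": c.neuac}
        if basis == "mass":
            w = {
                "GlcNAc": PERMETHYLATED_RESIDUE_MASS["hexnac"],
                "Man": PERMETHYLATED_RESIDUE_MASS["hex"],
                "Gal": PERMETHYLATED_RESIDUE_MASS["hex"],
                "Hex": PERMETHYLATED_RESIDUE_MASS["hex"],
                "Fuc": PERMETHYLATED_RESIDUE_MASS["dhex"],
                "NeuAc": PERMETHYLATED_RESIDUE_MASS["neuac"],
            }
            weighted = {k: counts[k] * w[k] for k in counts}
        else:
            weighted = dict(counts)
        total = sum(weighted.values())
        for k in counts:
            out[k] += abund * weighted[k] / total
    return out


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare(
    values: pd.DataFrame,
    genotypes: pd.Series | Mapping | Sequence,
    reference: str = "CC",
) -> pd.DataFrame:
    """One-way ANOVA plus pairwise Welch t-tests per feature.

    ``values`` is a samples x features table; ``genotypes`` assigns each
    sample (by index position or label) to a group.  Returns one row per
    feature with per-group mean/SEM, ANOVA F/p/df (df = groups - 1),
    pairwise two-sided Welch p-values, relative change of each group mean
    against the ``reference`` group, star annotations on the reference
    contrasts and a BH-FDR column over the per-feature ANOVA p-values.
    """
    if isinstance(genotypes, pd.Series):
        g = genotypes.reindex(values.index)
    else:
        g = pd.Series(list(genotypes), index=values.index)
    if g.isna().any():
        raise ValueError("every sample needs a genotype label")
    groups = list(dict.fromkeys(g))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent")
    counts = g.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 samples: {dict(small)}")
    # reference first, others in order of appearance
    groups = [reference] + [x for x in groups if x != reference]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]

    rows = []
    for feature in values.columns:
        col = values[feature].astype(float)
        arrays = {gr: col[g == gr].to_numpy() for gr in groups}
        if np.ptp(col.to_numpy()) == 0:
            # no variance anywhere: define F=0, p=1 rather than 0/0
            F, p_anova = 0.0, 1.0
        else:
            F, p_anova = stats.f_oneway(*arrays.values())
        row = {
            "feature": feature,
            "anova_F": float(F),
            "anova_p": float(p_anova),
            "anova_df": len(groups) - 1,
        }
        ref_mean = arrays[reference].mean()
        for gr in groups:
            a = arrays[gr]
            row[f"mean_{gr}"] = a.mean()
            row[f"sem_{gr}"] = a.std(ddof=1) / np.sqrt(len(a))
            if ref_mean != 0:
                row[f"relchange_{gr}"] = 100.0 * (a.mean() - ref_mean) / ref_mean
            else:
                row[f"relchange_{gr}"] = np.nan
        for a, b in pairs:
            if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0 and arrays[a][0] == arrays[b][0]:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            row[f"welch_p_{a}_{b}"] = float(p)
            if a == reference:
                row[f"stars_{b}"] = stars(float(p))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    out["anova_q_bh"] = multipletests(out["anova_p"].to_numpy(), method="fdr_bh")[1]
    return out


def relative_change_matrix(
    results: pd.DataFrame,
    reference: str = "CC",
    kind: str = "relative",
):
    """Feature x group matrix of change vs the reference group.

    ``kind='relative'`` uses percent change (display clip ±50); ``kind=
    'absolute'`` uses the difference of means in percentage points (display
    clip ±5).  Returns ``(matrix, display)`` where ``display`` is the
    clipped copy; data values are retained unclipped in ``matrix``.
    Features whose reference mean is zero get NaN (undefined change) in the
    relative variant.
    """
    mean_cols = [c for c in results.columns if c.startswith("mean_")]
    groups = [c[len("mean_"):] for c in mean_cols]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent from results")
    if kind == "relative":
        mat = results[[f"relchange_{g}" for g in groups]].copy()
        mat.columns = groups
        clip = RELATIVE_CLIP
    elif kind == "absolute":
        ref = results[f"mean_{reference}"]
        mat = pd.DataFrame(
            {gr: results[f"mean_{gr}"] - ref for gr in groups}, index=results.index
        )
        clip = ABSOLUTE_CLIP
    else:
        raise ValueError("kind must be 'relative' or 'absolute'")
    display = mat.clip(lower=-clip, upper=clip)
    return mat, display


def paired_change_table(
    pre: GlycomeProfile,
    post: GlycomeProfile,
    comparator: Mapping[str, float] | None = None,
    panel: GlycanPanel | None = None,
    categories: Sequence[CategoryDefinition] | None = None,
) -> pd.DataFrame:
    """Before/after/comparator table for a single supplemented subject.

    Rows are individual species, plus category aggregates when ``panel`` is
    given.  ``comparator`` is an optional reference profile (e.g. a control
    group mean), echoed unchanged.
    """
    if set(pre.abundance) != set(post.abundance):
        raise ValueError("pre and post profiles cover different panels")
    feats = {k: (pre.abundance[k], post.abundance[k]) for k in pre.abundance}
    if panel is not None:
        pre_cat = aggregate_by_category(pre, panel, categories)
        post_cat = aggregate_by_category(post, panel, categories)
        for k in pre_cat:
            feats[k] = (pre_cat[k], post_cat[k])
    rows = []
    for k, (a, b) in feats.items():
        row = {
            "feature": k,
            "pre": a,
            "post": b,
            "abs_change": b - a,
            "rel_change": 100.0 * (b - a) / a if a != 0 else np.nan,
        }
        if comparator is not None:
            row["comparator"] = comparator.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
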