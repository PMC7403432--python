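"""Seeded synthetic cohorts emulating the study's statistical structure.

The generators stand in for biobank data that cannot be redistributed.
Their defaults encode the study conditions: three rs13107325 genotype
groups (CC/CT/TT) matched on age/sex/BMI; genotype-graded serum Mn means
(0.814 / 0.732 / 0.669 μg/L) among 23 lognormal trace elements of which 7
fall below their method detection limits; glycome profiles whose
antennarity category means shift from tri-/tetra-antennary toward
bi-antennary in carriers; and T1w/T2w volume pairs whose T2w/T1w ratio is
decreased in GPi/SN and increased in lateral putamen and white matter in
TT carriers.  Every generator is bit-reproducible given (config, seed) and
returns its ground truth alongside the data so recovery tests can compare
estimates against configured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glycan_core import GlycanPanel, build_default_panel
from .neuroimaging import RoiLabelMap, VolumePair
from .spectra import GlycomeProfile
from .trace_elements import ELEMENTS, ElementPanel, compute_mdl

__all__ = [
    "GENOTYPES",
    "GlycomeEffectConfig",
    "ElementEffectConfig",
    "MriEffectConfig",
    "generate_cohort",
    "generate_glycome_profiles",
    "generate_element_panel",
    "generate_volume_pairs",
    "generate_cdg_pair",
    "default_label_map",
]

GENOTYPES = ("CC", "CT", "TT")

#: glycome assay group sizes of the study (samples with interpretable spectra)
GLYCOME_N = {"CC": 33, "CT": 31, "TT": 25}
#: serum trace-element group sizes of the study
ELEMENT_N = {"CC": 46, "CT": 46, "TT": 25}
#: MRI group sizes after scan-quality exclusions
MRI_N = {"CC": 46, "CT": 44, "TT": 43}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_cohort(
    n_per_genotype=48,
    seed: int | np.random.Generator = 0,
    age_mean: float = 55.0,
    age_sd: float = 7.5,
    bmi_mean: float = 27.0,
    bmi_sd: float = 4.0,
    jitter_sd: float = 0.5,
) -> pd.DataFrame:
    """Genotype-balanced cohort metadata matched on age/sex/BMI.

    ``n_per_genotype`` is an int (equal groups) or a mapping genotype ->
    size.  Matching is emulated by drawing one base table of age/sex/BMI
    and reusing it across genotypes with a small jitter, so group
    distributions agree by construction.
    """
    sizes = (
        dict(n_per_genotype)
        if isinstance(n_per_genotype, dict)
        else {g: int(n_per_genotype) for g in GENOTYPES}
    )
    if min(sizes.values()) < 2:
        raise ValueError("need at least 2 subjects per genotype")
    rng = _rng(seed)
    n_max = max(sizes.values())
    base_age = rng.normal(age_mean, age_sd, size=n_max)
    base_bmi = rng.normal(bmi_mean, bmi_sd, size=n_max)
    base_sex = np.where(np.arange(n_max) % 2 == 0, "F", "M")
    rows = []
    for g in GENOTYPES:
        n = sizes[g]
        age = base_age[:n] + rng.normal(0.0, jitter_sd, size=n)
        bmi = base_bmi[:n] + rng.normal(0.0, jitter_sd, size=n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{g}{i + 1:03d}",
                    "genotype": g,
                    "sex": base_sex[i],
                    "age": float(np.clip(age[i], 40.0, 70.0)),
                    "bmi": float(np.clip(bmi[i], 17.0, 45.0)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# glycome

#: antennarity-category means (percent) per genotype; CC column from the
#: study's branching table, CT/TT shifted in the reported directions.  The
#: hybrid share is not printed and is set to a small plasma-typical value.
DEFAULT_CATEGORY_MEANS = {
    "CC": {
        "mono-antennary": 1.09,
        "bi-antennary": 88.0,
        "tri-antennary": 6.77,
        "tetra-antennary": 0.574,
        "high-mannose": 3.59,
        "hybrid": 0.35,
    },
    "CT": {
        "mono-antennary": 1.09,
        "bi-antennary": 90.2,
        "tri-antennary": 4.99,
        "tetra-antennary": 0.420,
        "high-mannose": 3.59,
        "hybrid": 0.35,
    },
    "TT": {
        "mono-antennary": 1.09,
        "bi-antennary": 90.1,
        "tri-antennary": 4.91,
        "tetra-antennary": 0.457,
        "high-mannose": 3.59,
        "hybrid": 0.35,
    },
}


@dataclass(frozen=True)
class GlycomeEffectConfig:
    """Genotype-specific category means and compositional noise level.

    ``concentration`` is the Dirichlet concentration: category share
    variance is p(1-p)/(1+c), so the default c = 135 gives a bi-antennary
    group SD of ~2.8 percentage points, matching the significance pattern
    of the study at its group sizes.  ``concentration=None`` disables noise
    (every sample equals its genotype mean profile).
    """

    category_means: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_CATEGORY_MEANS.items()
    })
    concentration: float | None = 135.0

    def null(self) -> "GlycomeEffectConfig":
        """No-genotype-effect variant (all groups get the CC means)."""
        cc = dict(self.category_means["CC"])
        return replace(self, category_means={g: dict(cc) for g in self.category_means})


def species_means_from_categories(
    panel: GlycanPanel, category_means: dict, tol: float = 1.0
) -> pd.Series:
    """Scale the panel's baseline species weights to hit category means.

    Species weights within each antennarity/class category are proportional
    to the panel's curated baseline abundances; category totals match the
    configured means after normalizing the configured vector to 100 (sums
    deviating by more than ``tol`` raise).
    """
    from .glycome_stats import antennarity_categories

    total = float(sum(category_means.values()))
    if abs(total - 100.0) > tol:
        raise ValueError(f"category means must sum to ~100, got {total:.3f}")
    scale = 100.0 / total
    means = pd.Series(0.0, index=panel.short_names)
    covered = set()
    for cat in antennarity_categories():
        members = cat.members(panel)
        covered.update(members)
        if cat.name not in category_means:
            raise ValueError(f"category means missing {cat.name!r}")
        base = np.array([panel[m].baseline_percent for m in members], dtype=float)
        if base.sum() <= 0:
            base = np.ones(len(members))
        means[members] = category_means[cat.name] * scale * base / base.sum()
    uncovered = set(panel.short_names) - covered
    if uncovered:
        raise ValueError(f"species outside the antennarity partition: {sorted(uncovered)}")
    return means


def generate_glycome_profiles(
    cohort: pd.DataFrame,
    panel: GlycanPanel | None = None,
    effects: GlycomeEffectConfig | None = None,
    seed: int | np.random.Generator = 0,
):
    """Per-sample Dirichlet glycome profiles around genotype mean profiles.

    Returns ``(profiles, ground_truth)`` where ``ground_truth`` maps each
    genotype to its configured species mean vector (percent) and the
    normalized category means actually used.
    """
    panel = panel or build_default_panel()
    effects = effects or GlycomeEffectConfig()
    rng = _rng(seed)
    species_means = {
        g: species_means_from_categories(panel, effects.category_means[g])
        for g in effects.category_means
    }
    profiles = []
    for sid, row in cohort.iterrows():
        g = row["genotype"]
        if g not in species_means:
            raise ValueError(f"no category means configured for genotype {g!r}")
        mean = species_means[g].to_numpy()
        if effects.concentration is None:
            draw = mean.copy()
        else:
            alpha = effects.concentration * mean / 100.0
            # Dirichlet via independent gammas; zero-mean species stay zero
            gams = np.where(alpha > 0, rng.gamma(np.clip(alpha, 1e-12, None)), 0.0)
            if gams.sum() <= 0:
                draw = mean.copy()
            else:
                draw = 100.0 * gams / gams.sum()
        abundance = dict(zip(panel.short_names, draw))
        s = sum(abundance.values())
        if s != 100.0:  # absorb float round-off into the most abundant species
            top = max(abundance, key=abundance.get)
            abundance[top] += 100.0 - s
        profiles.append(GlycomeProfile(sample_id=str(sid), abundance=abundance))
    ground_truth = {
        "species_means": {g: m.copy() for g, m in species_means.items()},
        "category_means": {
            g: {
                k: v * 100.0 / sum(effects.category_means[g].values())
                for k, v in effects.category_means[g].items()
            }
            for g in effects.category_means
        },
    }
    return profiles, ground_truth


#: pre/post category means of the two Mn-supplemented CDG subjects
CDG_CATEGORY_MEANS = {
    "A": {
        "pre": {"mono-antennary": 1.49, "bi-antennary": 88.8, "tri-antennary": 5.48,
                "tetra-antennary": 0.46, "high-mannose": 3.76, "hybrid": 0.35},
        "post": {"mono-antennary": 1.11, "bi-antennary": 84.9, "tri-antennary": 10.8,
                 "tetra-antennary": 0.78, "high-mannose": 2.39, "hybrid": 0.35},
    },
    "B": {
        "pre": {"mono-antennary": 1.06, "bi-antennary": 87.7, "tri-antennary": 8.22,
                "tetra-antennary": 0.72, "high-mannose": 2.28, "hybrid": 0.35},
        "post": {"mono-antennary": 0.61, "bi-antennary": 82.8, "tri-antennary": 14.4,
                 "tetra-antennary": 0.89, "high-mannose": 1.31, "hybrid": 0.35},
    },
}

#: per-species anchors of the CDG subjects (percent): A2G1S1 elevated at
#: baseline and normalized with Mn; large tri-antennary species reduced at
#: baseline and restored with Mn
CDG_SPECIES_ANCHORS = {
    "A": {"pre": {"A2G1S1": 2.246, "A3G3S3": 3.25, "A3FG3S3": 0.662},
          "post": {"A2G1S1": 0.652, "A3G3S3": 8.03, "A3FG3S3": 0.725}},
    "B": {"pre": {"A2G1S1": 1.650, "A3G3S3": 2.24, "A3FG3S3": 3.81},
          "post": {"A2G1S1": 0.622, "A3G3S3": 5.71, "A3FG3S3": 6.72}},
}


def generate_cdg_pair(
    subject: str = "A",
    panel: GlycanPanel | None = None,
):
    """Noise-free pre/post-Mn profile pair for one synthetic CDG subject.

    Category means follow the supplementation response pattern (branching
    up, precursor species down after Mn); the A2G1S1 / A3G3S3 / A3FG3S3
    anchors are pinned to their tabulated values, with the remainder of
    each category rescaled to keep category totals.
    """
    panel = panel or build_default_panel()
    if subject not in CDG_CATEGORY_MEANS:
        raise ValueError(f"unknown CDG subject {subject!r}")
    out = {}
    for phase in ("pre", "post"):
        means = species_means_from_categories(panel, CDG_CATEGORY_MEANS[subject][phase])
        for name, value in CDG_SPECIES_ANCHORS[subject][phase].items():
            cat_members = [
                s.short_name
                for s in panel
                if s.annotation.glycan_class == panel[name].annotation.glycan_class
                and s.annotation.antennae == panel[name].annotation.antennae
                and s.short_name != name
            ]
            excess = means[name] - value
            means[name] = value
            sub = means[cat_members]
            if sub.sum() > 0:
                means[cat_members] = sub + excess * sub / sub.sum()
        means = means.clip(lower=0.0)
        means *= 100.0 / means.sum()
        abundance = dict(zip(means.index, means.to_numpy()))
        s = sum(abundance.values())
        top = max(abundance, key=abundance.get)
        abundance[top] += 100.0 - s
        out[phase] = GlycomeProfile(sample_id=f"CDG-{subject}-{phase}", abundance=abundance)
    return out["pre"], out["post"]


# ---------------------------------------------------------------------------
# trace elements

#: element -> (serum mean μg/L, nominal MDL μg/L).  The 16 detectable
#: elements sit well above their MDLs; Be/Cd/Ni/Pt/Te/Tl/W sit below.
DEFAULT_ELEMENT_TABLE = {
    "As": (1.5, 0.2), "Ba": (1.0, 0.15), "Co": (0.25, 0.03), "Cr": (0.5, 0.08),
    "Cs": (0.7, 0.05), "Cu": (1000.0, 5.0), "Hg": (0.6, 0.1), "Mn": (0.814, 0.2),
    "Mo": (1.0, 0.1), "Pb": (0.5, 0.08), "Sb": (0.3, 0.05), "Se": (110.0, 5.0),
    "Sn": (0.4, 0.08), "U": (0.06, 0.01), "V": (0.08, 0.015), "Zn": (900.0, 10.0),
    "Be": (0.005, 0.05), "Cd": (0.02, 0.1), "Ni": (0.3, 1.5), "Pt": (0.002, 0.02),
    "Te": (0.01, 0.08), "Tl": (0.005, 0.04), "W": (0.005, 0.05),
}

#: serum Mn genotype means (μg/L) of the study
MN_GENOTYPE_MEANS = {"CC": 0.814, "CT": 0.732, "TT": 0.669}


@dataclass(frozen=True)
class ElementEffectConfig:
    """Lognormal element panel configuration.

    Concentrations are lognormal (positive, right-skewed) with a common CV.
    The default CV of 0.225 is the within-group dispersion implied by the
    study's reported Mn ANOVA (F = 6.47 at group means 0.814/0.732/0.669
    μg/L and n = 46/46/25 gives a pooled SD of ~0.17, i.e. CV ≈ 0.225 at
    the grand mean), so the generator reproduces the significance pattern
    without hard-coding p-values.  Only Mn carries a genotype effect by
    default.
    """

    element_table: dict = field(default_factory=lambda: dict(DEFAULT_ELEMENT_TABLE))
    genotype_means: dict = field(
        default_factory=lambda: {"Mn": dict(MN_GENOTYPE_MEANS)}
    )
    cv: float = 0.225
    qc_level_factor: float = 3.0  # low-level QC concentration as multiple of MDL

    def null(self) -> "ElementEffectConfig":
        return replace(self, genotype_means={})


def generate_element_panel(
    cohort: pd.DataFrame,
    effects: ElementEffectConfig | None = None,
    seed: int | np.random.Generator = 0,
):
    """Synthesize concentrations and QC runs; MDLs come from the QC runs.

    Returns ``(panel, qc_runs, ground_truth)`` with ``ground_truth`` giving
    the configured per-element (and per-genotype for Mn) means.
    """
    effects = effects or ElementEffectConfig()
    rng = _rng(seed)
    if set(effects.element_table) != set(ELEMENTS):
        raise ValueError("element table must cover exactly the 23 panel elements")
    sigma = float(np.sqrt(np.log1p(effects.cv**2)))
    conc = {}
    truth_means = {}
    for el in ELEMENTS:
        mean, _ = effects.element_table[el]
        per_genotype = effects.genotype_means.get(el)
        vals = np.empty(len(cohort))
        for i, (sid, row) in enumerate(cohort.iterrows()):
            m = per_genotype[row["genotype"]] if per_genotype else mean
            mu = np.log(m) - sigma**2 / 2.0
            vals[i] = rng.lognormal(mu, sigma)
        conc[el] = vals
        truth_means[el] = dict(per_genotype) if per_genotype else mean
    concentrations = pd.DataFrame(conc, index=cohort.index)
    t99 = 3.142668  # t(0.99, 6); used only to size the QC spread
    qc = {}
    for el in ELEMENTS:
        _, mdl_nominal = effects.element_table[el]
        level = effects.qc_level_factor * mdl_nominal
        qc[el] = np.clip(
            rng.normal(level, mdl_nominal / t99, size=7), 0.0, None
        )
    qc_runs = pd.DataFrame(qc).T
    qc_runs.index.name = "element"
    qc_runs.columns = [f"run{i + 1}" for i in range(7)]
    panel = ElementPanel(concentrations=concentrations, mdl=compute_mdl(qc_runs))
    ground_truth = {
        "means": truth_means,
        "nominal_mdl": {el: effects.element_table[el][1] for el in ELEMENTS},
        "detectable": [
            el for el in ELEMENTS
            if effects.element_table[el][0] > effects.element_table[el][1]
        ],
    }
    return panel, qc_runs, ground_truth


# ---------------------------------------------------------------------------
# MRI volumes

#: CC-group T2w/T1w ratio per tissue; GPi/SN/LPut anchored to the study's
#: ROI means, white matter and unlabeled grey matter set to plausible levels
DEFAULT_ROI_RATIO = {"GPi": 0.279, "SN": 0.279, "LPut": 0.399, "WM": 0.30, "GM": 0.35}

#: multiplicative genotype effects on the ratio per tissue (study directions:
#: ratio down in GPi/SN, up in LPut and diffusely in white matter in TT;
#: same directions at roughly half strength in CT)
DEFAULT_ROI_EFFECTS = {
    "GPi": {"CC": 1.0, "CT": 0.273 / 0.279, "TT": 0.253 / 0.279},
    "SN": {"CC": 1.0, "CT": 0.275 / 0.279, "TT": 0.265 / 0.279},
    "LPut": {"CC": 1.0, "CT": 0.406 / 0.399, "TT": 0.423 / 0.399},
    "WM": {"CC": 1.0, "CT": 1.01, "TT": 1.02},
    "GM": {"CC": 1.0, "CT": 1.0, "TT": 1.0},
}


@dataclass(frozen=True)
class MriEffectConfig:
    """Ratio levels, genotype effects and noise for the volume generator.

    ``subject_sd`` is the between-subject log-SD of each tissue's ratio.
    The default 0.06 is calibrated to the study's reported post-hoc
    significance pattern: its smallest printed ROI contrast (SN, CC vs TT
    difference 0.014 at p = 0.0008, n = 46/43) implies a within-group SD of
    ~0.017, i.e. ~6% of the ratio level.  (The study's printed ROI SDs of
    ~0.03 are not jointly consistent with those p-values; the significance
    pattern is what the generator is meant to reproduce.)
    ``voxel_noise_frac`` is the white voxel noise SD as a fraction of
    tissue intensity; ``scale_range`` is the per-subject global intensity
    scale applied to BOTH images, which the ratio cancels.
    """

    roi_ratio: dict = field(default_factory=lambda: dict(DEFAULT_ROI_RATIO))
    roi_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ROI_EFFECTS.items()
    })
    subject_sd: float = 0.06
    voxel_noise_frac: float = 0.02
    scale_range: tuple = (0.8, 1.2)
    t1_intensity: float = 1000.0

    def null(self) -> "MriEffectConfig":
        return replace(
            self,
            roi_effects={k: {g: 1.0 for g in v} for k, v in self.roi_effects.items()},
        )


def default_label_map(shape: int = 64) -> RoiLabelMap:
    """Schematic 3-D label map: brain mask with GPi/SN/LPut/WM regions.

    Geometry is deliberately toy-scale (paired blobs on a spherical brain),
    not anatomical; radii scale with ``shape``.
    """
    n = int(shape)
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")

    def sphere(center, radius):
        return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2

    s = n / 64.0
    brain = sphere((c, c, c), 28 * s)
    labels = np.zeros((n, n, n), dtype=np.int16)
    wm = sphere((c, c, c), 17 * s)
    labels[wm] = 4
    for dx in (-10 * s, 10 * s):
        labels[sphere((c, c + 2 * s, c + dx), 4 * s)] = 1  # GPi
        labels[sphere((c - 8 * s, c - 6 * s, c + 0.7 * dx), 3 * s)] = 2  # SN
        labels[sphere((c, c + 4 * s, c + 1.45 * dx), 4.5 * s)] = 3  # LPut
    labels[~brain] = 0
    lm = RoiLabelMap(labels=labels, names={1: "GPi", 2: "SN", 3: "LPut", 4: "WM"})
    lm.mask = brain
    return lm


def generate_volume_pairs(
    cohort: pd.DataFrame,
    label_map: RoiLabelMap | None = None,
    effects: MriEffectConfig | None = None,
    seed: int | np.random.Generator = 0,
):
    """Yield one aligned VolumePair per subject plus the ground truth.

    Returns ``(pairs_iterator, ground_truth)``; the iterator is lazy so a
    full cohort of volumes never needs to sit in memory at once.
    ``ground_truth`` maps genotype -> expected ROI ratio mean.
    """
    label_map = label_map or default_label_map()
    effects = effects or MriEffectConfig()
    mask = getattr(label_map, "mask", None)
    if mask is None:
        mask = label_map.labels > 0
    regions = {"GM": mask & (label_map.labels == 0)}
    for lid, name in label_map.names.items():
        regions[name] = label_map.labels == lid
    for roi in effects.roi_effects:
        if roi not in regions:
            raise ValueError(f"label map missing configured ROI {roi!r}")
        if roi != "GM" and not regions[roi].any():
            raise ValueError(f"label map missing configured ROI {roi!r}")
    ground_truth = {
        g: {
            roi: effects.roi_ratio[roi] * effects.roi_effects[roi][g]
            for roi in effects.roi_ratio
        }
        for g in GENOTYPES
    }

    def pairs():
        rng = _rng(seed)
        t1_base = np.zeros(label_map.labels.shape)
        t1_base[mask] = effects.t1_intensity
        for sid, row in cohort.iterrows():
            g = row["genotype"]
            ratio_field = np.zeros_like(t1_base)
            for roi, reg in regions.items():
                level = effects.roi_ratio[roi] * effects.roi_effects[roi][g]
                subject_shift = (
                    np.exp(rng.normal(0.0, effects.subject_sd))
                    if effects.subject_sd > 0
                    else 1.0
                )
                ratio_field[reg] = level * subject_shift
            scale = rng.uniform(*effects.scale_range)
            noise1 = rng.normal(0.0, effects.voxel_noise_frac, size=t1_base.shape)
            noise2 = rng.normal(0.0, effects.voxel_noise_frac, size=t1_base.shape)
            t1w = np.clip(t1_base * (1.0 + noise1), 0.0, None) * scale
            t2w = np.clip(ratio_field * t1_base * (1.0 + noise2), 0.0, None) * scale
            yield VolumePair(t1w=t1w, t2w=t2w, mask=mask.copy(), subject_id=str(sid))

    return pairs(), ground_truth
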