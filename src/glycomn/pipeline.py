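"""End-to-end runs: simulate/load, analyze, and write tidy report tables.

Each stage is deterministic given (config, seed): the glycome stage emits a
per-glycan table (with a top-20-by-abundance view), a category table, the
relative-change heat-map matrix and star-annotated statistics; the element
stage emits the 23-row MDL audit plus genotype statistics; the MRI stage
emits ROI summaries, the ANOVA/Dunnett table with CC control and the LDA
classification report.  Every CSV carries a header comment naming units and
the generating module version, and the resolved configuration is written
next to the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glycan_core import build_default_panel
from .glycome_stats import (
    aggregate_table,
    default_categories,
    group_compare,
    relative_change_matrix,
)
from .neuroimaging import anova_dunnett, lda_classify, ratio_map, roi_summary, voxelwise_contrast
from .spectra import (
    SynthesisParams,
    annotate,
    frame_to_profiles,
    normalize,
    pick_peaks,
    profiles_to_frame,
    synthesize_spectrum,
)
from .synthetic_cohort import (
    ELEMENT_N,
    GLYCOME_N,
    MRI_N,
    ElementEffectConfig,
    GlycomeEffectConfig,
    MriEffectConfig,
    default_label_map,
    generate_cohort,
    generate_element_panel,
    generate_glycome_profiles,
    generate_volume_pairs,
)
from .trace_elements import element_genotype_stats, filter_elements

__all__ = ["RunConfig", "run_glycome", "run_elements", "run_mri", "run_all"]

log = logging.getLogger("glycomn")


@dataclass
class RunConfig:
    """Serializable run configuration shared by all stages."""

    seed: int = 0
    out_dir: str = "glycomn-out"
    reference: str = "CC"
    # glycome stage
    glycome_n: dict = field(default_factory=lambda: dict(GLYCOME_N))
    via_spectra: bool = True
    # element stage
    element_n: dict = field(default_factory=lambda: dict(ELEMENT_N))
    # MRI stage
    mri_n: dict = field(default_factory=lambda: dict(MRI_N))
    grid: int = 64
    # optional external inputs (CSV paths); when unset, stages simulate
    profiles_csv: str | None = None
    metadata_csv: str | None = None
    elements_csv: str | None = None
    qc_csv: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


def _write_csv(df: pd.DataFrame, path: Path, units: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# glycomn v{__version__}; units: {units}\n")
        df.to_csv(fh)


def _prepare(config: RunConfig, stage: str):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(config.to_yaml())
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("stage=%s seed=%d out=%s", stage, config.seed, out)
    return out, handler


def _seed_for(config: RunConfig, stage: str) -> np.random.Generator:
    stages = {"cohort": 0, "glycome": 1, "elements": 2, "mri": 3}
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[stages[stage]])


def profiles_through_spectra(profiles, panel, params: SynthesisParams, seed) -> list:
    """Round every profile through synthesize -> pick -> annotate -> normalize."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for p in profiles:
        spec = synthesize_spectrum(p, panel, params, seed=rng)
        peaks = pick_peaks(spec)
        heights, _ = annotate(peaks, panel)
        out.append(normalize(heights, sample_id=p.sample_id))
    return out


def run_glycome(config: RunConfig):
    """Glycome stage: profiles -> per-glycan, category and heat-map tables."""
    out, handler = _prepare(config, "glycome")
    try:
        panel = build_default_panel()
        if config.profiles_csv:
            profiles = frame_to_profiles(
                pd.read_csv(config.profiles_csv, comment="#")
            )
            metadata = pd.read_csv(config.metadata_csv, comment="#", index_col=0)
            orphans = [p.sample_id for p in profiles if p.sample_id not in metadata.index]
            if orphans:
                raise ValueError(f"profiles without metadata rows: {orphans}")
        else:
            cohort = generate_cohort(config.glycome_n, seed=_seed_for(config, "cohort"))
            rng = _seed_for(config, "glycome")
            profiles, _ = generate_glycome_profiles(cohort, panel, seed=rng)
            if config.via_spectra:
                profiles = profiles_through_spectra(profiles, panel, SynthesisParams(), rng)
            metadata = cohort
        genotypes = metadata.loc[[p.sample_id for p in profiles], "genotype"]

        per_glycan = profiles_to_frame(profiles).pivot(
            index="sample_id", columns="short_name", values="percent"
        )
        per_glycan_stats = group_compare(per_glycan, genotypes, reference=config.reference)
        order = per_glycan_stats[f"mean_{config.reference}"].sort_values(ascending=False).index
        per_glycan_stats = per_glycan_stats.loc[order]
        categories = aggregate_table(profiles, panel)
        category_stats = group_compare(categories, genotypes, reference=config.reference)
        heat, heat_display = relative_change_matrix(per_glycan_stats, config.reference)

        _write_csv(per_glycan_stats, out / "per_glycan_stats.csv", "percent abundance")
        _write_csv(per_glycan_stats.head(20), out / "per_glycan_top20.csv", "percent abundance")
        _write_csv(category_stats, out / "category_stats.csv", "percent abundance")
        _write_csv(heat, out / "heatmap_relative_change.csv", "percent change vs reference")
        _write_csv(
            heat_display, out / "heatmap_relative_change_display.csv",
            "percent change vs reference, clipped to +/-50",
        )
        log.info("glycome stage done: %d samples, %d glycans", len(profiles), per_glycan.shape[1])
        return {"per_glycan": per_glycan_stats, "categories": category_stats, "heatmap": heat}
    finally:
        log.removeHandler(handler)
        handler.close()


def run_elements(config: RunConfig):
    """Element stage: panel + QC -> 23-row audit and genotype statistics."""
    out, handler = _prepare(config, "elements")
    try:
        if config.elements_csv:
            conc = pd.read_csv(config.elements_csv, comment="#", index_col=0)
            qc = pd.read_csv(config.qc_csv, comment="#", index_col=0)
            metadata = pd.read_csv(config.metadata_csv, comment="#", index_col=0)
            from .trace_elements import ElementPanel, compute_mdl

            panel = ElementPanel(concentrations=conc, mdl=compute_mdl(qc))
        else:
            cohort = generate_cohort(config.element_n, seed=_seed_for(config, "cohort"))
            panel, qc, _ = generate_element_panel(cohort, seed=_seed_for(config, "elements"))
            metadata = cohort
        included, excluded, audit = filter_elements(panel)
        genotypes = metadata.loc[panel.concentrations.index, "genotype"]
        stats_table = element_genotype_stats(panel, genotypes, reference=config.reference)
        _write_csv(audit, out / "element_audit.csv", "ug/L")
        _write_csv(stats_table, out / "element_stats.csv", "ug/L")
        log.info("element stage done: %d included / %d excluded", len(included), len(excluded))
        return {"audit": audit, "stats": stats_table, "included": included, "excluded": excluded}
    finally:
        log.removeHandler(handler)
        handler.close()


def run_mri(config: RunConfig):
    """MRI stage: ratio maps -> ROI table, ANOVA/Dunnett and LDA report."""
    out, handler = _prepare(config, "mri")
    try:
        cohort = generate_cohort(config.mri_n, seed=_seed_for(config, "cohort"))
        label_map = default_label_map(config.grid)
        pairs, truth = generate_volume_pairs(
            cohort, label_map, seed=_seed_for(config, "mri")
        )
        ratios = {}
        for pair in pairs:
            r, _ = ratio_map(pair)
            ratios[pair.subject_id] = r
        rois = roi_summary(ratios, label_map)
        genotypes = cohort.loc[rois.index, "genotype"]
        dunnett_rows = []
        for roi in rois.columns:
            res = anova_dunnett(rois[roi], genotypes, control=config.reference,
                                seed=config.seed + 17)
            for grp, row in res.comparisons.iterrows():
                dunnett_rows.append(
                    {
                        "roi": roi, "control": config.reference, "group": grp,
                        "anova_F": res.anova_F, "anova_p": res.anova_p,
                        "anova_df": res.anova_df, "t": row["t"],
                        "p_unadjusted": row["p_unadjusted"],
                        "p_adjusted": row["p_adjusted"],
                    }
                )
        dunnett_table = pd.DataFrame(dunnett_rows).set_index(["roi", "group"])
        two = rois[genotypes.isin([config.reference, "TT"])]
        lda = lda_classify(
            two[["GPi", "SN", "LPut"]], genotypes.loc[two.index], positive="TT"
        )
        lda_report = pd.DataFrame(
            {"weight": lda.weights}
        )
        _write_csv(rois, out / "roi_means.csv", "T2w/T1w ratio")
        _write_csv(dunnett_table, out / "roi_dunnett.csv", "T2w/T1w ratio contrasts")
        _write_csv(lda_report, out / "lda_weights.csv", "standardized discriminant weights")
        (out / "lda_auc.json").write_text(
            json.dumps({"auc": lda.auc, "positive": "TT", "control": config.reference})
        )
        log.info("mri stage done: %d subjects, LDA AUC %.3f", len(rois), lda.auc)
        return {"roi_means": rois, "dunnett": dunnett_table, "lda": lda, "truth": truth}
    finally:
        log.removeHandler(handler)
        handler.close()


def run_all(config: RunConfig):
    return {
        "glycome": run_glycome(config),
        "elements": run_elements(config),
        "mri": run_mri(config),
    }


def simulate_to_files(config: RunConfig):
    """Write simulated inputs (profiles, elements, QC, metadata, volumes)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = build_default_panel()
    cohort = generate_cohort(config.glycome_n, seed=_seed_for(config, "cohort"))
    profiles, _ = generate_glycome_profiles(cohort, panel, seed=_seed_for(config, "glycome"))
    _write_csv(profiles_to_frame(profiles).set_index("sample_id"),
               out / "profiles.csv", "percent abundance")
    el_cohort = generate_cohort(config.element_n, seed=_seed_for(config, "cohort"))
    panel_el, qc, _ = generate_element_panel(el_cohort, seed=_seed_for(config, "elements"))
    _write_csv(panel_el.concentrations, out / "elements.csv", "ug/L")
    _write_csv(qc, out / "qc_runs.csv", "ug/L")
    _write_csv(cohort, out / "metadata_glycome.csv", "age: years, bmi: kg/m2")
    _write_csv(el_cohort, out / "metadata_elements.csv", "age: years, bmi: kg/m2")
    return out
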