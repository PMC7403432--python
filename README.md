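# glycomn

Analysis machinery for manganese-related phenotypes of the *SLC39A8* A391T
variant (rs13107325, genotypes CC/CT/TT): plasma protein **N-glycome
profiling** from permethylated MALDI-TOF spectra, **serum trace-element
panels** with method-detection-limit (MDL) screening, and **T2w/T1w ratio
neuroimaging** statistics — together with seeded synthetic-cohort
generators that emulate the statistical structure of the original biobank
data, which cannot be redistributed.

The package is a library first: import it from Python, or use the thin
`glycomn` CLI for shell-driven simulate/analyze runs. Short narrative
scripts live in `examples/`.

## What it computes

**Glycan masses.** For a composition in the four mass-distinct residue
classes (HexNAc, Hex, dHex, NeuAc), the monoisotopic m/z of the fully
permethylated, sodiated species is

> m/z = Σᵢ nᵢ·Mᵢ + M_end + M(Na) − mₑ

with permethylated residue masses derived from atomic monoisotopic masses
(Hex C₉H₁₆O₅ = 204.0998, HexNAc C₁₁H₁₉NO₅ = 245.1263, dHex C₈H₁₄O₄ =
174.0892, NeuAc C₁₆H₂₇NO₈ = 361.1737) and end-group C₂H₆O. A curated
57-species human plasma panel (AxFyGzSw nomenclature, structural
annotations for antennarity/bisection/fucosylation) drives spectrum
annotation; relative abundance of each glycan is its peak intensity
divided by the summed intensity of all 57 panel species, in percent.

**Glycome statistics.** Profiles aggregate into structural categories
(mono/bi/tri/tetra-antennary, high-mannose, hybrid, bisecting, core- and
antenna-fucosylated, terminal residues); genotype comparisons use one-way
ANOVA (df = 2) followed by pairwise Welch t-tests with star thresholds at
0.05/0.01/0.001, relative-change heat-map matrices (display clip ±50%
relative, ±5 absolute), abundance-weighted monosaccharide contributions
and pre/post supplementation paired tables.

**Trace elements.** MDL = t(0.99, n−1) × SD over n = 7 replicate low-level
QC runs (multiplier 3.143); an element enters the analysis only when its
mean concentration over all samples exceeds its MDL. Genotype statistics
share the ANOVA/Welch machinery; percent reductions are
100·(x̄_ref − x̄_alt)/x̄_ref.

**Neuroimaging.** Voxel-wise T2w/T1w ratios (invariant to per-subject
global intensity scaling), two-sample Welch t-maps with Benjamini–Hochberg
FDR at q < 0.05 over in-mask voxels, ROI mean tables, one-way ANOVA with
Dunnett many-to-one post-hoc tests (seeded Monte-Carlo max-|t| null,
200 000 draws), and Fisher LDA genotype classification with rank-statistic
AUC and a leave-one-out option.

## Worked example

```python
from glycomn import (generate_cohort, generate_element_panel,
                     filter_elements, element_genotype_stats, percent_reduction)
from glycomn.synthetic_cohort import ELEMENT_N   # n = 46/46/25

cohort = generate_cohort(ELEMENT_N, seed=21)
panel, qc, truth = generate_element_panel(cohort, seed=22)
included, excluded, audit = filter_elements(panel)
stats = element_genotype_stats(panel, cohort["genotype"], reference="CC")
```

prints (via `examples/04_trace_elements_mdl.py`):

```
16 elements above MDL, 7 excluded: ['Be', 'Cd', 'Ni', 'Pt', 'Te', 'Tl', 'W']

Mn means (ug/L): CC 0.806  CT 0.715  TT 0.643
Mn ANOVA: F=9.55, p=0.0001, df=2
reduction CC->CT: 11%  CC->TT: 20%
elements besides Mn with ANOVA p<0.05: []
```

Sixteen of 23 elements clear their detection limits; only manganese shows
a genotype gradient — a ~10%/~20% serum reduction in heterozygous and
homozygous carriers — while the other elements fire only at the nominal
false-positive rate. `examples/01_mass_calculator.py` prints the anchor
masses (A2G1S1 → 2227.109, A3G3S3 → 3602.782, A3FG3S3 → 3776.872), and
`examples/05_t2t1_ratio_mri.py` shows the TT ratio decrease in GPi/SN,
increase in lateral putamen, and an LDA AUC of ~0.93 from the three ROI
ratios alone.

## CLI

```bash
glycomn panel validate            # 57-species panel invariants
glycomn simulate all --seed 1 --out runs/sim
glycomn glycome  --seed 1 --out runs/glycome
glycomn elements --seed 1 --out runs/elements
glycomn mri      --seed 1 --out runs/mri
```

Every output CSV carries a header naming units and the package version;
each run writes its resolved YAML config and a seed-stamped log next to
its outputs.

## Layout

- `src/glycomn/glycan_core.py` — composition algebra, mass engine, nomenclature, panel
- `src/glycomn/spectra.py` — spectrum synthesis, peak picking, annotation, normalization
- `src/glycomn/glycome_stats.py` — categories, genotype statistics, heat maps, paired tables
- `src/glycomn/trace_elements.py` — MDL, inclusion filter, element statistics, regressions
- `src/glycomn/neuroimaging.py` — ratio maps, voxel-wise FDR, ROI/Dunnett, LDA/ROC
- `src/glycomn/synthetic_cohort.py` — seeded cohort/glycome/element/volume generators
- `src/glycomn/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — model assumptions, calibrations and limitations
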