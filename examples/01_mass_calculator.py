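"""Permethylated N-glycan mass calculation and the packaged plasma panel.

Computes [M+Na]+ monoisotopic m/z for glycan compositions given by
AxFyGzSw shorthand and shows the reference panel around one anchor.
"""

from glycomn import build_default_panel, parse_short_name, permethylated_mz

for label in ("A2G1S1", "A3G3S3", "A3FG3S3"):
    comp, ann = parse_short_name(label)
    mz = permethylated_mz(comp)
    print(f"{label:9s} {comp.counts()}  ->  m/z {mz:9.4f}  (rounds to {round(mz)})")

panel = build_default_panel()
print(f"\npackaged panel: {len(panel)} species spanning "
      f"{panel.mz_values.min():.1f}-{panel.mz_values.max():.1f} Da")
sp = panel["A2G1S1"]
print(f"A2G1S1 in panel: class={sp.annotation.glycan_class}, "
      f"antennae={sp.annotation.antennae}, baseline={sp.baseline_percent}%")

# The three printed values are the monosialo bi-antennary precursor (2,227)
# and the two large tri-antennary species (3,603 / 3,777) used as
# annotation anchors for plasma spectra.
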