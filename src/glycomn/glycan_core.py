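"""Composition algebra and mass calculation for permethylated N-glycans.

An N-glycan composition is expressed in the four mass-distinct residue
classes observable by MALDI-TOF of permethylated glycans: HexNAc (GlcNAc),
Hex (Man and Gal are isobaric and pooled), dHex (Fuc) and NeuAc (sialic
acid).  Masses are monoisotopic, computed for the fully permethylated, free
reducing-end glycan as a singly charged sodium adduct [M+Na]+ — the standard
ion species for permethylated glycans in reflectron-positive MALDI.

The module also carries the curated 57-species human plasma N-glycan
reference panel used for spectrum annotation and all downstream statistics.
Structural attributes that composition alone cannot resolve (bisecting
GlcNAc versus an extra antenna, core versus antennal fucose, Man/Gal split
of the pooled Hex count) are curated per species, in the spirit of
assignment by prior MS/MS knowledge of the plasma glycome.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "MonosaccharideComposition",
    "StructuralAnnotation",
    "GlycanSpecies",
    "GlycanPanel",
    "permethylated_mz",
    "molecular_formula",
    "parse_short_name",
    "derive_short_name",
    "classify_species",
    "build_default_panel",
    "ACQUISITION_WINDOW",
]

# Monoisotopic atomic masses (CODATA/AME-derived standard values), Da.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}
ELECTRON_MASS = 0.00054857990907

#: m/z acquisition window of the reflectron-positive MALDI method, Da.
ACQUISITION_WINDOW = (1500.0, 5000.0)

# Underivatized residue formulas (glycosidic-bond residues, i.e. monomer
# minus H2O) and the number of methylation sites each gains on full
# permethylation.  A methylation replaces H with CH3, net +CH2.
_RESIDUE_BASE = {
    "hexnac": ({"C": 8, "H": 13, "N": 1, "O": 5}, 3),
    "hex": ({"C": 6, "H": 10, "O": 5}, 3),
    "dhex": ({"C": 6, "H": 10, "O": 4}, 2),
    "neuac": ({"C": 11, "H": 17, "N": 1, "O": 8}, 5),
}
# Terminating a residue chain restores H2O; permethylation then methylates
# the reducing-end anomeric oxygen and the remaining non-reducing hydroxyl.
_END_GROUP = ({"H": 2, "O": 1}, 2)

_RESIDUE_ORDER = ("hexnac", "hex", "dhex", "neuac")


def _formula_mass(formula: Mapping[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def _permethylated_formula(base: Mapping[str, int], n_methyl: int) -> dict:
    f = dict(base)
    f["C"] = f.get("C", 0) + n_methyl
    f["H"] = f.get("H", 0) + 2 * n_methyl
    return f


PERMETHYLATED_RESIDUE_MASS = {
    name: _formula_mass(_permethylated_formula(base, n))
    for name, (base, n) in _RESIDUE_BASE.items()
}
_END_GROUP_MASS = _formula_mass(_permethylated_formula(*_END_GROUP))

_ADDUCT_MASS = {"Na": ATOMIC_MASS["Na"] - ELECTRON_MASS}


@dataclass(frozen=True)
class MonosaccharideComposition:
    """Residue-class counts of one N-glycan.

    Counts are non-negative integers; at least one must be positive.  A
    composition satisfying ``hexnac >= 2 and hex >= 3`` carries the
    trimannosyl-chitobiose core common to all N-glycans.
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self):
        for name in _RESIDUE_ORDER:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty composition: at least one residue count must be positive")

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.dhex + self.neuac

    @property
    def is_nglycan(self) -> bool:
        """True if the trimannosyl-chitobiose core is present."""
        return self.hexnac >= 2 and self.hex >= 3

    def counts(self) -> dict:
        return {k: getattr(self, k) for k in _RESIDUE_ORDER}

    def __add__(self, other: "MonosaccharideComposition") -> "MonosaccharideComposition":
        return MonosaccharideComposition(
            **{k: getattr(self, k) + getattr(other, k) for k in _RESIDUE_ORDER}
        )

    def add(self, residue: str, n: int = 1) -> "MonosaccharideComposition":
        if residue not in _RESIDUE_ORDER:
            raise ValueError(f"unknown residue class {residue!r}")
        d = self.counts()
        d[residue] += n
        return MonosaccharideComposition(**d)


def molecular_formula(composition: MonosaccharideComposition) -> dict:
    """Elemental formula of the fully permethylated free glycan (neutral M)."""
    total: dict = {}
    pieces = [
        _permethylated_formula(base, n)
        for name, (base, n) in _RESIDUE_BASE.items()
        for _ in range(getattr(composition, name))
    ]
    pieces.append(_permethylated_formula(*_END_GROUP))
    for f in pieces:
        for el, n in f.items():
            total[el] = total.get(el, 0) + n
    return total


def permethylated_mz(composition: MonosaccharideComposition, adduct: str = "Na") -> float:
    """Monoisotopic m/z of the permethylated glycan as singly charged [M+adduct]+.

    The neutral mass is the sum of permethylated residue masses plus the
    end-group mass (restored H2O, both termini methylated); the cation adds
    the adduct atom and removes one electron.
    """
    if adduct not in _ADDUCT_MASS:
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCT_MASS)}")
    m = sum(
        PERMETHYLATED_RESIDUE_MASS[name] * getattr(composition, name)
        for name in _RESIDUE_ORDER
    )
    return m + _END_GROUP_MASS + _ADDUCT_MASS[adduct]


@dataclass(frozen=True)
class StructuralAnnotation:
    """Curated/derived structural attributes of one glycan species.

    ``antennae`` counts GlcNAc attachments to the core mannoses (0 for
    high-mannose).  ``bisecting`` marks the MGAT3-added GlcNAc on the core
    beta-mannose, which raises the HexNAc count without adding an antenna.
    Fucose placement and the terminal-residue profile cannot be read from
    composition and are curated.
    """

    glycan_class: str  # "complex" | "hybrid" | "high-mannose"
    antennae: int
    bisecting: bool = False
    core_fucose: int = 0
    antenna_fucose: int = 0
    terminal_gal: int = 0
    terminal_glcnac: int = 0
    sialyl: int = 0
    gal: int = 0  # curated Gal share of the pooled Hex count

    def __post_init__(self):
        if self.glycan_class not in ("complex", "hybrid", "high-mannose"):
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")
        if not 0 <= self.antennae <= 4:
            raise ValueError("antennae must be within 0-4")
        if self.glycan_class == "high-mannose" and self.antennae != 0:
            raise ValueError("high-mannose glycans have no antennae")


@dataclass(frozen=True)
class GlycanSpecies:
    """A named panel glycan: composition, theoretical m/z and annotation."""

    short_name: str
    composition: MonosaccharideComposition
    theoretical_mz: float
    annotation: StructuralAnnotation
    baseline_percent: float = 0.0

    def __post_init__(self):
        expected = permethylated_mz(self.composition)
        if abs(expected - self.theoretical_mz) > 0.01:
            raise ValueError(
                f"{self.short_name}: stored m/z {self.theoretical_mz:.4f} disagrees with "
                f"computed {expected:.4f}"
            )
        lo, hi = ACQUISITION_WINDOW
        if not lo <= self.theoretical_mz <= hi:
            raise ValueError(
                f"{self.short_name}: m/z {self.theoretical_mz:.1f} outside acquisition "
                f"window [{lo:.0f}, {hi:.0f}]"
            )
        ann = self.annotation
        if ann.core_fucose + ann.antenna_fucose != self.composition.dhex:
            raise ValueError(f"{self.short_name}: fucose placement does not sum to dHex count")
        if ann.glycan_class == "complex":
            want = self.composition.hexnac - 2 - (1 if ann.bisecting else 0)
            if ann.antennae != want:
                raise ValueError(
                    f"{self.short_name}: complex glycan antennae {ann.antennae} != "
                    f"HexNAc-2-bisecting = {want}"
                )


class GlycanPanel:
    """Ordered reference panel of glycan species with unique names and m/z."""

    #: annotation assigns a peak to the nearest panel m/z within this window
    DEFAULT_TOLERANCE = 0.5

    def __init__(self, species: Iterable[GlycanSpecies], name: str = "panel", version: str = "1"):
        self.species = list(species)
        self.name = name
        self.version = version
        names = [s.short_name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate short_names in panel")
        mzs = sorted(s.theoretical_mz for s in self.species)
        min_sep = min(
            (b - a for a, b in zip(mzs, mzs[1:])), default=float("inf")
        )
        if min_sep <= 2 * self.DEFAULT_TOLERANCE:
            raise ValueError(
                f"panel m/z values too close: min separation {min_sep:.3f} Da "
                f"<= {2 * self.DEFAULT_TOLERANCE} Da"
            )

    def __len__(self):
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __getitem__(self, short_name: str) -> GlycanSpecies:
        for s in self.species:
            if s.short_name == short_name:
                return s
        raise KeyError(short_name)

    @property
    def short_names(self) -> list:
        return [s.short_name for s in self.species]

    @property
    def mz_values(self):
        import numpy as np

        return np.array([s.theoretical_mz for s in self.species])

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "version": self.version,
            "species": [
                {
                    "short_name": s.short_name,
                    "composition": s.composition.counts(),
                    "mz": round(s.theoretical_mz, 4),
                    "glycan_class": s.annotation.glycan_class,
                    "antennae": s.annotation.antennae,
                    "bisecting": s.annotation.bisecting,
                    "core_fucose": s.annotation.core_fucose,
                    "antenna_fucose": s.annotation.antenna_fucose,
                    "gal": s.annotation.gal,
                    "baseline_percent": s.baseline_percent,
                }
                for s in self.species
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GlycanPanel":
        doc = json.loads(text)
        species = []
        for rec in doc["species"]:
            comp = MonosaccharideComposition(**rec["composition"])
            ann = _build_annotation(
                comp,
                glycan_class=rec["glycan_class"],
                antennae=rec["antennae"],
                bisecting=rec["bisecting"],
                core_fucose=rec["core_fucose"],
                antenna_fucose=rec["antenna_fucose"],
                gal=rec["gal"],
            )
            species.append(
                GlycanSpecies(
                    short_name=rec["short_name"],
                    composition=comp,
                    theoretical_mz=rec["mz"],
                    annotation=ann,
                    baseline_percent=rec.get("baseline_percent", 0.0),
                )
            )
        return cls(species, name=doc.get("name", "panel"), version=doc.get("version", "1"))


_SHORT_NAME_RE = re.compile(
    r"^A(?P<a>\d)(?P<bis>B)?(?:F(?P<f>\d)?)?G(?P<g>\d)S(?P<s>\d)$"
)


class ShortNameError(ValueError):
    pass


def parse_short_name(label: str):
    """Parse an ``AxFyGzSw`` label into composition plus partial annotation.

    Grammar: ``A<antennae>[B][F[<fuc>]]G<gal>S<sia>``; a bare ``F`` means one
    fucose, the optional ``B`` flags a bisecting GlcNAc.  The composition is
    reconstructed on the N-glycan core: HexNAc = antennae + 2 (+1 if
    bisected), Hex = Gal + 3, dHex = fucoses, NeuAc = sialic acids.

    Returns ``(composition, annotation)``.
    """
    if not isinstance(label, str):
        raise ShortNameError(f"label must be a string, got {type(label).__name__}")
    m = _SHORT_NAME_RE.match(label.strip())
    if m is None:
        # name the offending token for diagnostics
        probe = re.match(r"^A\d(B)?(F\d?)?(G\d)?(S\d)?", label.strip() or "")
        offending = label[probe.end():] if probe else label
        raise ShortNameError(
            f"malformed glycan label {label!r}: unexpected token {offending or label!r}"
        )
    a = int(m.group("a"))
    g = int(m.group("g"))
    s = int(m.group("s"))
    f = int(m.group("f")) if m.group("f") else (1 if "F" in label else 0)
    bis = m.group("bis") is not None
    comp = MonosaccharideComposition(
        hexnac=a + 2 + (1 if bis else 0), hex=g + 3, dhex=f, neuac=s
    )
    ann = _build_annotation(
        comp,
        glycan_class="complex",
        antennae=a,
        bisecting=bis,
        core_fucose=None,
        antenna_fucose=None,
        gal=g,
    )
    return comp, ann


def derive_short_name(annotation: StructuralAnnotation, composition: MonosaccharideComposition) -> str:
    """Inverse of :func:`parse_short_name` for complex glycans."""
    if annotation.glycan_class != "complex":
        raise ValueError("short names of the AxFyGzSw form describe complex glycans only")
    f = composition.dhex
    fpart = "" if f == 0 else ("F" if f == 1 else f"F{f}")
    bpart = "B" if annotation.bisecting else ""
    return f"A{annotation.antennae}{bpart}{fpart}G{annotation.gal}S{composition.neuac}"


def _build_annotation(
    comp: MonosaccharideComposition,
    glycan_class: str,
    antennae: int,
    bisecting: bool,
    core_fucose,
    antenna_fucose,
    gal: int,
) -> StructuralAnnotation:
    """Complete an annotation: fill fucose placement and terminal profile."""
    if core_fucose is None and antenna_fucose is None:
        # default placement: first fucose is core on mono/bi structures and
        # antennal on tri/tetra structures; extras are antennal (plasma
        # convention: core-Fuc dominates small, antenna-Fuc large glycans)
        if antennae >= 3:
            core_fucose = 1 if comp.dhex >= 2 else 0
        else:
            core_fucose = min(comp.dhex, 1)
        antenna_fucose = comp.dhex - core_fucose
    elif antenna_fucose is None:
        antenna_fucose = comp.dhex - core_fucose
    elif core_fucose is None:
        core_fucose = comp.dhex - antenna_fucose
    sialyl = comp.neuac
    terminal_gal = max(gal - sialyl, 0)
    if glycan_class == "complex":
        terminal_glcnac = max(antennae - gal, 0)
    elif glycan_class == "hybrid":
        terminal_glcnac = 1 if gal == 0 else 0
    else:
        terminal_glcnac = 0
    return StructuralAnnotation(
        glycan_class=glycan_class,
        antennae=antennae,
        bisecting=bisecting,
        core_fucose=core_fucose,
        antenna_fucose=antenna_fucose,
        terminal_gal=terminal_gal,
        terminal_glcnac=terminal_glcnac,
        sialyl=sialyl,
        gal=gal,
    )


def classify_species(
    composition: MonosaccharideComposition,
    overrides: Mapping | None = None,
) -> StructuralAnnotation:
    """Heuristic structural classification of an unlabeled composition.

    Rules: high-mannose iff HexNAc = 2, Hex >= 5, no Fuc/NeuAc; hybrid iff
    HexNAc = 3 and Hex >= 5; otherwise complex with
    antennae = HexNAc - 2 - bisecting.  Curated ``overrides`` (``bisecting``,
    ``core_fucose``, ``antenna_fucose``, ``gal``) take precedence — by mass
    alone a bisected n-antennary glycan is indistinguishable from an
    (n+1)-antennary one.
    """
    if not composition.is_nglycan:
        raise ValueError(
            f"composition {composition.counts()} lacks the HexNAc2Hex3 N-glycan core"
        )
    ov = dict(overrides or {})
    bisecting = bool(ov.get("bisecting", False))
    if (
        composition.hexnac == 2
        and composition.hex >= 5
        and composition.neuac == 0
        and composition.dhex == 0
    ):
        glycan_class, antennae, gal = "high-mannose", 0, 0
        bisecting = False
    elif composition.hexnac == 3 and composition.hex >= 5:
        glycan_class, antennae = "hybrid", 1
        gal = ov.get("gal", min(composition.neuac + max(composition.hex - 5, 0), 1))
    else:
        glycan_class = "complex"
        antennae = composition.hexnac - 2 - (1 if bisecting else 0)
        if not 0 <= antennae <= 4:
            raise ValueError(
                f"composition {composition.counts()} implies {antennae} antennae, outside 0-4"
            )
        gal = ov.get("gal", composition.hex - 3)
    return _build_annotation(
        composition,
        glycan_class=glycan_class,
        antennae=antennae,
        bisecting=bisecting,
        core_fucose=ov.get("core_fucose"),
        antenna_fucose=ov.get("antenna_fucose"),
        gal=gal,
    )


_PANEL_RESOURCE = "panel57.json"


def build_default_panel() -> GlycanPanel:
    """Load the packaged 57-species human plasma N-glycan panel."""
    text = resources.files("glycomn.data").joinpath(_PANEL_RESOURCE).read_text()
    return GlycanPanel.from_json(text)
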