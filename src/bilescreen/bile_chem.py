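"""Bile acid cores, amino acids, and their amide conjugates.

All fifteen steroid cores handled here are C24 cholanic-acid skeletons that
differ only in the substituent carried at ring carbons C-3, C-6, C-7 and
C-12 (an alpha- or beta-oriented hydroxyl, a keto group, or plain hydrogen).
Microbially conjugated bile acids (MCBAs) are modelled as an amide
condensation of a core's carboxyl group with the amine of a free amino acid,
losing one water.  Masses are exact monoisotopic sums over the elemental
composition; ionisation is negative-mode ([M-H]-) throughout.

Each conjugate carries a predicted three-fragment MS/MS signature: the free
amino-acid anion, the fragment left after loss of the amino-acid residue
(i.e. the deprotonated core), and a "major sterol" fragment, by default the
dehydrated deprotonated core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MONO_MASS",
    "ElementComposition",
    "BileAcidCore",
    "AminoAcidResidue",
    "FragmentTriad",
    "ConjugateSpecies",
    "TransformationEdge",
    "monoisotopic_mass",
    "average_mass",
    "build_core_registry",
    "build_amino_acid_registry",
    "enumerate_conjugates",
    "predict_fragments",
    "transformation_graph",
    "library_frame",
    "core_library_frame",
    "export_library",
]

#: Mass of a proton, Da (CODATA).
PROTON_MASS = 1.00727646688

ALPHA_OH = "α-OH"
BETA_OH = "β-OH"
OXO = "oxo"
H = "H"
SUBSTITUENT_STATES = (ALPHA_OH, BETA_OH, OXO, H)

_KNOWN_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ElementComposition:
    """Counts per chemical element (CHNOS organic subset)."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = {}
        for element, n in self.counts:
            if n < 0:
                raise ValueError(f"negative count for element {element!r}")
            if element in seen:
                raise ValueError(f"duplicate element {element!r}")
            seen[element] = n
        if not any(n > 0 for n in seen.values()):
            raise ValueError("composition must contain at least one atom")

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementComposition":
        return cls(tuple(sorted((e, int(n)) for e, n in counts.items() if n)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        out = self.as_dict()
        for e, n in other.counts:
            out[e] = out.get(e, 0) + n
        return ElementComposition.from_dict(out)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        out = self.as_dict()
        for e, n in other.counts:
            out[e] = out.get(e, 0) - n
            if out[e] < 0:
                raise ValueError(f"subtraction drives element {e!r} negative")
        return ElementComposition.from_dict(out)

    def formula(self) -> str:
        """Hill-order molecular formula (C, H, then alphabetical)."""
        d = self.as_dict()
        order = ["C", "H"] + sorted(k for k in d if k not in ("C", "H"))
        return "".join(f"{e}{d[e]}" for e in order if d.get(e))


def _comp(**counts: int) -> ElementComposition:
    return ElementComposition.from_dict(counts)


WATER = _comp(H=2, O=1)


def monoisotopic_mass(composition: ElementComposition) -> float:
    """Exact mass as the sum of most-abundant-isotope atomic masses (Da)."""
    total = 0.0
    for element, n in composition.counts:
        try:
            total += n * _pmass.nist_mass[element][0][0]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


def average_mass(composition: ElementComposition) -> float:
    """Average molar mass (g/mol) from standard isotopic abundances."""
    for element, _ in composition.counts:
        if element not in _pmass.nist_mass:
            raise ValueError(f"unknown element symbol {element!r}")
    return _pmass.calculate_mass(composition=composition.as_dict(), average=True)


#: Monoisotopic mass of one water molecule, Da.
WATER_MONO_MASS = monoisotopic_mass(WATER)


@dataclass(frozen=True)
class BileAcidCore:
    """A C24 bile acid steroid core with substituents at C-3/C-6/C-7/C-12."""

    name: str
    abbreviation: str
    substituents: tuple[str, str, str, str]  # state at C-3, C-6, C-7, C-12
    composition: ElementComposition = field(init=False)
    monoisotopic_mass: float = field(init=False)
    average_mass: float = field(init=False)

    def __post_init__(self) -> None:
        for s in self.substituents:
            if s not in SUBSTITUENT_STATES:
                raise ValueError(f"unknown substituent state {s!r}")
        # Unsubstituted cholanic acid skeleton is C24H40O2 (the two oxygens
        # belong to the carboxyl); each hydroxyl adds O, each oxo adds O and
        # removes H2 relative to the hydroxyl form.
        comp = _comp(C=24, H=40, O=2)
        for s in self.substituents:
            if s in (ALPHA_OH, BETA_OH):
                comp = comp + _comp(O=1)
            elif s == OXO:
                comp = comp + _comp(O=1) - _comp(H=2)
        object.__setattr__(self, "composition", comp)
        object.__setattr__(self, "monoisotopic_mass", monoisotopic_mass(comp))
        object.__setattr__(self, "average_mass", average_mass(comp))


_CORE_TABLE = [
    # name, abbreviation, (C-3, C-6, C-7, C-12)
    ("cholic acid", "CA", (ALPHA_OH, H, ALPHA_OH, ALPHA_OH)),
    ("chenodeoxycholic acid", "CDCA", (ALPHA_OH, H, ALPHA_OH, H)),
    ("deoxycholic acid", "DCA", (ALPHA_OH, H, H, ALPHA_OH)),
    ("lithocholic acid", "LCA", (ALPHA_OH, H, H, H)),
    ("ursodeoxycholic acid", "UDCA", (ALPHA_OH, H, BETA_OH, H)),
    ("hyodeoxycholic acid", "HDCA", (ALPHA_OH, ALPHA_OH, H, H)),
    ("β-muricholic acid", "β-MCA", (ALPHA_OH, BETA_OH, BETA_OH, H)),
    ("3-oxocholic acid", "3-oxoCA", (OXO, H, ALPHA_OH, ALPHA_OH)),
    ("3-oxochenodeoxycholic acid", "3-oxoCDCA", (OXO, H, ALPHA_OH, H)),
    ("3-oxodeoxycholic acid", "3-oxoDCA", (OXO, H, H, ALPHA_OH)),
    ("7-oxodeoxycholic acid", "7-oxoDCA", (ALPHA_OH, H, OXO, ALPHA_OH)),
    ("7-oxolithocholic acid", "7-oxoLCA", (ALPHA_OH, H, OXO, H)),
    ("12-oxochenodeoxycholic acid", "12-oxoCDCA", (ALPHA_OH, H, ALPHA_OH, OXO)),
    ("12-oxolithocholic acid", "12-oxoLCA", (ALPHA_OH, H, H, OXO)),
    ("7,12-dioxolithocholic acid", "7,12-dioxoLCA", (ALPHA_OH, H, OXO, OXO)),
]


def build_core_registry() -> list[BileAcidCore]:
    """The fifteen steroid cores of the screen, CA-derived compositions."""
    cores = [BileAcidCore(name, abbr, subs) for name, abbr, subs in _CORE_TABLE]
    abbrs = [c.abbreviation for c in cores]
    assert len(set(abbrs)) == len(abbrs)
    return cores


@dataclass(frozen=True)
class AminoAcidResidue:
    """A free amino acid and its residue (free minus water) masses."""

    name: str
    code: str
    composition: ElementComposition
    isobaric_group: str
    free_monoisotopic_mass: float = field(init=False)
    residue_mass: float = field(init=False)

    def __post_init__(self) -> None:
        m = monoisotopic_mass(self.composition)
        object.__setattr__(self, "free_monoisotopic_mass", m)
        object.__setattr__(self, "residue_mass", m - WATER_MONO_MASS)


_AA_TABLE = [
    # name, three-letter code, composition of the free amino acid
    ("glycine", "Gly", dict(C=2, H=5, N=1, O=2)),
    ("alanine", "Ala", dict(C=3, H=7, N=1, O=2)),
    ("serine", "Ser", dict(C=3, H=7, N=1, O=3)),
    ("valine", "Val", dict(C=5, H=11, N=1, O=2)),
    ("leucine", "Leu", dict(C=6, H=13, N=1, O=2)),
    ("isoleucine", "Ile", dict(C=6, H=13, N=1, O=2)),
    ("methionine", "Met", dict(C=5, H=11, N=1, O=2, S=1)),
    ("phenylalanine", "Phe", dict(C=9, H=11, N=1, O=2)),
    ("tyrosine", "Tyr", dict(C=9, H=11, N=1, O=3)),
    ("tryptophan", "Trp", dict(C=11, H=12, N=2, O=2)),
    ("aspartate", "Asp", dict(C=4, H=7, N=1, O=4)),
    ("glutamate", "Glu", dict(C=5, H=9, N=1, O=4)),
    ("asparagine", "Asn", dict(C=4, H=8, N=2, O=3)),
    ("glutamine", "Gln", dict(C=5, H=10, N=2, O=3)),
    ("histidine", "His", dict(C=6, H=9, N=3, O=2)),
    ("lysine", "Lys", dict(C=6, H=14, N=2, O=2)),
    ("arginine", "Arg", dict(C=6, H=14, N=4, O=2)),
]


def build_amino_acid_registry(extra: Sequence[AminoAcidResidue] = ()) -> list[AminoAcidResidue]:
    """The amino acids searched for conjugation (taurine excluded by default).

    Leucine and isoleucine share one isobaric group id; every other entry is
    its own group.  Pass ``extra`` residues (e.g. taurine) to widen the search.
    """
    out = []
    for name, code, comp in _AA_TABLE:
        group = "Leu/Ile" if code in ("Leu", "Ile") else code
        out.append(AminoAcidResidue(name, code, _comp(**comp), group))
    out.extend(extra)
    return out


@dataclass(frozen=True)
class FragmentTriad:
    """The three diagnostic negative-mode fragments of a conjugate."""

    aa_anion: float       # deprotonated free amino acid
    aa_loss: float        # parent minus the amino-acid residue (= core - H)
    sterol: float         # major sterol fragment (default: aa_loss - H2O)


@dataclass(frozen=True)
class ConjugateSpecies:
    """An amide conjugate of one steroid core and one amino acid."""

    species_id: str
    core: BileAcidCore
    amino_acid: AminoAcidResidue
    composition: ElementComposition
    neutral_mass: float
    mz_mh: float          # [M-H]- m/z
    fragments: FragmentTriad
    aa_ambiguous: bool = False   # Leu/Ile cannot be distinguished by mass
    aa_label: str = ""

    @property
    def isobaric_group(self) -> str:
        return self.composition.formula()


SterolRule = Callable[[BileAcidCore], float]


def _default_sterol_rule(core: BileAcidCore) -> float:
    # dehydrated deprotonated core, [core - H - H2O]-
    return core.monoisotopic_mass - PROTON_MASS - WATER_MONO_MASS


def predict_fragments(core: BileAcidCore, amino_acid: AminoAcidResidue,
                      sterol_rule: SterolRule | None = None) -> FragmentTriad:
    """Predict the diagnostic fragment triad for a (core, amino acid) pair.

    The sterol fragment rule is a plug-in; the default is dehydration of the
    deprotonated core.
    """
    rule = sterol_rule or _default_sterol_rule
    return FragmentTriad(
        aa_anion=amino_acid.free_monoisotopic_mass - PROTON_MASS,
        aa_loss=core.monoisotopic_mass - PROTON_MASS,
        sterol=rule(core),
    )


def enumerate_conjugates(cores: Sequence[BileAcidCore] | None = None,
                         amino_acids: Sequence[AminoAcidResidue] | None = None,
                         sterol_rule: SterolRule | None = None) -> list[ConjugateSpecies]:
    """Cartesian conjugate library; isobaric amino acids collapse to one entry.

    With the default registries this yields 15 cores x 15 mass-distinct amino
    acids = 225 species.  The Leu/Ile pair is emitted once, labelled
    "Leu/Ile" and flagged ambiguous.
    """
    cores = list(cores) if cores is not None else build_core_registry()
    amino_acids = list(amino_acids) if amino_acids is not None else build_amino_acid_registry()
    if not cores or not amino_acids:
        raise ValueError("core and amino acid lists must be non-empty")

    # collapse amino acids by isobaric group, keeping insertion order
    groups: dict[str, list[AminoAcidResidue]] = {}
    for aa in amino_acids:
        groups.setdefault(aa.isobaric_group, []).append(aa)

    out: list[ConjugateSpecies] = []
    seen: set[tuple[str, str]] = set()
    for core in cores:
        for group_id, members in groups.items():
            aa = members[0]
            key = (core.abbreviation, group_id)
            if key in seen:
                raise ValueError(f"duplicate (core, amino acid) pair {key}")
            seen.add(key)
            comp = core.composition + aa.composition - WATER
            neutral = monoisotopic_mass(comp)
            out.append(ConjugateSpecies(
                species_id=f"{core.abbreviation}-{group_id}",
                core=core,
                amino_acid=aa,
                composition=comp,
                neutral_mass=neutral,
                mz_mh=neutral - PROTON_MASS,
                fragments=predict_fragments(core, aa, sterol_rule),
                aa_ambiguous=len(members) > 1,
                aa_label=group_id,
            ))
    return out


@dataclass(frozen=True)
class TransformationEdge:
    """A substrate-to-product steroid-core transformation."""

    substrate: str
    product: str
    label: str


LABEL_3A = "3α-HSD"
LABEL_7A = "7α-HSD"
LABEL_12A = "12α-HSD"
LABEL_7A12A = "7α+12α-HSD"
LABEL_DEHYDROX = "7α-dehydroxylation"
LABEL_EPI = "7-epimerization"
LABEL_OTHER = "other"

_GRAPH = [
    ("CA", "7-oxoDCA", LABEL_7A),
    ("CDCA", "7-oxoLCA", LABEL_7A),
    ("CA", "12-oxoCDCA", LABEL_12A),
    ("DCA", "12-oxoLCA", LABEL_12A),
    ("CA", "3-oxoCA", LABEL_3A),
    ("CDCA", "3-oxoCDCA", LABEL_3A),
    ("DCA", "3-oxoDCA", LABEL_3A),
    ("CA", "7,12-dioxoLCA", LABEL_7A12A),
    ("CA", "DCA", LABEL_DEHYDROX),
    ("CDCA", "LCA", LABEL_DEHYDROX),
    ("CDCA", "UDCA", LABEL_EPI),
    ("DCA", "HDCA", LABEL_OTHER),
    ("CA", "β-MCA", LABEL_OTHER),
]


def transformation_graph() -> list[TransformationEdge]:
    """The observed substrate/product transformations over the core registry.

    Edges cover position-specific dehydrogenation (3α/7α/12α-HSD), the double
    7α+12α oxidation of CA, 7α-dehydroxylation, 7-epimerization of CDCA to
    UDCA, and the two multi-step conversions DCA→HDCA and CA→β-MCA.
    """
    return [TransformationEdge(*e) for e in _GRAPH]


def library_frame(species: Iterable[ConjugateSpecies]) -> pd.DataFrame:
    """Tabular view of a conjugate library (one row per species)."""
    rows = []
    for s in species:
        rows.append({
            "species_id": s.species_id,
            "core_abbrev": s.core.abbreviation,
            "amino_acid": s.aa_label,
            "formula": s.composition.formula(),
            "neutral_mono_mass": s.neutral_mass,
            "mz_M_minus_H": s.mz_mh,
            "frag_aa_anion": s.fragments.aa_anion,
            "frag_aa_loss": s.fragments.aa_loss,
            "frag_sterol": s.fragments.sterol,
            "isobaric_group": s.isobaric_group,
            "aa_ambiguous": s.aa_ambiguous,
        })
    return pd.DataFrame(rows)


def core_library_frame(cores: Sequence[BileAcidCore] | None = None) -> pd.DataFrame:
    """Unconjugated cores as matchable [M-H]- species (species_id = abbrev)."""
    cores = list(cores) if cores is not None else build_core_registry()
    return pd.DataFrame({
        "species_id": [c.abbreviation for c in cores],
        "core_abbrev": [c.abbreviation for c in cores],
        "amino_acid": ["" for _ in cores],
        "formula": [c.composition.formula() for c in cores],
        "neutral_mono_mass": [c.monoisotopic_mass for c in cores],
        "mz_M_minus_H": [c.monoisotopic_mass - PROTON_MASS for c in cores],
        "isobaric_group": [c.composition.formula() for c in cores],
        "aa_ambiguous": [False for _ in cores],
    })


def export_library(species: Iterable[ConjugateSpecies], path) -> None:
    """Write the conjugate library as TSV."""
    cols = ["species_id", "core_abbrev", "amino_acid", "formula",
            "neutral_mono_mass", "mz_M_minus_H",
            "frag_aa_anion", "frag_aa_loss", "frag_sterol"]
    library_frame(species)[cols].to_csv(path, sep="\t", index=False)
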