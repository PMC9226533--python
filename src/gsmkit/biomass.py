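"""Genome-derived biomass composition and pseudo-reaction generation.

The protein, DNA and RNA contributions to the biomass equation are
computed from the genome itself: monomer frequencies are counted from
the CDS translations (optionally weighted by expression), from both
genome strands (dNMPs), or from transcripts (NMPs).  Frequencies are
turned into stoichiometric coefficients in mmol per gram of polymer via
the average residue masses, so that every composition satisfies

    sum_i c_i * residue_mass_i = 1000  (mg of polymer per mmol basis)

A macromolecule template (mass fractions per gram dry weight plus the
growth-associated maintenance, GAM) then assembles the polymerisation
pseudo-reactions and the biomass reaction itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .model import PSEUDO_PREFIX, Reaction

WATER_MASS = 18.0153  # g/mol, lost per polymerised residue

#: genome-derived macromolecules whose composition must be supplied
GENOME_DERIVED = ("protein", "dna", "rna")

# average (not monoisotopic) monomer masses, g/mol; free monomers
AMINO_ACID_MASSES = {
    "A": 89.0932, "R": 174.2010, "N": 132.1179, "D": 133.1027, "C": 121.1582,
    "E": 147.1293, "Q": 146.1445, "G": 75.0666, "H": 155.1546, "I": 131.1729,
    "L": 131.1729, "K": 146.1876, "M": 149.2113, "F": 165.1891, "P": 115.1305,
    "S": 105.0926, "T": 119.1192, "W": 204.2252, "Y": 181.1885, "V": 117.1463,
}
NMP_MASSES = {"A": 347.2212, "C": 323.1965, "G": 363.2206, "U": 324.1813}
DNMP_MASSES = {"A": 331.2218, "C": 307.1971, "G": 347.2212, "T": 322.2085}

AMINO_ACID_IDS = {
    "A": "ala_L", "R": "arg_L", "N": "asn_L", "D": "asp_L", "C": "cys_L",
    "E": "glu_L", "Q": "gln_L", "G": "gly", "H": "his_L", "I": "ile_L",
    "L": "leu_L", "K": "lys_L", "M": "met_L", "F": "phe_L", "P": "pro_L",
    "S": "ser_L", "T": "thr_L", "W": "trp_L", "Y": "tyr_L", "V": "val_L",
}
NMP_IDS = {"A": "amp", "C": "cmp", "G": "gmp", "U": "ump"}
DNMP_IDS = {"A": "damp", "C": "dcmp", "G": "dgmp", "T": "dtmp"}


@dataclass(frozen=True)
class Monomer:
    key: str            # one-letter code within its class
    metabolite_id: str  # compartment-free metabolite id
    mass: float         # free-monomer average molecular mass, g/mol

    @property
    def residue_mass(self) -> float:
        return self.mass - WATER_MASS


@dataclass
class MonomerTable:
    """Average masses for the 20 amino acids, 4 NMPs and 4 dNMPs."""

    amino_acids: Dict[str, Monomer]
    nmps: Dict[str, Monomer]
    dnmps: Dict[str, Monomer]

    def __post_init__(self):
        for group in (self.amino_acids, self.nmps, self.dnmps):
            for mono in group.values():
                if mono.mass <= 0 or mono.residue_mass <= 0:
                    raise ValueError(f"monomer {mono.key}: non-positive mass")

    @classmethod
    def default(cls) -> "MonomerTable":
        return cls(
            amino_acids={
                k: Monomer(k, AMINO_ACID_IDS[k], m) for k, m in AMINO_ACID_MASSES.items()
            },
            nmps={k: Monomer(k, NMP_IDS[k], m) for k, m in NMP_MASSES.items()},
            dnmps={k: Monomer(k, DNMP_IDS[k], m) for k, m in DNMP_MASSES.items()},
        )

    def group(self, macromolecule: str) -> Dict[str, Monomer]:
        return {"protein": self.amino_acids, "rna": self.nmps, "dna": self.dnmps}[
            macromolecule
        ]


@dataclass
class Composition:
    """Monomer frequencies and mmol-per-gram coefficients of one polymer."""

    macromolecule: str                 # protein | dna | rna
    frequencies: Dict[str, float]      # monomer key -> fraction, sums to 1
    coefficients: Dict[str, float]     # monomer key -> mmol per g polymer

    def mass_check(self, monomers: MonomerTable) -> float:
        """sum c_i * residue_mass_i; equals 1000 for a consistent composition."""
        group = monomers.group(self.macromolecule)
        return sum(c * group[k].residue_mass for k, c in self.coefficients.items())


def _finalise(freqs: Dict[str, float], macromolecule: str,
              monomers: MonomerTable) -> Composition:
    group = monomers.group(macromolecule)
    mean_residue = sum(f * group[k].residue_mass for k, f in freqs.items())
    coeffs = {k: 1000.0 * f / mean_residue for k, f in freqs.items()}
    return Composition(macromolecule=macromolecule, frequencies=freqs,
                       coefficients=coeffs)


def protein_composition(
    cds_translations: Sequence[str],
    expression_weights: Optional[Mapping[str, float]] = None,
    monomers: Optional[MonomerTable] = None,
    locus_tags: Optional[Sequence[str]] = None,
) -> Composition:
    """Amino-acid composition of the proteome.

    ``f_i = sum_g w_g * count_i(g) / sum_g w_g * len(g)``; without
    expression weights every protein copy counts once per residue.
    Letters outside the 20 standard codes are skipped with a warning.
    """
    monomers = monomers or MonomerTable.default()
    if not cds_translations:
        raise ValueError("no protein sequences given")
    if locus_tags is None:
        locus_tags = [str(i) for i in range(len(cds_translations))]
    counts = {k: 0.0 for k in monomers.amino_acids}
    total = 0.0
    skipped = set()
    for tag, seq in zip(locus_tags, cds_translations):
        w = 1.0 if expression_weights is None else float(
            expression_weights.get(tag, 1.0)
        )
        if w < 0:
            raise ValueError(f"negative expression weight for {tag}")
        for aa in seq.upper():
            if aa in counts:
                counts[aa] += w
                total += w
            else:
                skipped.add(aa)
    if skipped:
        warnings.warn(f"skipped non-standard residues: {sorted(skipped)}", stacklevel=2)
    if total == 0:
        raise ValueError("all residues have zero weight; cannot form a composition")
    freqs = {k: v / total for k, v in counts.items() if v > 0}
    return _finalise(freqs, "protein", monomers)


def dna_composition(genome: str, monomers: Optional[MonomerTable] = None) -> Composition:
    """dNMP composition counted over both strands, so f_A = f_T and f_G = f_C."""
    monomers = monomers or MonomerTable.default()
    if not genome:
        raise ValueError("empty genome sequence")
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    skipped = set()
    for base in genome.upper():
        if base in counts:
            counts[base] += 1
        else:
            skipped.add(base)
    if skipped:
        warnings.warn(f"skipped ambiguity codes: {sorted(skipped)}", stacklevel=2)
    usable = sum(counts.values())
    if usable == 0:
        raise ValueError("no unambiguous bases in genome sequence")
    at = (counts["A"] + counts["T"]) / (2 * usable)
    gc = (counts["G"] + counts["C"]) / (2 * usable)
    freqs = {k: v for k, v in (("A", at), ("T", at), ("G", gc), ("C", gc)) if v > 0}
    return _finalise(freqs, "dna", monomers)


def rna_composition(
    gene_transcripts: Sequence[str],
    expression_weights: Optional[Mapping[str, float]] = None,
    monomers: Optional[MonomerTable] = None,
    locus_tags: Optional[Sequence[str]] = None,
) -> Composition:
    """NMP composition over single-strand transcripts (T read as U)."""
    monomers = monomers or MonomerTable.default()
    if not gene_transcripts:
        raise ValueError("no transcript sequences given")
    if locus_tags is None:
        locus_tags = [str(i) for i in range(len(gene_transcripts))]
    counts = {"A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0}
    total = 0.0
    skipped = set()
    for tag, seq in zip(locus_tags, gene_transcripts):
        w = 1.0 if expression_weights is None else float(
            expression_weights.get(tag, 1.0)
        )
        if w < 0:
            raise ValueError(f"negative expression weight for {tag}")
        for base in seq.upper().replace("T", "U"):
            if base in counts:
                counts[base] += w
                total += w
            else:
                skipped.add(base)
    if skipped:
        warnings.warn(f"skipped ambiguity codes: {sorted(skipped)}", stacklevel=2)
    if total == 0:
        raise ValueError("all bases have zero weight; cannot form a composition")
    freqs = {k: v / total for k, v in counts.items() if v > 0}
    return _finalise(freqs, "rna", monomers)


# -- templates and reaction emission ------------------------------------------

@dataclass
class BiomassTemplate:
    """Macromolecule mass fractions (g/gDW), GAM and fixed pools."""

    fractions: Dict[str, float]
    gam: float = 0.0                    # mmol ATP per gDW
    fixed_pools: Dict[str, float] = field(default_factory=dict)  # met id -> mmol/gDW consumed
    renormalize: bool = False
    organism_class: str = ""

    def __post_init__(self):
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("macromolecule fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-3:
            if not self.renormalize:
                raise ValueError(
                    f"macromolecule fractions sum to {total:.4f}, not 1 "
                    "(set renormalize to accept)"
                )
            self.fractions = {k: v / total for k, v in self.fractions.items()}

    @classmethod
    def from_yaml(cls, path) -> "BiomassTemplate":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            fractions=dict(raw["fractions"]),
            gam=float(raw.get("gam", 0.0)),
            fixed_pools=dict(raw.get("fixed_pools", {})),
            renormalize=bool(raw.get("renormalize", False)),
            organism_class=raw.get("organism_class", ""),
        )

    @classmethod
    def builtin(cls, organism_class: str) -> "BiomassTemplate":
        """Shipped baseline template: gram_positive, gram_negative,
        fungus or plant.  Baselines only — review before use."""
        ref = resources.files("gsmkit.data") / f"biomass_{organism_class}.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


#: byproduct released per polymerised residue, by macromolecule
DEFAULT_BYPRODUCTS = {"protein": "h2o", "dna": "ppi", "rna": "ppi"}


def build_biomass(
    compositions: Mapping[str, Composition],
    template: BiomassTemplate,
    monomers: Optional[MonomerTable] = None,
    compartment: str = "c",
    byproducts: Optional[Mapping[str, str]] = None,
) -> List[Reaction]:
    """Emit polymerisation pseudo-reactions and the biomass reaction.

    Per macromolecule with a composition: ``sum_i c_i monomer_i -> 1
    e-<Macro> + sum_i c_i byproduct``.  Macromolecule pools without a
    genome-derived composition (lipid, carbohydrate, ...) get a
    placeholder source reaction that the curator must replace.  The
    biomass reaction drains ``m_k`` grams of each pool plus GAM mmol of
    ATP.  Pseudo-species carry the ``e-`` prefix and are skipped by the
    balance auditor.
    """
    monomers = monomers or MonomerTable.default()
    byproducts = dict(DEFAULT_BYPRODUCTS, **(byproducts or {}))
    missing = [m for m in GENOME_DERIVED
               if m in template.fractions and m not in compositions]
    if missing:
        raise ValueError(f"missing composition for macromolecule(s): {missing}")

    def met(met_id: str) -> str:
        return f"{met_id}_{compartment}"

    def pool(macro: str) -> str:
        return met(f"{PSEUDO_PREFIX}{macro.capitalize()}")

    reactions: List[Reaction] = []
    for macro in sorted(template.fractions):
        if macro in compositions:
            comp = compositions[macro]
            group = monomers.group(comp.macromolecule)
            stoich: Dict[str, float] = {}
            total_links = 0.0
            for key, coeff in sorted(comp.coefficients.items()):
                stoich[met(group[key].metabolite_id)] = -coeff
                total_links += coeff
            stoich[pool(macro)] = 1.0
            byproduct = byproducts.get(macro)
            if byproduct:
                stoich[met(byproduct)] = stoich.get(met(byproduct), 0.0) + total_links
            reactions.append(Reaction(
                id=f"{PSEUDO_PREFIX}{macro.capitalize()}_synthesis",
                name=f"{macro} polymerisation (pseudo)",
                stoichiometry=stoich,
            ))
        else:
            # placeholder pool source; curation must supply real precursors
            reactions.append(Reaction(
                id=f"{PSEUDO_PREFIX}{macro.capitalize()}_pool",
                name=f"{macro} pool placeholder (pseudo)",
                stoichiometry={pool(macro): 1.0},
            ))

    biomass_stoich: Dict[str, float] = {}
    for macro, fraction in sorted(template.fractions.items()):
        if fraction > 0:
            biomass_stoich[pool(macro)] = -fraction
    if template.gam > 0:
        for species, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            key = met(species)
            biomass_stoich[key] = biomass_stoich.get(key, 0.0) + sign * template.gam
    for species, coeff in sorted(template.fixed_pools.items()):
        key = met(species)
        biomass_stoich[key] = biomass_stoich.get(key, 0.0) - coeff
    biomass_stoich[met(f"{PSEUDO_PREFIX}Biomass")] = 1.0
    reactions.append(Reaction(
        id="biomass", name="biomass pseudo-reaction", stoichiometry=biomass_stoich,
    ))
    return reactions


__all__ = [
    "Monomer", "MonomerTable", "Composition", "BiomassTemplate",
    "protein_composition", "dna_composition", "rna_composition", "build_biomass",
    "WATER_MASS", "GENOME_DERIVED", "DEFAULT_BYPRODUCTS",
]
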