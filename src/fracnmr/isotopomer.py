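"""Biosynthesis-aware prediction of fractional 13C labeling patterns.

Growing cells on a mixture of uniformly 13C-labeled and unlabeled glucose
produces amino acids whose carbon-carbon bonds are either *intact* (both
carbons from adjacent positions of one precursor molecule, hence co-labeled)
or *broken* (carbons from independent precursor molecules, hence labeled
independently).  This module enumerates the joint 13C/12C state of every
carbon of a residue from a per-amino-acid precursor map and derives bond
statistics, expected CB/CA peak-intensity ratios and methyl multiplet
patterns from that distribution.

The precursor map ships as a plain-text table (``data/pathway_map.tsv``);
see that file for the biochemical provenance of each assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .errors import (
    ExcludedResidueError,
    UndefinedProbabilityError,
    UnknownBondError,
    UnknownResidueError,
)

__all__ = [
    "LabelingScheme",
    "PathwayMap",
    "BondLabelStats",
    "IsotopomerDistribution",
    "enumerate_isotopomers",
    "p_joint_label",
    "conditional_partner_label",
    "bond_stats",
    "predict_cbca_ratio",
    "methyl_multiplet",
    "classify_group",
    "DEFAULT_ATTENUATION",
    "STANDARD_RESIDUES",
]

STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

ONE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: precursor families whose internal bonds are scrambled by TCA-cycle turnover
TCA_FAMILIES = frozenset({"oxaloacetate", "2-oxoglutarate"})

#: covalent carbon-carbon bonds per residue type (C' included via the C-CA bond)
CARBON_SKELETON: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("C", "CA"), ("CA", "CB")),
    "ARG": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")),
    "ASN": (("C", "CA"), ("CA", "CB"), ("CB", "CG")),
    "ASP": (("C", "CA"), ("CA", "CB"), ("CB", "CG")),
    "CYS": (("C", "CA"), ("CA", "CB")),
    "GLN": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")),
    "GLU": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")),
    "GLY": (("C", "CA"),),
    "HIS": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD2")),
    "ILE": (("C", "CA"), ("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"),
            ("CG1", "CD1")),
    "LEU": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
            ("CG", "CD2")),
    "LYS": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"),
            ("CD", "CE")),
    "MET": (("C", "CA"), ("CA", "CB"), ("CB", "CG")),
    "PHE": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
            ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"),
            ("CE2", "CZ")),
    "PRO": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD")),
    "SER": (("C", "CA"), ("CA", "CB")),
    "THR": (("C", "CA"), ("CA", "CB"), ("CB", "CG2")),
    "TRP": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
            ("CG", "CD2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE3", "CZ3"),
            ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")),
    "TYR": (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"),
            ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"),
            ("CE2", "CZ")),
    "VAL": (("C", "CA"), ("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}

#: (residue, stereo descriptor) -> (methyl carbon, attached carbon)
DIASTEREOTOPIC_METHYLS: dict[tuple[str, str], tuple[str, str]] = {
    ("VAL", "pro-R"): ("CG1", "CB"),
    ("VAL", "pro-S"): ("CG2", "CB"),
    ("LEU", "pro-R"): ("CD1", "CG"),
    ("LEU", "pro-S"): ("CD2", "CG"),
}

GROUP_INTACT = "intact-high"
GROUP_TCA = "intermediate-TCA"
GROUP_BROKEN = "broken-low"
GROUP_EXCLUDED = "excluded"

_GROUP_MEMBERS = {
    GROUP_INTACT: ("PHE", "TYR", "ALA", "HIS"),
    GROUP_BROKEN: ("VAL", "LEU", "ILE"),
    GROUP_EXCLUDED: ("GLY", "PRO"),
}

# Per-group intensity attenuation relative to the bare conditional labeling
# probability, calibrated so that at f=0.2 the intact group predicts CB/CA in
# the observed 0.75-0.9 band and the broken group lands near 0.1.  Transfer
# and relaxation losses are not modeled mechanistically.
DEFAULT_ATTENUATION: dict[str, float] = {
    GROUP_INTACT: 0.85,
    GROUP_TCA: 0.55,
    GROUP_BROKEN: 0.50,
}


def _canonical_residue(aa_type: str) -> str:
    aa = str(aa_type).strip().upper()
    if len(aa) == 1:
        aa = ONE_LETTER.get(aa, aa)
    if aa not in STANDARD_RESIDUES:
        raise UnknownResidueError(aa_type)
    return aa


@dataclass(frozen=True)
class LabelingScheme:
    """Parameters of a fractional 13C / uniform 15N labeling experiment.

    Parameters
    ----------
    f_labeled:
        Molar fraction of U-13C6 glucose in the carbon source (0-1).
    nat_abund:
        13C natural abundance applied per carbon of unlabeled precursors.
    scramble:
        TCA-cycle bond-scrambling parameter in [0, 1]; 0 keeps
        oxaloacetate/2-oxoglutarate-derived bonds intact, 1 makes their
        carbons fully independent.  Growth aeration moves this and the
        default 0.5 is a modeling choice, not a measured value.
    isotopic_purity:
        13C enrichment of the labeled glucose.
    """

    f_labeled: float
    nat_abund: float = 0.011
    scramble: float = 0.5
    isotopic_purity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("f_labeled", "nat_abund", "scramble", "isotopic_purity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")

    @property
    def p_full(self) -> float:
        """Probability that a precursor molecule is fully 13C-labeled."""
        return self.f_labeled * self.isotopic_purity

    @property
    def p_site(self) -> float:
        """Marginal 13C probability of any single carbon site."""
        return self.p_full + (1.0 - self.p_full) * self.nat_abund


@dataclass(frozen=True)
class _Site:
    atom: str
    molecule: str
    precursor_carbon: int
    family: str


class PathwayMap:
    """Per-residue carbon precursor origins loaded from a plain-text table."""

    def __init__(self, sites: Mapping[str, tuple[_Site, ...]]):
        self._sites = dict(sites)
        self._validate()

    @classmethod
    def default(cls) -> "PathwayMap":
        """The packaged E. coli glucose-minimal-medium map (cached)."""
        global _DEFAULT_MAP
        if _DEFAULT_MAP is None:
            path = resources.files("fracnmr.data") / "pathway_map.tsv"
            _DEFAULT_MAP = cls.from_table(path.read_text().splitlines())
        return _DEFAULT_MAP

    @classmethod
    def from_table(cls, lines) -> "PathwayMap":
        sites: dict[str, list[_Site]] = {}
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            res, atom, mol, idx, family = line.split("\t")
            sites.setdefault(res, []).append(_Site(atom, mol, int(idx), family))
        return cls({res: tuple(v) for res, v in sites.items()})

    def _validate(self) -> None:
        for res, sites in self._sites.items():
            atoms = [s.atom for s in sites]
            if len(atoms) != len(set(atoms)):
                raise ValueError(f"{res}: duplicate carbon site in pathway map")
            skel = {frozenset(b) for b in CARBON_SKELETON[res]}
            for b in self.intact_bonds(res):
                if frozenset(b) not in skel:
                    raise ValueError(f"{res}: intact bond {b} not a covalent bond")

    def residues(self) -> tuple[str, ...]:
        return tuple(sorted(self._sites))

    def sites(self, aa_type: str) -> tuple[_Site, ...]:
        return self._sites[_canonical_residue(aa_type)]

    def carbons(self, aa_type: str) -> tuple[str, ...]:
        return tuple(s.atom for s in self.sites(aa_type))

    def bonds(self, aa_type: str) -> tuple[tuple[str, str], ...]:
        return CARBON_SKELETON[_canonical_residue(aa_type)]

    def intact_bonds(self, aa_type: str) -> frozenset[frozenset[str]]:
        """Covalent bonds whose carbons are adjacent within one precursor."""
        aa = _canonical_residue(aa_type)
        lookup = {s.atom: s for s in self.sites(aa)}
        out = set()
        for a, b in CARBON_SKELETON[aa]:
            sa, sb = lookup[a], lookup[b]
            if sa.molecule == sb.molecule and abs(
                sa.precursor_carbon - sb.precursor_carbon
            ) == 1:
                out.add(frozenset((a, b)))
        return frozenset(out)


_DEFAULT_MAP: PathwayMap | None = None


@dataclass(frozen=True)
class BondLabelStats:
    """Labeling statistics of one carbon-carbon bond."""

    p_joint: float
    p_conditional: float
    multiplet: Mapping[str, float] = field(default_factory=dict)


class IsotopomerDistribution:
    """Joint 13C/12C distribution over a residue's carbons.

    States are tuples of 0/1 in the order of :attr:`atoms`; probabilities
    sum to one.
    """

    def __init__(self, aa_type: str, atoms: tuple[str, ...],
                 probs: dict[tuple[int, ...], float]):
        self.aa_type = aa_type
        self.atoms = atoms
        self.probs = probs
        self._index = {a: i for i, a in enumerate(atoms)}

    def _idx(self, atom: str) -> int:
        try:
            return self._index[atom]
        except KeyError:
            raise UnknownBondError(self.aa_type, (atom,), []) from None

    def marginal(self, atom: str) -> float:
        """P(atom is 13C)."""
        i = self._idx(atom)
        return sum(p for s, p in self.probs.items() if s[i])

    def joint(self, atom_a: str, atom_b: str) -> float:
        """P(both atoms are 13C)."""
        i, j = self._idx(atom_a), self._idx(atom_b)
        return sum(p for s, p in self.probs.items() if s[i] and s[j])

    def conditional(self, partner: str, reference: str) -> float:
        """P(partner 13C | reference 13C)."""
        m = self.marginal(reference)
        if m <= 0.0:
            raise UndefinedProbabilityError(
                f"{self.aa_type} {reference}: reference carbon has zero "
                "label probability; conditional undefined"
            )
        return self.joint(partner, reference) / m


def _molecule_distribution(k: int, scheme: LabelingScheme,
                           scramble: float) -> dict[tuple[int, ...], float]:
    """Joint label distribution of the k carbons of one precursor molecule.

    A molecule is fully 13C with probability f*purity, otherwise each of its
    carbons is 13C independently at natural abundance.  ``scramble``
    linearly mixes in a fully independent state with per-site marginals
    preserved, modeling TCA-cycle turnover breaking intra-molecule bonds.
    """
    q, a, p = scheme.p_full, scheme.nat_abund, scheme.p_site
    dist: dict[tuple[int, ...], float] = {}
    for state in itertools.product((0, 1), repeat=k):
        ones = sum(state)
        nat = a ** ones * (1.0 - a) ** (k - ones)
        intact = (1.0 - q) * nat + (q if ones == k else 0.0)
        indep = p ** ones * (1.0 - p) ** (k - ones)
        dist[state] = (1.0 - scramble) * intact + scramble * indep
    return dist


def enumerate_isotopomers(
    aa_type: str,
    scheme: LabelingScheme,
    pathway: PathwayMap | None = None,
) -> IsotopomerDistribution:
    """Brute-force enumeration of the residue's carbon label states.

    Precursor molecules are independent; the joint distribution is the
    product of per-molecule distributions (see
    :func:`_molecule_distribution`), with scramble mixing applied to
    oxaloacetate- and 2-oxoglutarate-derived molecules.
    """
    aa = _canonical_residue(aa_type)
    pmap = pathway or PathwayMap.default()
    sites = pmap.sites(aa)
    atoms = tuple(s.atom for s in sites)

    by_mol: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_mol.setdefault(s.molecule, []).append(i)

    probs: dict[tuple[int, ...], float] = {tuple([0] * len(atoms)): 1.0}
    for mol, idxs in by_mol.items():
        family = sites[idxs[0]].family
        s_eff = scheme.scramble if family in TCA_FAMILIES else 0.0
        mdist = _molecule_distribution(len(idxs), scheme, s_eff)
        new: dict[tuple[int, ...], float] = {}
        for state, p0 in probs.items():
            for mstate, pm in mdist.items():
                s = list(state)
                for pos, bit in zip(idxs, mstate):
                    s[pos] = bit
                key = tuple(s)
                new[key] = new.get(key, 0.0) + p0 * pm
        probs = new
    return IsotopomerDistribution(aa, atoms, probs)


def _resolve_bond(aa: str, bond, pmap: PathwayMap) -> tuple[str, str]:
    pair = tuple(bond)
    if len(pair) != 2:
        raise UnknownBondError(aa, pair, CARBON_SKELETON[aa])
    skel = {frozenset(b) for b in CARBON_SKELETON[aa]}
    if frozenset(pair) not in skel:
        raise UnknownBondError(aa, pair, CARBON_SKELETON[aa])
    return pair  # type: ignore[return-value]


def p_joint_label(
    aa_type: str,
    bond,
    scheme: LabelingScheme,
    pathway: PathwayMap | None = None,
) -> float:
    """Probability that both carbons of ``bond`` are 13C.

    For an intact bond with zero natural abundance this equals
    ``f_labeled * purity``; for a bond across two independent precursors it
    equals ``(f_labeled * purity)**2`` - e.g. 4% for valine Cα-Cβ at 20%
    labeling, versus 20% for alanine.
    """
    aa = _canonical_residue(aa_type)
    a, b = _resolve_bond(aa, bond, pathway or PathwayMap.default())
    dist = enumerate_isotopomers(aa, scheme, pathway)
    return dist.joint(a, b)


def conditional_partner_label(
    aa_type: str,
    reference_atom: str,
    partner_atom: str,
    scheme: LabelingScheme,
    pathway: PathwayMap | None = None,
) -> float:
    """P(partner carbon 13C | reference carbon 13C) for a bonded pair."""
    aa = _canonical_residue(aa_type)
    _resolve_bond(aa, (reference_atom, partner_atom), pathway or PathwayMap.default())
    dist = enumerate_isotopomers(aa, scheme, pathway)
    return dist.conditional(partner_atom, reference_atom)


def bond_stats(
    aa_type: str,
    bond,
    scheme: LabelingScheme,
    pathway: PathwayMap | None = None,
) -> BondLabelStats:
    """Joint/conditional labeling and singlet/doublet split for one bond.

    The multiplet refers to the signal of the first atom of ``bond``: its
    doublet fraction is the conditional label probability of the partner.
    """
    aa = _canonical_residue(aa_type)
    ref, partner = _resolve_bond(aa, bond, pathway or PathwayMap.default())
    dist = enumerate_isotopomers(aa, scheme, pathway)
    cond = dist.conditional(partner, ref)
    return BondLabelStats(
        p_joint=dist.joint(ref, partner),
        p_conditional=cond,
        multiplet={"singlet": 1.0 - cond, "doublet": cond},
    )


def classify_group(aa_type: str) -> str:
    """Amino-acid-type group by expected CB/CA behavior.

    Phe/Tyr/Ala/His keep the Cα-Cβ bond intact (highest ratio); Val/Leu/Ile
    break it across precursors (lowest); Gly/Pro are excluded from the
    analysis; everything else is intermediate, dominated by TCA-derived
    types whose bonds scramble with aeration.
    """
    aa = _canonical_residue(aa_type)
    for group, members in _GROUP_MEMBERS.items():
        if aa in members:
            return group
    return GROUP_TCA


def _attenuation_factor(aa: str, attenuation) -> float:
    if attenuation is None:
        attenuation = DEFAULT_ATTENUATION
    if isinstance(attenuation, (int, float)):
        return float(attenuation)
    return float(attenuation[classify_group(aa)])


def predict_cbca_ratio(
    aa_type: str,
    scheme: LabelingScheme,
    attenuation=None,
    pathway: PathwayMap | None = None,
) -> float:
    """Expected intra-residue CB/CA peak intensity ratio.

    The Cβ peak requires magnetization transfer across the Cα-Cβ bond, so
    its intensity relative to the Cα reference peak scales with
    P(Cβ 13C | Cα 13C), times a per-group attenuation accounting for
    relaxation and transfer losses (``attenuation`` may be a scalar, a
    mapping from group name to factor, or None for the calibrated default).
    """
    aa = _canonical_residue(aa_type)
    if aa in ("GLY", "PRO"):
        raise ExcludedResidueError(
            f"{aa} excluded by construction: "
            + ("no CB carbon" if aa == "GLY" else "no amide proton")
        )
    cond = conditional_partner_label(aa, "CA", "CB", scheme, pathway)
    return cond * _attenuation_factor(aa, attenuation)


def methyl_multiplet(
    aa_type: str,
    methyl: str,
    scheme: LabelingScheme,
    pathway: PathwayMap | None = None,
) -> dict[str, float]:
    """Singlet/doublet fractions of a Val/Leu methyl 13C signal.

    The doublet fraction equals the conditional label probability of the
    attached carbon given the methyl is 13C.  The pro-R methyl remains
    bonded to its biosynthetic neighbor (doublet at any labeling fraction);
    the pro-S methyl sits across two precursor molecules.
    """
    aa = _canonical_residue(aa_type)
    key = (aa, methyl)
    if key not in DIASTEREOTOPIC_METHYLS:
        if aa not in ("VAL", "LEU"):
            raise ExcludedResidueError(
                f"{aa} has no diastereotopic methyl pair (only VAL and LEU do)"
            )
        raise ValueError(f"methyl must be 'pro-R' or 'pro-S', got {methyl!r}")
    methyl_c, attached_c = DIASTEREOTOPIC_METHYLS[key]
    dist = enumerate_isotopomers(aa, scheme, pathway)
    doublet = dist.conditional(attached_c, methyl_c)
    return {"singlet": 1.0 - doublet, "doublet": doublet}
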