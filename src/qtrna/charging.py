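"""Variant-peptide prediction and amino-acid occupancy from chromatogram areas.

Which amino acid a qtRNA delivers is read out by translating a reporter
protein (sfGFP with a quadruplet codon at permissive residue 151),
trypsin-digesting it, and quantifying the 20 possible variant peptides
that straddle the reporter site.  This module predicts that 20-member
peptide database (sequence + monoisotopic mass) and converts extracted
ion chromatogram areas into fractional residue occupancy, with
limit-of-detection censoring and a charging classification
(selective-cognate / selective-noncognate / promiscuous).

Quantification consumes a feature table (peptide key or observed mass,
area under the curve); spectral search and peak picking are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pt_mass

from .aa import AA_LETTERS

WATER_MONO = 18.010565  # Da

#: sfGFP (superfolder GFP) amino-acid sequence; residue 151 (1-based) is
#: the permissive tyrosine replaced by the quadruplet codon in the
#: charging reporter.
SFGFP = (
    "MSKGEELFTGVVPILVELDGDVNGHKFSVRGEGEGDATNGKLTLKFICTTGKLPVPWPTLVTTLTYGVQ"
    "CFSRYPDHMKRHDFFKSAMPEGYVQERTISFKDDGTYKTRAEVKFEGDTLVNRIELKGIDFKEDGNILG"
    "HKLEYNFNSHNVYITADKQKNGIKANFKIRHNVEDGSVQLADHYQQNTPIGDGPVLLPDNHYLSTQSVL"
    "SKDPNEKRDHMVLLEFVTAAGITHGMDELYK"
)
SFGFP_REPORTER_SITE = 151


class ChargingClass:  # kept as plain strings for easy serialization
    SELECTIVE_COGNATE = "SELECTIVE_COGNATE"
    SELECTIVE_NONCOGNATE = "SELECTIVE_NONCOGNATE"
    PROMISCUOUS = "PROMISCUOUS"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class ProteinVariantPeptide:
    """The tryptic peptide straddling the reporter site for one variant."""

    variant: str               # one-letter amino acid at the site
    peptide: str
    mass: float                # monoisotopic, Da
    site_position: int         # 1-based position of the site within peptide
    start: int                 # 0-based peptide start in the variant protein
    end: int                   # 0-based exclusive end
    digest_altering: bool      # peptide boundaries differ from reference


@dataclass(frozen=True)
class ChromatogramFeature:
    """One extracted-ion-chromatogram feature: a key or mass, plus its area."""

    auc: float
    key: str | None = None       # variant letter or peptide sequence
    observed_mass: float | None = None

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValueError("AUC must be non-negative")
        if self.key is None and self.observed_mass is None:
            raise ValueError("feature needs a key or an observed mass")


@dataclass
class OccupancyResult:
    """Fractional occupancy of the reporter site across detected variants.

    Keys are variant letters, or slash-joined groups (e.g. ``I/L``) when
    mass-only assignment cannot distinguish isobaric variants.
    """

    fractions: dict[str, float]
    detected: set[str]
    below_lod: set[str]
    ambiguity_groups: list[tuple[str, ...]]
    unassigned_auc: float = 0.0
    classification: str = ChargingClass.UNDETERMINED


def peptide_mass(peptide: str, fixed_mods: Mapping[str, float] | None = None
                 ) -> float:
    """Monoisotopic peptide mass: residue masses plus one water.

    *fixed_mods* adds a constant mass offset (Da) per occurrence of a
    residue, e.g. ``{"C": 57.02146}`` for carbamidomethyl cysteine.
    """
    peptide = peptide.upper()
    for i, ch in enumerate(peptide):
        if ch not in AA_LETTERS:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
    if not peptide:
        return WATER_MONO
    m = float(_pt_mass.calculate_mass(sequence=peptide))
    if fixed_mods:
        m += sum(fixed_mods.get(ch, 0.0) for ch in peptide)
    return m


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic peptides of *protein*, in N-to-C order.

    Cleaves C-terminal to K or R except when the next residue is P.  With
    ``missed_cleavages = m``, merged peptides spanning up to m junctions
    are appended after the fully cleaved set.  The 0-missed-cleavage
    peptides concatenate back to the input.
    """
    protein = protein.upper()
    for i, ch in enumerate(protein):
        if ch not in AA_LETTERS:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
    if not protein:
        return []
    cuts = [0]
    for i, ch in enumerate(protein[:-1]):
        if ch in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    base = [protein[a:b] for a, b in zip(cuts, cuts[1:])]
    peptides = list(base)
    for m in range(1, missed_cleavages + 1):
        for j in range(len(base) - m):
            peptides.append("".join(base[j : j + m + 1]))
    return peptides


def _straddling_peptide(protein: str, site_index: int) -> tuple[int, int]:
    """0-based [start, end) of the 0-missed-cleavage peptide containing site."""
    pos = 0
    for pep in tryptic_digest(protein):
        if pos <= site_index < pos + len(pep):
            return pos, pos + len(pep)
        pos += len(pep)
    raise AssertionError("site not covered by digest")  # unreachable


def variant_peptides(
    protein: str,
    site: int,
    variants: Iterable[str] = AA_LETTERS,
    fixed_mods: Mapping[str, float] | None = None,
) -> list[ProteinVariantPeptide]:
    """Predicted straddling peptides for every amino acid at *site* (1-based).

    Each variant is substituted into the protein and the tryptic peptide
    containing the site is reported.  When the substitution creates or
    destroys a cleavage site (e.g. a K/R variant), the peptide boundaries
    change and ``digest_altering`` is set: AUC comparisons across such
    peptides mix different ionization efficiencies, which this pipeline
    does not correct for.
    """
    protein = protein.upper()
    if not 1 <= site <= len(protein):
        raise ValueError(f"site {site} outside protein of length {len(protein)}")
    idx = site - 1
    ref_bounds = _straddling_peptide(protein, idx)
    out = []
    for v in variants:
        v = v.upper()
        if v not in AA_LETTERS:
            raise ValueError(f"unknown variant residue {v!r}")
        prot_v = protein[:idx] + v + protein[idx + 1 :]
        start, end = _straddling_peptide(prot_v, idx)
        pep = prot_v[start:end]
        out.append(
            ProteinVariantPeptide(
                variant=v,
                peptide=pep,
                mass=peptide_mass(pep, fixed_mods),
                site_position=idx - start + 1,
                start=start,
                end=end,
                digest_altering=(start, end) != ref_bounds,
            )
        )
    return out


def ambiguity_groups(
    variants: Sequence[ProteinVariantPeptide], mass_tol_ppm: float = 10.0
) -> list[tuple[str, ...]]:
    """Group variants whose peptide masses are indistinguishable.

    Transitive closure of pairwise agreement within *mass_tol_ppm*; Leu
    and Ile (identical residue masses) always group together.
    """
    ordered = sorted(variants, key=lambda v: v.mass)
    groups: list[list[ProteinVariantPeptide]] = []
    for v in ordered:
        if groups and abs(v.mass - groups[-1][-1].mass) <= \
                mass_tol_ppm * 1e-6 * groups[-1][-1].mass:
            groups[-1].append(v)
        else:
            groups.append([v])
    return [tuple(sorted(x.variant for x in g)) for g in groups]


def _group_label(group: tuple[str, ...]) -> str:
    return "/".join(group)


def quantify_occupancy(
    features: Sequence[ChromatogramFeature],
    variants: Sequence[ProteinVariantPeptide],
    lod: float = 1e4,
    mass_tol_ppm: float = 10.0,
) -> OccupancyResult:
    """Fractional site occupancy from chromatogram feature areas.

    Features below *lod* (the instrument's lower AUC limit, 1e4 AU by
    default) are censored.  Remaining features are assigned to variants by
    key (variant letter or peptide sequence) or, when only a mass is
    given, to the ambiguity group of variants within *mass_tol_ppm*.
    Fractions are each label's AUC over the total detected AUC, so they
    sum to 1 over the detected set.
    """
    if not variants:
        raise ValueError("no variant peptides supplied")
    groups = ambiguity_groups(variants, mass_tol_ppm)
    by_letter = {v.variant: v for v in variants}
    by_peptide = {v.peptide: v for v in variants}
    group_of = {v: g for g in groups for v in g}

    auc: dict[str, float] = {}
    below: set[str] = set()
    unassigned = 0.0
    for f in features:
        label: str | None = None
        if f.key is not None:
            key = f.key.upper()
            if key in by_letter:
                label = key
            elif key in by_peptide:
                label = by_peptide[key].variant
        elif f.observed_mass is not None:
            matched = [
                v.variant for v in variants
                if abs(v.mass - f.observed_mass) <= mass_tol_ppm * 1e-6 * v.mass
            ]
            if matched:
                g = group_of[matched[0]]
                label = _group_label(g) if len(g) > 1 else matched[0]
        if label is None:
            unassigned += f.auc
            continue
        if f.auc < lod:
            below.add(label)
            continue
        auc[label] = auc.get(label, 0.0) + f.auc

    total = sum(auc.values())
    fractions = {k: v / total for k, v in auc.items()} if total > 0 else {}
    return OccupancyResult(
        fractions=fractions,
        detected=set(fractions),
        below_lod=below - set(fractions),
        ambiguity_groups=[g for g in groups if len(g) > 1],
        unassigned_auc=unassigned,
    )


def classify_charging(
    occupancy: OccupancyResult,
    cognate: str,
    selectivity_threshold: float = 0.75,
    minor_threshold: float = 0.2,
) -> str:
    """Classify a qtRNA's charging profile from its occupancy result.

    SELECTIVE_COGNATE when the cognate amino acid carries at least the
    selectivity threshold of the detected signal; SELECTIVE_NONCOGNATE
    when a single other variant does; PROMISCUOUS when two or more
    variants each exceed the minor threshold; otherwise UNDETERMINED.  A
    slash-joined ambiguity group counts as cognate when it contains the
    cognate letter.  The result is also stored on ``occupancy``.
    """
    cognate = cognate.upper()

    def is_cognate(label: str) -> bool:
        return cognate in label.split("/")

    fr = occupancy.fractions
    label = ChargingClass.UNDETERMINED
    if fr:
        cog = sum(v for k, v in fr.items() if is_cognate(k))
        others = {k: v for k, v in fr.items() if not is_cognate(k)}
        if cog >= selectivity_threshold:
            label = ChargingClass.SELECTIVE_COGNATE
        elif any(v >= selectivity_threshold for v in others.values()):
            label = ChargingClass.SELECTIVE_NONCOGNATE
        elif sum(v >= minor_threshold for v in fr.values()) >= 2:
            label = ChargingClass.PROMISCUOUS
    occupancy.classification = label
    return label
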