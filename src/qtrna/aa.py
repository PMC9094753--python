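"""Amino-acid code tables shared across the package.

The scaffold registry tracks 21 tRNA species: one per canonical amino acid
plus the initiator methionine, which is carried as the distinct label
``fMet`` (it is charged with methionine but is a separate tRNA gene).
"""

from __future__ import annotations

# Canonical 20, three-letter -> one-letter
THREE_TO_ONE: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Valid scaffold amino-acid labels: the canonical 20 plus initiator Met.
SCAFFOLD_AMINO_ACIDS: tuple[str, ...] = tuple(THREE_TO_ONE) + ("fMet",)

#: One-letter alphabet of the canonical amino acids.
AA_LETTERS: str = "ACDEFGHIKLMNPQRSTVWY"


def normalize_amino_acid(aa: str) -> str:
    """Return the canonical three-letter label (or ``fMet``) for *aa*.

    Accepts three-letter labels (case-insensitive first letter), ``fMet``,
    or one-letter codes.
    """
    if aa == "fMet" or aa.lower() == "fmet":
        return "fMet"
    cap = aa.capitalize()
    if cap in THREE_TO_ONE:
        return cap
    if len(aa) == 1 and aa.upper() in ONE_TO_THREE:
        return ONE_TO_THREE[aa.upper()]
    raise ValueError(f"unknown amino acid label: {aa!r}")


def one_letter(aa: str) -> str:
    """One-letter code for a scaffold amino-acid label (fMet -> M)."""
    label = normalize_amino_acid(aa)
    return "M" if label == "fMet" else THREE_TO_ONE[label]
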