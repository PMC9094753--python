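"""Default scaffold registry: one tRNA per isoacceptor class plus fMet.

The anticodons follow the first-listed E. coli tRNA gene of each
isoacceptor class; the sequences themselves are deterministic synthetic
stand-ins from :func:`qtrna.simulate.make_toy_scaffold` (curated genomic
tRNA bodies are not bundled), which is sufficient for every design and
library operation since those act only on the annotated anticodon loop.
"""

from __future__ import annotations

from .design import TRNAScaffold
from .simulate import make_toy_scaffold

#: Triplet anticodons (RNA, 5'->3') per scaffold amino-acid label.
CANONICAL_ANTICODONS: dict[str, str] = {
    "Ala": "UGC",
    "Arg": "ACG",
    "Asn": "GUU",
    "Asp": "GUC",
    "Cys": "GCA",
    "Gln": "CUG",
    "Glu": "UUC",
    "Gly": "CCC",
    "His": "GUG",
    "Ile": "GAU",
    "Leu": "CAG",
    "Lys": "UUU",
    "Met": "CAU",
    "Phe": "GAA",
    "Pro": "CGG",
    "Ser": "CGA",
    "Thr": "CGU",
    "Trp": "CCA",
    "Tyr": "GUA",
    "Val": "UAC",
    "fMet": "CAU",
}


def default_scaffold_registry() -> dict[str, TRNAScaffold]:
    """All 21 default scaffolds (20 canonical amino acids + initiator Met),
    keyed by amino-acid label."""
    return {
        aa: make_toy_scaffold(aa, anticodon, scaffold_id=f"tRNA-{aa}")
        for aa, anticodon in CANONICAL_ANTICODONS.items()
    }


def elongator_scaffolds() -> list[TRNAScaffold]:
    """The 20 elongator scaffolds (fMet excluded), in registry order."""
    return [s for aa, s in default_scaffold_registry().items() if aa != "fMet"]
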