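"""qtRNA sequence design and degenerate-library enumeration.

A quadruplet tRNA (qtRNA) is built from an annotated triplet tRNA
"scaffold" by replacing the three-nucleotide anticodon (tRNA positions
34-36) with a four-nucleotide anticodon (positions 34, 35, 35.5, 36) that
is the reverse complement of a chosen four-base mRNA codon.  Codons and
mRNA are handled in the DNA alphabet, tRNA sequences in the RNA alphabet;
the only conversion is T<->U at the codon/anticodon boundary.

All sequence indices are 0-based with half-open windows.  tRNA position
labels (32...38) are annotations supplied with the scaffold; this module
never predicts cloverleaf structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .aa import normalize_amino_acid

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

#: The eight quadruplet codons used to challenge the NNNN anticodon
#: libraries: six point-insertion (XYZZ) codons plus two arginine-like
#: codons.
NNNN_SELECTION_CODONS: tuple[str, ...] = (
    "CGTT", "GGGG", "CCGG", "CAGG", "TCGG", "ACGG", "AGGG", "CGGT",
)


class AlphabetError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


def _check_alphabet(seq: str, alphabet: str, what: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise AlphabetError(
                f"{what} contains non-{alphabet} character {ch!r} at position {i}"
            )


def dna_to_rna(seq: str) -> str:
    """Transcribe the coding-strand DNA string to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    """Back-transcribe an RNA string to its gene (coding-strand) DNA."""
    return seq.upper().replace("U", "T")


def codon_to_anticodon(codon: str) -> str:
    """Reverse-complement a DNA codon into the pairing RNA anticodon, 5'->3'.

    Works for any codon length; the qtRNA workflow uses length-4 codons
    (e.g. ``TAGA`` -> ``UCUA``).
    """
    codon = codon.upper()
    _check_alphabet(codon, DNA_BASES, "codon")
    return dna_to_rna(str(Seq(codon).reverse_complement()))


def anticodon_to_codon(anticodon: str) -> str:
    """Inverse of :func:`codon_to_anticodon`: RNA anticodon -> DNA codon."""
    anticodon = anticodon.upper()
    _check_alphabet(anticodon, RNA_BASES, "anticodon")
    return str(Seq(rna_to_dna(anticodon)).reverse_complement())


def make_point_insertion_codons(triplet: str) -> tuple[str, str, bool]:
    """Quadruplet codons reachable from a triplet codon by one insertion.

    For a triplet ``XYZ`` returns ``(XYZZ, XYYZ, same)`` where ``XYZZ``
    duplicates the third base, ``XYYZ`` duplicates the second, and
    ``same`` is True when the two coincide (e.g. ``GGG`` -> ``GGGG``).
    """
    triplet = triplet.upper()
    if len(triplet) != 3:
        raise ValueError(f"expected a triplet codon, got {triplet!r}")
    _check_alphabet(triplet, DNA_BASES, "triplet codon")
    x, y, z = triplet
    xyzz = x + y + z + z
    xyyz = x + y + y + z
    return xyzz, xyyz, xyzz == xyyz


@dataclass(frozen=True)
class TRNAScaffold:
    """An annotated triplet tRNA used as the substrate for qtRNA design.

    Parameters
    ----------
    id : str
        Short label, e.g. ``serU``.
    amino_acid : str
        Three-letter amino-acid label or ``fMet``.
    sequence : str
        Full tRNA sequence 5'->3' in the RNA alphabet.
    anticodon_start : int
        0-based index of tRNA position 34 (first anticodon base).
    pos32_index : int
        0-based index of tRNA position 32 (5' anticodon-loop side).

    Positions 37 and 38 (3' loop side) sit immediately after the triplet
    anticodon and are derived, not stored.
    """

    id: str
    amino_acid: str
    sequence: str
    anticodon_start: int
    pos32_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(
            self, "amino_acid", normalize_amino_acid(self.amino_acid)
        )
        _check_alphabet(self.sequence, RNA_BASES, f"scaffold {self.id} sequence")
        n = len(self.sequence)
        if not (0 <= self.anticodon_start and self.anticodon_start + 2 < n):
            raise ValueError(
                f"scaffold {self.id}: anticodon window [{self.anticodon_start},"
                f" {self.anticodon_start + 3}) out of range for length {n}"
            )
        if not 0 <= self.pos32_index < self.anticodon_start:
            raise ValueError(
                f"scaffold {self.id}: position-32 index {self.pos32_index} must "
                f"precede the anticodon at {self.anticodon_start}"
            )
        if self.pos38_index >= n:
            raise ValueError(f"scaffold {self.id}: position 38 beyond sequence end")

    @property
    def pos37_index(self) -> int:
        return self.anticodon_start + 3

    @property
    def pos38_index(self) -> int:
        return self.anticodon_start + 4

    @property
    def anticodon(self) -> str:
        """The triplet anticodon, 5'->3' RNA."""
        return self.sequence[self.anticodon_start : self.anticodon_start + 3]

    @property
    def codon(self) -> str:
        """The decoded triplet codon (DNA, mRNA sense)."""
        return anticodon_to_codon(self.anticodon)


@dataclass(frozen=True)
class QtRNA:
    """An engineered quadruplet-anticodon tRNA variant.

    ``sequence`` equals the scaffold with its triplet anticodon replaced by
    the four-base anticodon (net +1 length) and, optionally, the loop-side
    positions 32/37/38 overwritten.  Because of the insertion, positions 37
    and 38 shift by +1 relative to the scaffold.
    """

    scaffold_id: str
    amino_acid: str
    codon: str
    anticodon: str
    sequence: str
    anticodon_start: int
    pos32_index: int

    @property
    def pos37_index(self) -> int:
        return self.anticodon_start + 4

    @property
    def pos38_index(self) -> int:
        return self.anticodon_start + 5

    @property
    def loop_sides(self) -> tuple[str, str, str]:
        """Bases at positions 32, 37, 38 of the qtRNA."""
        s = self.sequence
        return (s[self.pos32_index], s[self.pos37_index], s[self.pos38_index])

    @property
    def name(self) -> str:
        """Plain-text label, e.g. ``qtRNA-Ser-TAGA``."""
        return f"qtRNA-{self.amino_acid}-{self.codon}"


def build_qtrna(
    scaffold: TRNAScaffold,
    codon: str,
    loop_sides: Sequence[str] | None = None,
) -> QtRNA:
    """Construct a qtRNA decoding *codon* from a triplet scaffold.

    The three-base anticodon window is replaced by
    :func:`codon_to_anticodon` of the four-base codon; every other base is
    preserved unless *loop_sides* (RNA bases for positions 32, 37, 38)
    overwrites the anticodon-loop sides.
    """
    codon = codon.upper()
    if len(codon) != 4:
        raise ValueError(f"qtRNA codon must have length 4, got {codon!r}")
    anticodon = codon_to_anticodon(codon)
    start = scaffold.anticodon_start
    seq = scaffold.sequence[:start] + anticodon + scaffold.sequence[start + 3 :]
    if loop_sides is not None:
        if len(loop_sides) != 3:
            raise ValueError("loop_sides must give bases for positions 32, 37, 38")
        b32, b37, b38 = (b.upper() for b in loop_sides)
        for b in (b32, b37, b38):
            _check_alphabet(b, RNA_BASES, "loop-side base")
        chars = list(seq)
        chars[scaffold.pos32_index] = b32
        chars[start + 4] = b37
        chars[start + 5] = b38
        seq = "".join(chars)
    return QtRNA(
        scaffold_id=scaffold.id,
        amino_acid=scaffold.amino_acid,
        codon=codon,
        anticodon=anticodon,
        sequence=seq,
        anticodon_start=start,
        pos32_index=scaffold.pos32_index,
    )


class LibraryMode(str, Enum):
    """Which positions a degenerate qtRNA library randomizes."""

    ANTICODON_NNNN = "nnnn"          # positions 34, 35, 35.5, 36 (4^4 = 256)
    LOOP_SIDES_32_37_38 = "loopsides"  # positions 32, 37, 38      (4^3 = 64)


@dataclass(frozen=True)
class DegenerateLibrary:
    """An enumerated degenerate qtRNA library.

    ``members`` maps the randomized bases (DNA, gene sense, in window
    order) to the full variant tRNA sequence (RNA).  ``flank_5`` /
    ``flank_3`` are the constant gene-sense DNA sequences bounding the
    randomized window, recorded for exact-match read extraction;
    ``randomized_offsets`` are the offsets of the randomized bases within
    the window (the loop-side window also spans the constant anticodon).
    """

    scaffold_id: str
    mode: LibraryMode
    members: dict[str, str]
    flank_5: str
    flank_3: str
    window_start: int
    window_length: int
    randomized_offsets: tuple[int, ...]
    position_labels: tuple[str, ...]
    codon: str | None = None

    def __len__(self) -> int:
        return len(self.members)

    def member_window(self, key: str) -> str:
        """Gene-sense DNA window for a member (what a read contains)."""
        seq = self.members[key]
        return rna_to_dna(
            seq[self.window_start : self.window_start + self.window_length]
        )


def enumerate_library(
    scaffold: TRNAScaffold,
    mode: LibraryMode | str,
    codon: str | None = None,
    flank_length: int = 10,
) -> DegenerateLibrary:
    """Enumerate every member of a degenerate qtRNA library.

    ``ANTICODON_NNNN`` randomizes the four anticodon bases (34, 35, 35.5,
    36) of the scaffold, yielding all 256 quadruplet anticodons.
    ``LOOP_SIDES_32_37_38`` randomizes the three anticodon-loop side
    positions of the qtRNA built for *codon* (required in that mode),
    yielding 64 members.  Only fully degenerate (N) windows are supported;
    member keys are the randomized bases in gene-sense DNA.
    """
    mode = LibraryMode(mode)
    if mode is LibraryMode.ANTICODON_NNNN:
        start = scaffold.anticodon_start
        base_seq = scaffold.sequence
        # replace the 3-nt anticodon with each 4-nt window
        members = {
            "".join(bases): base_seq[:start]
            + dna_to_rna("".join(bases))
            + base_seq[start + 3 :]
            for bases in itertools.product(DNA_BASES, repeat=4)
        }
        window_start, window_length = start, 4
        offsets: tuple[int, ...] = (0, 1, 2, 3)
        labels = ("34", "35", "35.5", "36")
        ref_seq = next(iter(members.values()))
    elif mode is LibraryMode.LOOP_SIDES_32_37_38:
        if codon is None:
            raise ValueError(
                "LOOP_SIDES_32_37_38 libraries diversify a qtRNA; pass the "
                "quadruplet codon the base qtRNA decodes"
            )
        base = build_qtrna(scaffold, codon)
        i32, i37, i38 = base.pos32_index, base.pos37_index, base.pos38_index
        window_start = i32
        window_length = i38 - i32 + 1
        offsets = (0, i37 - i32, i38 - i32)
        labels = ("32", "37", "38")
        members = {}
        for bases in itertools.product(DNA_BASES, repeat=3):
            chars = list(base.sequence)
            for off, b in zip(offsets, bases):
                chars[window_start + off] = dna_to_rna(b)
            members["".join(bases)] = "".join(chars)
        ref_seq = base.sequence
    else:  # pragma: no cover - LibraryMode() already rejects unknown modes
        raise ValueError(f"unknown library mode: {mode!r}")

    flank_5 = rna_to_dna(ref_seq[max(0, window_start - flank_length) : window_start])
    end = window_start + window_length
    flank_3 = rna_to_dna(ref_seq[end : end + flank_length])
    return DegenerateLibrary(
        scaffold_id=scaffold.id,
        mode=mode,
        members=members,
        flank_5=flank_5,
        flank_3=flank_3,
        window_start=window_start,
        window_length=window_length,
        randomized_offsets=offsets,
        position_labels=labels,
        codon=codon,
    )


def selection_matrix(
    scaffolds: Sequence[TRNAScaffold], codons: Sequence[str]
) -> list[tuple[TRNAScaffold, str]]:
    """Cross every scaffold library with every reporter codon.

    Returns the full Cartesian product, the layout of a library-by-codon
    selection campaign (20 scaffolds x 8 codons = 160 selections).
    """
    if not scaffolds or not codons:
        raise ValueError("selection_matrix requires non-empty scaffold and codon lists")
    return [(s, c) for s in scaffolds for c in codons]


def find_decodable_codons(
    mrna: str, anticodon: str, match_mode: str = "full"
) -> list[int]:
    """Positions in *mrna* where a qtRNA anticodon could decode a codon.

    ``full`` requires the whole four-base codon to match; ``first_three``
    requires agreement only at the codon's first three bases, the
    crosstalk regime in which qtRNAs tolerate a fourth-base mismatch.
    Returns 0-based start positions; an mRNA shorter than 4 nt yields [].
    """
    mrna = mrna.upper()
    _check_alphabet(mrna, DNA_BASES, "mRNA")
    if match_mode not in ("full", "first_three"):
        raise ValueError(f"match_mode must be 'full' or 'first_three', got {match_mode!r}")
    codon = anticodon_to_codon(anticodon)
    if len(codon) != 4:
        raise ValueError("find_decodable_codons expects a quadruplet anticodon")
    target = codon if match_mode == "full" else codon[:3]
    hits = []
    for p in range(len(mrna) - 3):
        if mrna[p : p + len(target)] == target:
            hits.append(p)
    return hits
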