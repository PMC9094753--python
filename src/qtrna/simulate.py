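"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one experimental regime of the qtRNA workflow:

* kinetic plates — logistic growth with induction-dependent toxicity and
  luminescence proportional to OD times readthrough efficiency, with
  multiplicative log-normal noise;
* selection read sets — uniform pre-selection and weighted multinomial
  post-selection reads over a degenerate library, with constant flanks;
* chromatogram features — AUC vectors drawn from a configured occupancy
  with log-normal noise (limit-of-detection censoring is left to the
  quantifier);
* toy tRNA scaffolds — deterministic annotated sequences standing in for
  curated genomic tRNA genes.

A single seed fans out to independent substreams via
``numpy.random.SeedSequence.spawn``, so every output is bit-reproducible
and the modules can be exercised independently.  The luminescence model
is a testing instrument, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .charging import ChromatogramFeature
from .design import (
    DNA_BASES,
    DegenerateLibrary,
    TRNAScaffold,
    dna_to_rna,
)
from .kinetics import (
    INDUCED,
    QUAD,
    TRIPLET_CONTROL,
    UNINDUCED,
    PlateKinetics,
    WellSeries,
)


@dataclass
class GrowthConfig:
    """Logistic growth parameters.

    Defaults emulate an overnight culture diluted 1:500 into rich medium
    and grown for 8 h: starting OD 0.01, rate 0.9 per hour, carrying
    capacity 1.2.  ``toxicity`` in [0, 1] scales the induced-well growth
    rate by (1 - toxicity).
    """

    od0: float = 0.01
    rate: float = 0.9           # per hour
    capacity: float = 1.2
    toxicity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.toxicity <= 1.0:
            raise ValueError("toxicity must lie in [0, 1]")


@dataclass
class LuminescenceConfig:
    """Reporter luminescence model: background + amplitude * eff * OD."""

    triplet_amplitude: float = 2e5   # AU at OD 1 for the all-triplet control
    efficiency: float = 0.1          # fractional readthrough of the quad reporter
    background: float = 50.0         # AU
    noise_cv: float = 0.05


@dataclass
class SimConfig:
    """Bundle of generator settings sharing one master seed."""

    seed: int = 0
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    luminescence: LuminescenceConfig = field(default_factory=LuminescenceConfig)


def _substream(seed: int, index: int) -> np.random.Generator:
    """Independent child RNG *index* of the master *seed*."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def logistic_od(t: np.ndarray, od0: float, rate: float, capacity: float
                ) -> np.ndarray:
    """OD(t) = K / (1 + ((K - od0)/od0) * exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return capacity / (1.0 + ((capacity - od0) / od0) * np.exp(-rate * t))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int
                      ) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_plate(
    config: SimConfig,
    n_replicates: int = 8,
    duration_h: float = 8.0,
    interval_h: float = 1 / 6,
    qtrna: str = "qtRNA-Ser-TAGA",
    codon: str = "TAGA",
) -> PlateKinetics:
    """Simulate a kinetic readthrough plate with known ground truth.

    Generates, per replicate: a triplet-control well (uninduced), a
    quad-reporter induced well (effective efficiency as configured, growth
    slowed by toxicity) and a quad-reporter uninduced well (efficiency 0).
    Time grid: every 10 min over 8 h by default.
    """
    g, l = config.growth, config.luminescence
    rng = _substream(config.seed, 0)
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    wells = []

    def add_well(reporter: str, induction: str, rep: int, eff: float,
                 rate: float) -> None:
        od = logistic_od(times, g.od0, rate, g.capacity)
        lum = l.background + l.triplet_amplitude * eff * od
        lum = lum * _lognormal_factor(rng, l.noise_cv, len(times))
        wells.append(
            WellSeries(
                times=times, od600=od, luminescence=lum,
                reporter=reporter, induction=induction,
                replicate=f"r{rep}", qtrna=qtrna, codon=codon,
                well=f"{reporter[:4]}-{induction[:3]}-r{rep}",
            )
        )

    induced_rate = g.rate * (1.0 - g.toxicity)
    for rep in range(1, n_replicates + 1):
        add_well(TRIPLET_CONTROL, UNINDUCED, rep, 1.0, g.rate)
        add_well(QUAD, INDUCED, rep, l.efficiency, induced_rate)
        add_well(QUAD, UNINDUCED, rep, 0.0, g.rate)
    return PlateKinetics(wells=wells)


#: Default concentration of the Dirichlet enrichment weights.  Phage
#: selections are strongly winner-take-most, so the emulated weight
#: vectors are sparse and heavy-tailed (alpha < 1).
DEFAULT_DIRICHLET_ALPHA = 0.5


def dirichlet_weights(n_members: int, alpha: float = DEFAULT_DIRICHLET_ALPHA,
                      seed: int = 0) -> np.ndarray:
    """Random post-selection enrichment weights over a library."""
    rng = _substream(seed, 3)
    return rng.dirichlet([alpha] * n_members)


def simulate_selection_reads(
    library: DegenerateLibrary,
    weights: Sequence[float] | Mapping[str, float],
    depth: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simulate pre- and post-selection read sets over a library.

    Pre-selection reads are multinomial-uniform over the members;
    post-selection reads are multinomial with the given enrichment
    weights (keyed like the library, or in sorted-key order).  Each read
    is flank5 + member window + flank3.  ``error_rate`` optionally applies
    per-base uniform substitutions to exercise discard accounting.
    Exactly *depth* reads are emitted per phase.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    keys = sorted(library.members)
    if isinstance(weights, Mapping):
        w = np.array([weights[k] for k in keys], dtype=float)
    else:
        w = np.asarray(list(weights), dtype=float)
    if len(w) != len(keys):
        raise ValueError("need one weight per library member")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    rng = _substream(seed, 1)

    def phase_reads(p: np.ndarray, tag: str) -> list[SeqRecord]:
        counts = rng.multinomial(depth, p)
        records = []
        i = 0
        for key, c in zip(keys, counts):
            window = library.member_window(key)
            for _ in range(c):
                seq = library.flank_5 + window + library.flank_3
                if error_rate > 0:
                    seq = _mutate(seq, error_rate, rng)
                records.append(
                    SeqRecord(
                        Seq(seq), id=f"{tag}_{i}", description="",
                        letter_annotations={
                            "phred_quality": [40] * len(seq)},
                    )
                )
                i += 1
        rng.shuffle(records)
        return records

    uniform = np.full(len(keys), 1.0 / len(keys))
    pre = phase_reads(uniform, "pre")
    post = phase_reads(w / w.sum(), "post")
    return pre, post


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [b for b in DNA_BASES if b != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def simulate_chromatogram(
    occupancy: Mapping[str, float],
    total_au: float = 1e7,
    noise_cv: float = 0.05,
    lod: float = 1e4,
    seed: int = 0,
) -> list[ChromatogramFeature]:
    """Simulate chromatogram AUC features from a known occupancy vector.

    AUC_v = occupancy_v * total_au * lognormal(CV).  Features below *lod*
    are still emitted — censoring is the quantifier's job (the argument is
    accepted so a config can carry the instrument's limit alongside).
    """
    if total_au <= 0:
        raise ValueError("total_au must be positive")
    s = sum(occupancy.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"occupancy must sum to 1, got {s}")
    rng = _substream(seed, 2)
    keys = sorted(occupancy)
    noise = _lognormal_factor(rng, noise_cv, len(keys))
    return [
        ChromatogramFeature(key=k, auc=occupancy[k] * total_au * n)
        for k, n in zip(keys, noise)
    ]


# Deterministic 76-nt tRNA-like template (RNA); the anticodon slot is
# indices 33-35 (tRNA positions 34-36), the canonical layout.
_TRNA_TEMPLATE = (
    "GGGGCUAUAGCUCAGCUGGGAGAGCGCCUGCUUUGCACGCAGGAGGUCUGCGGUUCGAUCCCGCAUAGCUCCACCA"
)
_ANTICODON_OFFSET = 33  # 0-based index of tRNA position 34
_POS32_OFFSET = 31


def make_toy_scaffold(
    amino_acid: str, anticodon: str, length: int = 76, scaffold_id: str | None = None
) -> TRNAScaffold:
    """Deterministic synthetic tRNA scaffold with a given triplet anticodon.

    Stands in for curated genomic tRNA genes: a fixed cloverleaf-length
    template with the anticodon spliced at the canonical offset (position
    34 at index 33) and consistent 32/37/38 annotations.  Identical
    arguments always return an identical scaffold.
    """
    anticodon = dna_to_rna(anticodon.upper())
    if len(anticodon) != 3:
        raise ValueError("toy scaffolds take a triplet anticodon")
    if length < 44:
        raise ValueError("toy scaffold length must be at least 44 nt")
    reps = -(-length // len(_TRNA_TEMPLATE))  # ceil
    seq = (_TRNA_TEMPLATE * reps)[:length]
    seq = seq[:_ANTICODON_OFFSET] + anticodon + seq[_ANTICODON_OFFSET + 3 :]
    return TRNAScaffold(
        id=scaffold_id or f"toy-{amino_acid}-{anticodon}",
        amino_acid=amino_acid,
        sequence=seq,
        anticodon_start=_ANTICODON_OFFSET,
        pos32_index=_POS32_OFFSET,
    )
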