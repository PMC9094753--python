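"""Readers and writers for the plain-text formats the pipeline exchanges.

Scaffolds travel as FASTA plus a TSV sidecar carrying the anticodon
annotations (structure is never inferred from sequence); libraries as
FASTA plus a TSV manifest; kinetic plates, titers and chromatogram
features as CSV; selection reads as FASTQ.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .charging import ChromatogramFeature, OccupancyResult, ProteinVariantPeptide
from .design import DegenerateLibrary, TRNAScaffold, dna_to_rna
from .enrichment import EnrichmentResult, TiterRecord
from .kinetics import EfficiencyResult, GrowthDefectResult, PlateKinetics


# -- scaffolds ---------------------------------------------------------------

def read_scaffolds(fasta_path: str | Path, annot_path: str | Path
                   ) -> list[TRNAScaffold]:
    """Load scaffolds from FASTA plus a TSV sidecar.

    The sidecar columns are: id, amino_acid, anticodon_start, pos32_index
    (0-based indices).  DNA or RNA sequences are accepted and normalized
    to RNA.
    """
    seqs = {rec.id: dna_to_rna(str(rec.seq)) for rec in
            SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annot_path, sep="\t", dtype={"id": str})
    scaffolds = []
    for row in annot.itertuples(index=False):
        if row.id not in seqs:
            raise KeyError(f"annotation row {row.id!r} has no FASTA record")
        scaffolds.append(
            TRNAScaffold(
                id=row.id,
                amino_acid=row.amino_acid,
                sequence=seqs[row.id],
                anticodon_start=int(row.anticodon_start),
                pos32_index=int(row.pos32_index),
            )
        )
    return scaffolds


def write_scaffolds(scaffolds: Sequence[TRNAScaffold], fasta_path: str | Path,
                    annot_path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description=s.amino_acid)
               for s in scaffolds]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [dict(id=s.id, amino_acid=s.amino_acid,
              anticodon_start=s.anticodon_start, pos32_index=s.pos32_index)
         for s in scaffolds]
    ).to_csv(annot_path, sep="\t", index=False)


# -- libraries ---------------------------------------------------------------

def write_library(library: DegenerateLibrary, fasta_path: str | Path,
                  manifest_path: str | Path) -> None:
    """Write member sequences (FASTA) and a TSV manifest with the matching
    metadata (mode, flanks, window coordinates)."""
    records = [
        SeqRecord(Seq(seq), id=f"{library.scaffold_id}|{key}", description="")
        for key, seq in sorted(library.members.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["field", "value"])
        w.writerow(["scaffold_id", library.scaffold_id])
        w.writerow(["mode", library.mode.value])
        w.writerow(["codon", library.codon or ""])
        w.writerow(["flank_5", library.flank_5])
        w.writerow(["flank_3", library.flank_3])
        w.writerow(["window_start", library.window_start])
        w.writerow(["window_length", library.window_length])
        w.writerow(["randomized_offsets",
                    ",".join(map(str, library.randomized_offsets))])
        w.writerow(["position_labels", ",".join(library.position_labels)])
        w.writerow(["n_members", len(library)])


# -- kinetic plates ----------------------------------------------------------

def read_plate(csv_path: str | Path) -> PlateKinetics:
    """Load a long-format kinetic plate CSV (well, time_h, od600, lum,
    reporter, induction, replicate, qtrna, codon)."""
    return PlateKinetics.from_dataframe(pd.read_csv(csv_path))


def write_plate(plate: PlateKinetics, csv_path: str | Path) -> None:
    plate.to_dataframe().to_csv(csv_path, index=False)


def efficiency_to_frame(results: Iterable[EfficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(qtrna=r.qtrna, codon=r.codon, mean_pct=r.mean, sd_pct=r.sd,
              n=r.n, flags=";".join(f"{k}:{v}" for k, v in r.flags.items()))
         for r in results]
    )


def growth_defect_to_frame(results: Iterable[GrowthDefectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(qtrna=r.qtrna, t_measure_h=r.t_measure, ratio=r.ratio,
              density_difference=1.0 - r.ratio,
              flags=";".join(f"{k}:{v}" for k, v in r.flags.items()))
         for r in results]
    )


# -- selections --------------------------------------------------------------

def read_fastq(path: str | Path) -> list[str]:
    """Read sequences (as strings) from an uncompressed FASTQ file."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_titers(csv_path: str | Path) -> list[TiterRecord]:
    """Load a titer CSV with columns selection, pre_pfu_ml, post_pfu_ml."""
    df = pd.read_csv(csv_path)
    return [
        TiterRecord(selection=str(r.selection), pre_pfu_ml=float(r.pre_pfu_ml),
                    post_pfu_ml=float(r.post_pfu_ml))
        for r in df.itertuples(index=False)
    ]


def enrichment_to_frame(result: EnrichmentResult) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(
            (dict(member=k, log10_enrichment=v) for k, v in
             result.enrichment.items()),
            key=lambda d: -d["log10_enrichment"],
        )
    )


# -- charging ----------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> str:
    """Single-record protein FASTA -> amino-acid string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one protein record, got {len(records)}")
    return str(records[0].seq)


def read_features(csv_path: str | Path) -> list[ChromatogramFeature]:
    """Load a feature CSV with columns key_or_mass, auc.

    A numeric key_or_mass is an observed mass (Da); anything else is a
    variant letter or peptide-sequence key.
    """
    df = pd.read_csv(csv_path, dtype={"key_or_mass": str})
    features = []
    for r in df.itertuples(index=False):
        token = str(r.key_or_mass).strip()
        try:
            mass = float(token)
            features.append(ChromatogramFeature(auc=float(r.auc),
                                                observed_mass=mass))
        except ValueError:
            features.append(ChromatogramFeature(auc=float(r.auc), key=token))
    return features


def variants_to_frame(variants: Sequence[ProteinVariantPeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(variant=v.variant, peptide=v.peptide, monoisotopic_mass=v.mass,
              site_position=v.site_position, digest_altering=v.digest_altering)
         for v in variants]
    )


def occupancy_to_frame(result: OccupancyResult) -> pd.DataFrame:
    rows = [dict(variant=k, fraction=v, status="detected")
            for k, v in sorted(result.fractions.items(),
                               key=lambda kv: -kv[1])]
    rows += [dict(variant=k, fraction=0.0, status="below_lod")
             for k in sorted(result.below_lod)]
    return pd.DataFrame(rows)
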