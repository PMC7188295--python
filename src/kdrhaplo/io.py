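"""Readers and writers for the package's interchange formats.

FASTA/FASTQ go through Biopython; failures are re-raised with the record
index so malformed files point at the offending record.  Tables are plain
TSV via pandas; segment annotations travel as a JSON sidecar next to the
reference FASTA.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refpanel import KdrSite, SegmentModel, SimulatedRead


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} origin={r.origin} segment={r.segment_id}\n"
                     f"{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[SimulatedRead]:
    """Parse FASTQ into SimulatedRead records (origin from the description
    when present, else empty).  Malformed records raise with the record index.
    """
    reads: list[SimulatedRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            desc = dict(kv.split("=", 1) for kv in rec.description.split()[1:]
                        if "=" in kv)
            qual = "".join(chr(q + 33)
                           for q in rec.letter_annotations["phred_quality"])
            reads.append(SimulatedRead(
                read_id=rec.id, sequence=str(rec.seq), quality=qual,
                origin=desc.get("origin", ""),
                population_id="", segment_id=desc.get("segment", "")))
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record #{len(reads) + 1} in {path}: {exc}") from exc
    return reads


# ---------------------------------------------------------------------------
# segment annotation sidecar (JSON)
# ---------------------------------------------------------------------------

def write_segment_json(segment: SegmentModel, path) -> None:
    payload = {
        "segment_id": segment.segment_id,
        "sequence": segment.sequence,
        "exon_intervals": [list(iv) for iv in segment.exon_intervals],
        "exon_codon_starts": list(segment.exon_codon_starts),
        "frame_phase": segment.frame_phase,
        "primers": list(segment.primers),
        "kdr_catalogue": [
            {"residue_number": s.residue_number, "wild_type_aa": s.wild_type_aa,
             "resistant_aas": sorted(s.resistant_aas), "segment_id": s.segment_id}
            for s in segment.kdr_catalogue],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_segment_json(path) -> SegmentModel:
    d = json.loads(Path(path).read_text())
    return SegmentModel(
        d["segment_id"], d["sequence"],
        tuple(tuple(iv) for iv in d["exon_intervals"]),
        tuple(d["exon_codon_starts"]), d["frame_phase"],
        tuple(d["primers"]),
        tuple(KdrSite(s["residue_number"], s["wild_type_aa"],
                      frozenset(s["resistant_aas"]), s["segment_id"])
              for s in d["kdr_catalogue"]))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, expected_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if expected_columns:
        missing = set(expected_columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        extra = set(df.columns) - set(expected_columns)
        if extra:
            warnings.warn(f"{path}: unknown columns {sorted(extra)} preserved")
    return df
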