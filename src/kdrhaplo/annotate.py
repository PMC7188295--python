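"""Reference-anchored alignment and codon-level kdr annotation.

Each haplotype is globally aligned to its segment's wild-type amplicon with
affine gap penalties; exon codons are then compared in frame, translated,
and every exonic substitution reported as an amino-acid change in housefly
numbering.  Intron differences are listed verbatim but never translated.
Haplotypes with exonic indels are flagged as putative artifacts and
excluded from translation (the amplified exons are under strong purifying
selection; a frameshift in them is virtually always a sequencing artifact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .refpanel import PanelHaplotype, SegmentModel, translate

log = logging.getLogger(__name__)


class ForeignSequenceError(ValueError):
    """Raised when a sequence aligns to the reference below 70% identity."""


class FrameshiftWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AminoAcidChange:
    residue_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    known_kdr: bool

    @property
    def notation(self) -> str:
        """Field notation like ``V1016I`` (``V1000V`` for synonymous)."""
        return f"{self.ref_aa}{self.residue_number}{self.alt_aa}"


@dataclass(frozen=True)
class HaplotypeAnnotation:
    haplotype_name: str
    segment_id: str
    exon_changes: tuple[AminoAcidChange, ...]
    intron_edits: tuple[tuple[int, str, str], ...]  # (1-based ref pos, ref, alt)
    label: str
    putative_artifact: bool = False

    @property
    def is_wild_type(self) -> bool:
        return not self.exon_changes

    @property
    def nonsynonymous(self) -> tuple[AminoAcidChange, ...]:
        return tuple(c for c in self.exon_changes if not c.synonymous)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def trim_primers(sequence: str, segment: SegmentModel) -> str:
    """Strip primer prefix/suffix when present (each within one mismatch)."""
    from .caller import _hamming
    from .refpanel import reverse_complement

    fwd, rev = segment.primers
    rev_rc = reverse_complement(rev)
    if len(sequence) > len(fwd) + len(rev_rc):
        if _hamming(sequence[: len(fwd)], fwd) <= 1:
            sequence = sequence[len(fwd):]
        if _hamming(sequence[-len(rev_rc):], rev_rc) <= 1:
            sequence = sequence[: -len(rev_rc)]
    return sequence


def align_to_reference(sequence: str, segment: SegmentModel):
    """Global affine-gap alignment of a haplotype against the reference.

    Scoring: match +1, mismatch -2, gap open -4, gap extend -1; the first
    optimal alignment reported by the aligner is used, which places
    score-equivalent gaps deterministically (leftmost).  Raises
    :class:`ForeignSequenceError` below 70% identity.
    """
    if not sequence:
        raise ValueError("empty sequence")
    alignment = _aligner().align(segment.sequence, sequence)[0]
    ref_aln, hap_aln = str(alignment[0]), str(alignment[1])
    matches = sum(a == b for a, b in zip(ref_aln, hap_aln) if a != "-" and b != "-")
    identity = matches / len(ref_aln)
    if identity < 0.70:
        raise ForeignSequenceError(
            f"alignment identity {identity:.2f} < 0.70 against {segment.segment_id}")
    return alignment


def _aligned_columns(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _project(alignment):
    """Per-reference-position haplotype content.

    Returns (bases, insertions): ``bases[i]`` is the haplotype base aligned
    to reference position i ('-' for deletion); ``insertions[i]`` is any
    haplotype sequence inserted immediately before reference position i.
    """
    ref_aln, hap_aln = _aligned_columns(alignment)
    n_ref = sum(c != "-" for c in ref_aln)
    bases = [""] * n_ref
    insertions = [""] * (n_ref + 1)
    i = 0
    for r, h in zip(ref_aln, hap_aln):
        if r == "-":
            insertions[i] += h
        else:
            bases[i] = h
            i += 1
    return bases, insertions


def annotate(sequence: str, segment: SegmentModel,
             name: str = "") -> HaplotypeAnnotation:
    """Annotate one haplotype against its segment reference.

    The sequence may be a full amplicon or primer-trimmed; primers are
    stripped before alignment against the primer-trimmed reference window.
    """
    trimmed = trim_primers(sequence, segment)
    # align against the primer-trimmed reference so terminal gaps do not
    # depend on whether the caller left primers on
    lo, hi = segment.inner_interval
    inner_ref = segment.sequence[lo:hi]
    inner_model = SegmentModel(
        segment.segment_id, inner_ref,
        tuple((s - lo, e - lo) for (s, e) in segment.exon_intervals),
        segment.exon_codon_starts, segment.frame_phase, segment.primers,
        segment.kdr_catalogue)
    alignment = align_to_reference(trimmed, inner_model)
    bases, insertions = _project(alignment)

    kdr_lookup = {(site.residue_number, aa)
                  for site in segment.kdr_catalogue for aa in site.resistant_aas}

    exon_changes: list[AminoAcidChange] = []
    artifact = False
    for (s, e), codon_start in zip(inner_model.exon_intervals,
                                   inner_model.exon_codon_starts):
        # any indel touching exon columns (deleted base or insertion strictly
        # inside the exon) marks the haplotype as a putative artifact
        if any(bases[i] == "-" for i in range(s, e)) or \
                any(insertions[i] for i in range(s + 1, e)):
            artifact = True
            continue
        for ci in range((e - s) // 3):
            ref_codon = inner_ref[s + 3 * ci: s + 3 * ci + 3]
            alt_codon = "".join(bases[s + 3 * ci: s + 3 * ci + 3])
            if ref_codon == alt_codon:
                continue
            ref_aa = translate(ref_codon)
            alt_aa = translate(alt_codon)
            residue = codon_start + ci
            exon_changes.append(AminoAcidChange(
                residue, ref_codon, alt_codon, ref_aa, alt_aa,
                synonymous=(ref_aa == alt_aa),
                known_kdr=(residue, alt_aa) in kdr_lookup))

    intron_edits: list[tuple[int, str, str]] = []
    i0, i1 = inner_model.intron_interval
    for i in range(i0, i1):
        if bases[i] != inner_ref[i]:
            intron_edits.append((i + 1, inner_ref[i], bases[i]))
        if insertions[i] and i > i0:
            intron_edits.append((i + 1, "-", insertions[i]))

    if artifact:
        log.warning("haplotype %s: exonic indel; flagged as putative artifact "
                    "and excluded from translation", name or "<unnamed>")
        label = "putative artifact"
        exon_changes = []
    elif exon_changes:
        label = "+".join(c.notation
                         for c in sorted(exon_changes,
                                         key=lambda c: c.residue_number))
    else:
        label = "wild-type"
    return HaplotypeAnnotation(name, segment.segment_id, tuple(exon_changes),
                               tuple(intron_edits), label, artifact)


def annotate_panel(models: dict[str, SegmentModel],
                   panel: list[PanelHaplotype]) -> dict[str, HaplotypeAnnotation]:
    return {h.name: annotate(h.sequence, models[h.segment_id], h.name)
            for h in panel}


def annotate_table(table: pd.DataFrame, name_to_seq: dict[str, str],
                   models: dict[str, SegmentModel]
                   ) -> tuple[pd.DataFrame, pd.DataFrame,
                              dict[str, HaplotypeAnnotation]]:
    """Label every haplotype in a frequency table and summarise populations.

    Returns (table with a ``label`` column, per-population summary with the
    summed frequency of haplotypes carrying at least one non-synonymous
    change vs the wild-type remainder, name -> annotation mapping).
    """
    annotations: dict[str, HaplotypeAnnotation] = {}
    for _, row in table[["haplotype_name", "segment_id"]].drop_duplicates().iterrows():
        nm = row["haplotype_name"]
        annotations[nm] = annotate(name_to_seq[nm], models[row["segment_id"]], nm)

    out = table.copy()
    out["label"] = out["haplotype_name"].map(lambda n: annotations[n].label)
    out["nonsynonymous"] = out["haplotype_name"].map(
        lambda n: bool(annotations[n].nonsynonymous))

    nonsyn_freq = out["frequency"].where(out["nonsynonymous"], 0.0)
    grp = out.assign(_nonsyn=nonsyn_freq).groupby(
        ["population_id", "segment_id"], as_index=False).agg(
        country=("country", "first"), year=("year", "first"),
        nonsyn_share=("_nonsyn", "sum"), _total=("frequency", "sum"))
    grp["wild_type_share"] = grp["_total"] - grp["nonsyn_share"]
    grp = grp.drop(columns="_total")
    return out, grp, annotations
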