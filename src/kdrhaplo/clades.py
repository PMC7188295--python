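"""Intron-based bipartition of IIS6 haplotypes into clades A and B.

The two IIS6 lineages observed in field material are separated by intron
indels and substitutions while their exons stay nearly invariant, so a
deterministic average-linkage bipartition on normalised intron distances
recovers the same grouping as a phylogenetic tree — with the clade carrying
the catalogued kdr exon changes anchored as clade A.  IIIS6 intron
variation does not support distinct clades and is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotate import annotate, trim_primers
from .refpanel import SegmentModel, build_default_panel


class UnsupportedSegmentError(ValueError):
    """Intron clades are only defined for IIS6."""


@dataclass(frozen=True)
class CladeAssignment:
    labels: dict[str, str]          # haplotype name -> "A" / "B"
    linkage_height: float
    anchor_used: str


def _intron_string(sequence: str, segment: SegmentModel) -> str:
    """Haplotype bases across the aligned intron columns (plus insertions)."""
    from .annotate import _project, align_to_reference

    trimmed = trim_primers(sequence, segment)
    lo, hi = segment.inner_interval
    inner_ref = segment.sequence[lo:hi]
    inner_model = SegmentModel(
        segment.segment_id, inner_ref,
        tuple((s - lo, e - lo) for (s, e) in segment.exon_intervals),
        segment.exon_codon_starts, segment.frame_phase, segment.primers,
        segment.kdr_catalogue)
    alignment = align_to_reference(trimmed, inner_model)
    bases, insertions = _project(alignment)
    i0, i1 = inner_model.intron_interval
    parts = []
    for i in range(i0, i1):
        if i > i0 and insertions[i]:
            parts.append(insertions[i])
        if bases[i] != "-":
            parts.append(bases[i])
    return "".join(parts)


def intron_distance(a: str, b: str, segment: SegmentModel) -> float:
    """Normalised Levenshtein distance between two haplotypes' introns.

    Both haplotypes are anchored to the reference; the distance is computed
    on the bases each aligns into the reference intron window, divided by
    the longer intron string, so the value lies in [0, 1].
    """
    if segment.segment_id != "IIS6":
        raise UnsupportedSegmentError(
            f"intron clades are not supported for {segment.segment_id}")
    ia = _intron_string(a, segment)
    ib = _intron_string(b, segment)
    if not ia and not ib:
        return 0.0
    d = edlib.align(ia, ib, task="distance")["editDistance"]
    return d / max(len(ia), len(ib))


def classify(haplotypes: dict[str, str],
             segment: SegmentModel | None = None) -> CladeAssignment:
    """Assign clade A/B labels to IIS6 haplotypes (name -> sequence).

    Average-linkage hierarchical clustering on pairwise intron distances,
    cut into two groups at the root.  The group containing the anchor — a
    haplotype whose exons carry a catalogued kdr change at 989/1011/1016,
    else the group closest to the packaged clade-A reference intron — is
    labelled A.  Identical intron signatures across all haplotypes yield a
    single-clade result with a warning.
    """
    if segment is None:
        segment = build_default_panel()[0]["IIS6"]
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes to classify")
    names = sorted(haplotypes)
    introns = {n: _intron_string(haplotypes[n], segment) for n in names}

    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ia, ib = introns[names[i]], introns[names[j]]
            if ia or ib:
                d = edlib.align(ia, ib, task="distance")["editDistance"]
                dm[i, j] = dm[j, i] = d / max(len(ia), len(ib))

    if not dm.any():
        warnings.warn("all intron signatures identical; single clade")
        return CladeAssignment({nm: "A" for nm in names}, 0.0, "")

    z = linkage(squareform(dm, checks=False), method="average")
    groups = fcluster(z, t=2, criterion="maxclust")
    height = float(z[-1, 2])

    # anchor: kdr-bearing haplotype pins its group as clade A
    kdr_sites = {s.residue_number for s in segment.kdr_catalogue}
    anchor = ""
    for nm in names:
        ann = annotate(haplotypes[nm], segment, nm)
        if any(c.known_kdr and c.residue_number in kdr_sites
               for c in ann.exon_changes):
            anchor = nm
            break
    if anchor:
        a_group = groups[names.index(anchor)]
    else:
        # nearest group to the packaged clade-A reference intron signature
        ref_intron = segment.sequence[slice(*segment.intron_interval)]
        means = {}
        for gid in set(groups):
            ds = []
            for nm, g in zip(names, groups):
                if g == gid:
                    d = edlib.align(introns[nm], ref_intron,
                                    task="distance")["editDistance"]
                    ds.append(d / max(len(introns[nm]), len(ref_intron)))
            means[gid] = float(np.mean(ds))
        a_group = min(sorted(means), key=lambda g: means[g])
        anchor = "<reference-intron>"

    labels = {nm: ("A" if g == a_group else "B") for nm, g in zip(names, groups)}
    return CladeAssignment(labels, height, anchor)
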