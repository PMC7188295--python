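"""Demultiplexing, quality filtering and haplotype denoising for pooled reads.

This is the package's defined replacement for the black-box clustering stage
used on the original Ion Torrent data: reads are assigned to populations by
barcode, quality/length/primer-filtered, dereplicated, and then denoised by
iterated absorption of minor sequences into sufficiently more abundant
neighbours within a small edit distance, with an extra rule that merges
pure homopolymer-length variants (the platform's dominant error mode)
regardless of the abundance ratio.  Surviving sequences below a frequency
floor are discarded and the remainder renormalised.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .refpanel import SEGMENT_PREFIX, SegmentModel, SimulatedRead, reverse_complement

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for demultiplexing, filtering and denoising.

    The frequency floor default (0.01) sits below the minimum real allele
    frequency expected in a pool of ~30 diploid individuals (1/60), so a
    single chromosome in a pool is still callable while sub-floor error
    clusters are removed.
    """

    barcode_max_mismatch: int = 1
    length_window: tuple[int, int] = (300, 380)
    min_mean_quality: float = 20.0
    collapse_distance: int = 2
    abundance_ratio: float = 20.0
    frequency_floor: float = 0.01

    def __post_init__(self):
        if not 0 <= self.barcode_max_mismatch <= 2:
            raise ValueError("barcode_max_mismatch must be in [0, 2]")
        if self.abundance_ratio <= 1:
            raise ValueError("abundance_ratio must exceed 1")
        if not 0 <= self.frequency_floor < 0.5:
            raise ValueError("frequency_floor must be in [0, 0.5)")


@dataclass(frozen=True)
class HaplotypeCall:
    """A denoised haplotype for one population and segment."""

    population_id: str
    segment_id: str
    sequence: str
    read_count: int
    frequency: float


FREQUENCY_TABLE_COLUMNS = [
    "population_id", "country", "continent", "year", "segment_id",
    "haplotype_name", "read_count", "frequency",
]


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads, manifest: pd.DataFrame, params: CallerParams
                ) -> tuple[dict[str, list], list]:
    """Assign reads to populations by barcode prefix.

    A read is assigned iff exactly one manifest barcode lies within
    ``barcode_max_mismatch`` of its prefix; reads matching zero or several
    barcodes land in the unassigned bin.  The barcode is stripped from
    assigned reads.  Returns (population_id -> reads, unassigned).
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    barcodes = list(manifest["barcode"])
    pops = list(manifest["population_id"])
    bc_len = len(barcodes[0])
    assigned: dict[str, list] = {p: [] for p in pops}
    unassigned: list = []
    exact = {bc: pop for bc, pop in zip(barcodes, pops)}
    for read in reads:
        prefix = read.sequence[:bc_len]
        pop = exact.get(prefix)
        if pop is None:
            hits = [p for bc, p in zip(barcodes, pops)
                    if _hamming(prefix, bc) <= params.barcode_max_mismatch]
            pop = hits[0] if len(hits) == 1 else None
        if pop is None:
            unassigned.append(read)
        else:
            assigned[pop].append(_strip_prefix(read, bc_len))
    return assigned, unassigned


def _strip_prefix(read, n: int):
    from dataclasses import replace

    return replace(read, sequence=read.sequence[n:], quality=read.quality[n:])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _match_end(seq: str, primer: str, where: str) -> bool:
    window = seq[: len(primer)] if where == "start" else seq[-len(primer):]
    return len(window) == len(primer) and _hamming(window, primer) <= 1

def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean([ord(c) - 33 for c in qual]))


def filter_reads(reads, segment: SegmentModel, params: CallerParams) -> list:
    """Length/quality/primer filter; output reads are primer-trimmed, forward.

    A read is retained when both primers are found (each within one
    mismatch, at the read ends), its primer-trimmed length falls inside the
    length window, and its mean Phred quality is at least the minimum.
    Reads sequenced from the reverse strand are reverse-complemented first,
    so all retained reads are forward-oriented.
    """
    from dataclasses import replace

    fwd, rev = segment.primers
    rev_rc = reverse_complement(rev)
    lo, hi = params.length_window
    kept = []
    for read in reads:
        seq, qual = read.sequence, read.quality
        if not (_match_end(seq, fwd, "start") and _match_end(seq, rev_rc, "end")):
            rc = reverse_complement(seq)
            if _match_end(rc, fwd, "start") and _match_end(rc, rev_rc, "end"):
                seq, qual = rc, qual[::-1]
            else:
                continue
        if not lo <= len(seq) <= hi:
            continue
        if _mean_quality(qual) < params.min_mean_quality:
            continue
        trimmed = seq[len(fwd): len(seq) - len(rev_rc)]
        kept.append(replace(read, sequence=trimmed,
                            quality=qual[len(fwd): len(seq) - len(rev_rc)]))
    return kept


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def _levenshtein(a: str, b: str, k: int | None = None) -> int:
    res = edlib.align(a, b, task="distance", k=-1 if k is None else k)
    d = res["editDistance"]
    return d if d >= 0 else k + 1


def _homopolymer_variants(seq: str):
    """All sequences reachable by +/-1 base in one homopolymer run (run >= 2)."""
    n = len(seq)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            yield seq[:i] + seq[i + 1:]          # contract run by one
        yield seq[:i] + seq[i] + seq[i:]          # extend run by one
        i = j


def call_haplotypes(reads, params: CallerParams,
                    population_id: str | None = None,
                    segment_id: str | None = None) -> list[HaplotypeCall]:
    """Dereplicate and denoise filtered reads of one population+segment.

    Procedure: (i) exact dereplication; (ii) iterated absorption — minor
    sequences, visited in ascending count (ties broken lexicographically),
    are merged into the nearest surviving sequence within
    ``collapse_distance`` edits that is at least ``abundance_ratio`` times
    more abundant (distance ties broken by abundance), or into a more
    abundant sequence differing only by one homopolymer-run length (merged
    regardless of ratio); (iii) sequences below ``frequency_floor`` are
    dropped and frequencies renormalised.  Output sorted by descending count.
    """
    reads = list(reads)
    if not reads:
        warnings.warn(f"no retained reads for {population_id}/{segment_id}; "
                      "population dropped")
        return []
    if population_id is None:
        population_id = reads[0].population_id
    if segment_id is None:
        segment_id = reads[0].segment_id

    counts = Counter(r.sequence for r in reads)
    order = sorted(counts, key=lambda s: (counts[s], s))
    alive = dict(counts)

    for seq in order:
        if seq not in alive:
            continue
        cnt = alive[seq]
        # abundance-ratio rule within collapse distance: among the (few)
        # survivors at or above ratio x minor count, absorb into the nearest
        # one, breaking distance ties by abundance — nearest-first absorption
        # keeps the error cloud of a haplotype from draining into a more
        # abundant neighbour one extra edit away
        threshold = params.abundance_ratio * cnt
        best = None
        for cand, c in alive.items():
            if cand == seq or c < threshold \
                    or abs(len(cand) - len(seq)) > params.collapse_distance:
                continue
            d = _levenshtein(seq, cand, params.collapse_distance)
            if d <= params.collapse_distance:
                key = (d, -c, cand)
                if best is None or key < best:
                    best = key
        target = best[2] if best is not None else None
        if target is None:
            # homopolymer-length-only difference: merge into any more
            # abundant neighbour irrespective of the ratio
            variants = set(_homopolymer_variants(seq))
            cands = [s for s in variants if s in alive and alive[s] > cnt]
            if cands:
                target = max(cands, key=lambda s: (alive[s], s))
        if target is not None:
            alive[target] += alive.pop(seq)

    total = sum(alive.values())
    surviving = {s: c for s, c in alive.items()
                 if c / total >= params.frequency_floor}
    if not surviving:
        warnings.warn(f"all sequences below frequency floor for "
                      f"{population_id}/{segment_id}")
        return []
    kept_total = sum(surviving.values())
    calls = [HaplotypeCall(population_id, segment_id, s, c, c / kept_total)
             for s, c in surviving.items()]
    calls.sort(key=lambda c: (-c.read_count, c.sequence))
    return calls


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def merge_tables(calls_by_population: dict[str, list[HaplotypeCall]],
                 manifest: pd.DataFrame,
                 name_map: dict[str, str] | None = None
                 ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Combine per-population calls into one frequency table.

    Identical sequences share one haplotype name across populations.  Names
    are the segment prefix plus a zero-padded rank by total read count
    (ties broken lexicographically by sequence); ``name_map`` (sequence ->
    name) can pin known panel names instead.  Returns the table and the
    name -> sequence mapping.
    """
    meta = manifest.set_index("population_id")
    totals: Counter = Counter()
    seq_segment: dict[str, str] = {}
    for calls in calls_by_population.values():
        for c in calls:
            totals[c.sequence] += c.read_count
            seq_segment[c.sequence] = c.segment_id

    names: dict[str, str] = {}
    if name_map:
        names.update({s: n for s, n in name_map.items() if s in totals})
    for segment in sorted({c for c in seq_segment.values()}):
        seqs = [s for s in totals if seq_segment[s] == segment and s not in names]
        seqs.sort(key=lambda s: (-totals[s], s))
        taken = set(names.values())
        rank = 0
        for s in seqs:
            while f"{SEGMENT_PREFIX[segment]}_{rank:02d}" in taken:
                rank += 1
            names[s] = f"{SEGMENT_PREFIX[segment]}_{rank:02d}"
            rank += 1

    rows = []
    for pop, calls in calls_by_population.items():
        for c in calls:
            m = meta.loc[pop]
            rows.append([pop, m["country"], m["continent"], int(m["year"]),
                         c.segment_id, names[c.sequence], c.read_count,
                         c.frequency])
    table = pd.DataFrame(rows, columns=FREQUENCY_TABLE_COLUMNS)
    table = table.sort_values(
        ["segment_id", "population_id", "read_count"],
        ascending=[True, True, False]).reset_index(drop=True)
    name_to_seq = {n: s for s, n in names.items()}
    return table, name_to_seq


def validate_frequency_table(table: pd.DataFrame, tol: float = 1e-6) -> None:
    """Check that per (population, segment) frequencies sum to one."""
    sums = table.groupby(["population_id", "segment_id"])["frequency"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if not bad.empty:
        raise ValueError(f"frequencies do not sum to 1: {bad.to_dict()}")
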