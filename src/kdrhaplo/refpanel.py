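"""Annotated segment references, haplotype panel and pooled-read simulator.

The package ships synthetic wild-type references for the two amplified
voltage-gated sodium channel (Na_V) segments of *Aedes aegypti* — IIS6 and
IIIS6 — together with a haplotype panel that reproduces the relational
structure observed in worldwide field samples: kdr point-mutation
derivatives of a common clade-A background, a second IIS6 clade separated
by intron indels, and intron-only IIIS6 variants.  On top of the panel sits
a simulator that emits barcoded, Ion-Torrent-flavoured single-end amplicon
reads for per-population pools.

Residue numbers follow the housefly (*Musca domestica*) Na_V convention
used throughout the insecticide-resistance literature (e.g. V1016I,
F1534C).  Coordinates are 0-based half-open internally; reports are
1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

SEGMENTS = ("IIS6", "IIIS6")

#: haplotype-name prefix per segment, following the 2s6_/3s6_ convention
SEGMENT_PREFIX = {"IIS6": "2s6", "IIIS6": "3s6"}

#: amplification primers, 5'->3' (forward x reverse)
PRIMERS = {
    "IIS6": ("CGGGTATTATGCGGCGAGTG", "TGGACAAAAGCAAGGCTAAG"),
    "IIIS6": ("GTGGGAAAGCAGCCGATTCGC", "TGTTGAACCCGATGAACAAC"),
}

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# deterministic seed for panel sequence generation; the panel is a fixed
# artifact of the package, not a function of user randomness
_PANEL_SEED = 20191105


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KdrSite:
    """A catalogued knockdown-resistance site in housefly numbering."""

    residue_number: int
    wild_type_aa: str
    resistant_aas: frozenset[str]
    segment_id: str

    def __post_init__(self):
        if self.wild_type_aa in self.resistant_aas:
            raise ValueError("wild-type amino acid cannot be resistant")


@dataclass(frozen=True)
class SegmentModel:
    """Annotated wild-type amplicon reference for one Na_V segment.

    ``sequence`` is the full amplicon including both primer sites.
    ``exon_intervals`` are 0-based half-open intervals into ``sequence``;
    ``exon_codon_starts[i]`` gives the housefly residue number of the first
    complete codon of exon *i* (exons need not be contiguous in protein
    coordinates — the IIIS6 amplicon spans two exons separated in the
    protein by residues not sequenced here).
    """

    segment_id: str
    sequence: str
    exon_intervals: tuple[tuple[int, int], ...]
    exon_codon_starts: tuple[int, ...]
    frame_phase: int
    primers: tuple[str, str]
    kdr_catalogue: tuple[KdrSite, ...]

    def __post_init__(self):
        prev_end = 0
        for (s, e) in self.exon_intervals:
            if not (prev_end <= s < e <= len(self.sequence)):
                raise ValueError("exon intervals must be disjoint, sorted, in bounds")
            if (e - s) % 3 != self.frame_phase and (e - s) % 3 != 0:
                raise ValueError("exon length inconsistent with frame phase")
            prev_end = e
        for p in self.primers:
            if set(p) - set(_BASES):
                raise ValueError("primers must be uppercase A/C/G/T")

    @property
    def codon_offset(self) -> int:
        """Residue number of the first complete exon codon."""
        return self.exon_codon_starts[0]

    @property
    def intron_interval(self) -> tuple[int, int]:
        """The (single) intron between the two exons."""
        return (self.exon_intervals[0][1], self.exon_intervals[1][0])

    @property
    def inner_interval(self) -> tuple[int, int]:
        """Primer-trimmed region of the amplicon."""
        return (len(self.primers[0]), len(self.sequence) - len(self.primers[1]))

    def codon_slice(self, residue_number: int) -> tuple[int, int]:
        """Full-sequence interval of the codon for a housefly residue."""
        for (s, e), start in zip(self.exon_intervals, self.exon_codon_starts):
            n_codons = (e - s) // 3
            if start <= residue_number < start + n_codons:
                off = s + 3 * (residue_number - start)
                return (off, off + 3)
        raise KeyError(f"residue {residue_number} not covered by {self.segment_id}")

    def codon(self, residue_number: int) -> str:
        s, e = self.codon_slice(residue_number)
        return self.sequence[s:e]


@dataclass(frozen=True)
class PanelHaplotype:
    """One haplotype of the packaged panel (full amplicon, primers included)."""

    name: str
    segment_id: str
    sequence: str
    clade_label: str = "none"  # A / B / none
    aa_changes: tuple[tuple[int, str], ...] = ()


@dataclass
class PopulationConfig:
    """True per-population haplotype frequencies and pool metadata."""

    population_id: str
    country: str
    continent: str
    year: int
    frequencies: dict[str, dict[str, float]]  # segment -> {haplotype name: freq}
    barcode: str
    reads_per_segment: int = 2000

    def validate(self, panel_names: set[str] | None = None) -> None:
        for seg, freqs in self.frequencies.items():
            if seg not in SEGMENTS:
                raise ValueError(f"unknown segment {seg!r}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.population_id}/{seg}: frequencies sum to "
                    f"{sum(freqs.values())}, expected 1"
                )
            if panel_names is not None:
                missing = set(freqs) - panel_names
                if missing:
                    raise ValueError(
                        f"{self.population_id}/{seg}: unknown haplotypes {sorted(missing)}"
                    )
        if self.reads_per_segment <= 0:
            raise ValueError("reads_per_segment must be positive")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error model with homopolymer-inflated indels.

    Emulates the dominant Ion Torrent failure mode: indels concentrated in
    homopolymer runs, plus a low substitution floor.  ``quality_mean`` is
    the flat Phred score written for every base.
    """

    substitution_rate: float = 0.005
    indel_rate: float = 0.001
    homopolymer_multiplier: float = 3.0
    quality_mean: int = 30

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.homopolymer_multiplier < 1:
            raise ValueError("homopolymer multiplier must be >= 1")


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated FASTQ record; ``origin`` is the source haplotype."""

    read_id: str
    sequence: str
    quality: str
    origin: str
    population_id: str
    segment_id: str


# ---------------------------------------------------------------------------
# reference + panel construction
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    sense = sorted(set("".join(c) for c in itertools.product(_BASES, repeat=3)) - _STOPS)
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _build_exon(rng, codon_start: int, n_codons: int, fixed: dict[int, str]) -> str:
    codons = _random_codons(rng, n_codons)
    for residue, codon in fixed.items():
        codons[residue - codon_start] = codon
    return "".join(codons)


def _substitute(seq: str, pos: int) -> str:
    """Deterministic substitution: replace base at pos with the next base cyclically."""
    alt = _BASES[(_BASES.index(seq[pos]) + 1) % 4]
    return seq[:pos] + alt + seq[pos + 1:]


def closest_codon(ref_codon: str, aa: str) -> str:
    """Codon for ``aa`` with fewest nucleotide differences from ``ref_codon``.

    Ties broken lexicographically, so the choice is deterministic.
    """
    best = None
    for c in itertools.product(_BASES, repeat=3):
        codon = "".join(c)
        if codon in _STOPS or translate(codon) != aa:
            continue
        d = sum(a != b for a, b in zip(codon, ref_codon))
        key = (d, codon)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no codon encodes {aa!r}")
    return best[1]


def mutate_haplotype(segment: SegmentModel, changes: dict[int, str],
                     base_sequence: str | None = None) -> str:
    """Apply amino-acid changes (residue -> alt aa) to an amplicon sequence.

    Each change replaces the reference codon with the closest codon encoding
    the requested amino acid.  Only valid on sequences that keep reference
    exon coordinates (i.e. no prior exonic indels).
    """
    seq = base_sequence if base_sequence is not None else segment.sequence
    if len(seq) != len(segment.sequence):
        raise ValueError("base sequence must preserve reference coordinates")
    for residue, aa in sorted(changes.items()):
        s, e = segment.codon_slice(residue)
        seq = seq[:s] + closest_codon(segment.codon(residue), aa) + seq[e:]
    return seq


def _build_iis6(rng) -> SegmentModel:
    fwd, rev = PRIMERS["IIS6"]
    # exon1: codons 981-1008 (84 bp) carrying S989; exon2: codons 1009-1030
    # (66 bp) carrying I1011 and V1016; 162 bp intron between them.
    exon1 = _build_exon(rng, 981, 28, {989: "TCC"})
    exon2 = _build_exon(rng, 1009, 22, {1011: "ATA", 1016: "GTA"})
    intron = "GT" + _random_bases(rng, 64) + "AAAA" + _random_bases(rng, 50) \
        + "TTTT" + _random_bases(rng, 36) + "AG"
    seq = fwd + exon1 + intron + exon2 + reverse_complement(rev)
    e1 = (len(fwd), len(fwd) + len(exon1))
    e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon2))
    catalogue = (
        KdrSite(989, "S", frozenset({"P"}), "IIS6"),
        KdrSite(1011, "I", frozenset({"M"}), "IIS6"),
        KdrSite(1016, "V", frozenset({"I", "G"}), "IIS6"),
    )
    return SegmentModel("IIS6", seq, (e1, e2), (981, 1009), 0, (fwd, rev), catalogue)


def _build_iiis6(rng) -> SegmentModel:
    fwd, rev = PRIMERS["IIIS6"]
    # exon1: codons 1515-1544 (90 bp) carrying T1520/I1532/F1534; exon2:
    # codons 1595-1615 (63 bp) carrying residue 1605; 160 bp intron.
    exon1 = _build_exon(rng, 1515, 30, {1520: "ACC", 1532: "ATT", 1534: "TTC"})
    exon2 = _build_exon(rng, 1595, 21, {1605: "GTG"})
    intron = "GT" + _random_bases(rng, 70) + "CCCC" + _random_bases(rng, 46) \
        + "GGGG" + _random_bases(rng, 32) + "AG"
    seq = fwd + exon1 + intron + exon2 + reverse_complement(rev)
    e1 = (len(fwd), len(fwd) + len(exon1))
    e2 = (e1[1] + len(intron), e1[1] + len(intron) + len(exon2))
    catalogue = (
        KdrSite(1520, "T", frozenset({"I"}), "IIIS6"),
        KdrSite(1532, "I", frozenset({"T"}), "IIIS6"),
        KdrSite(1534, "F", frozenset({"C"}), "IIIS6"),
    )
    return SegmentModel("IIIS6", seq, (e1, e2), (1515, 1595), 0, (fwd, rev), catalogue)


def _intron_edit(segment: SegmentModel, seq: str, *, subs: tuple[int, ...] = (),
                 deletion: tuple[int, int] | None = None) -> str:
    """Edit intron positions (offsets relative to intron start) of a haplotype."""
    i0, _ = segment.intron_interval
    for off in subs:
        seq = _substitute(seq, i0 + off)
    if deletion is not None:
        d0, d1 = deletion
        seq = seq[: i0 + d0] + seq[i0 + d1:]
    return seq


_panel_cache: tuple | None = None


def build_default_panel() -> tuple[dict[str, SegmentModel], list[PanelHaplotype]]:
    """Packaged segment references plus the relational haplotype panel.

    The panel mirrors the structure reported for field material: IIS6 kdr
    haplotypes (I1011M, V1016I, S989P+V1016G) are single-/double-codon
    derivatives of the widespread clade-A wild type 2s6_A_03; clade B is
    separated from clade A by a 4 bp intron deletion plus four intron
    substitutions; IIIS6 has the F1534C haplotype 3s6_01 with the Asian
    T1520I+F1534C haplotype 3s6_13 derived from it, intron-only variants
    3s6_02/3s6_03, the I1532T haplotype 3s6_11 and the V1605A haplotype
    3s6_17.
    """
    global _panel_cache
    if _panel_cache is not None:
        return _panel_cache

    rng = np.random.default_rng(_PANEL_SEED)
    iis6 = _build_iis6(rng)
    iiis6 = _build_iiis6(rng)
    models = {"IIS6": iis6, "IIIS6": iiis6}

    a03 = iis6.sequence
    b00 = _intron_edit(iis6, a03, subs=(20, 45, 90, 130), deletion=(60, 64))
    panel = [
        PanelHaplotype("2s6_A_03", "IIS6", a03, "A"),
        PanelHaplotype("2s6_A_01", "IIS6", mutate_haplotype(iis6, {1011: "M"}),
                       "A", ((1011, "M"),)),
        PanelHaplotype("2s6_A_02", "IIS6", mutate_haplotype(iis6, {1016: "I"}),
                       "A", ((1016, "I"),)),
        PanelHaplotype("2s6_A_06", "IIS6",
                       mutate_haplotype(iis6, {989: "P", 1016: "G"}),
                       "A", ((989, "P"), (1016, "G"))),
        PanelHaplotype("2s6_B_00", "IIS6", b00, "B"),
        PanelHaplotype("2s6_B_04", "IIS6", _intron_edit(iis6, b00, subs=(100,)), "B"),
    ]

    w3 = iiis6.sequence
    h01 = mutate_haplotype(iiis6, {1534: "C"})
    panel += [
        PanelHaplotype("3s6_00", "IIIS6", w3),
        PanelHaplotype("3s6_01", "IIIS6", h01, aa_changes=((1534, "C"),)),
        PanelHaplotype("3s6_13", "IIIS6",
                       mutate_haplotype(iiis6, {1520: "I"}, base_sequence=h01),
                       aa_changes=((1520, "I"), (1534, "C"))),
        PanelHaplotype("3s6_02", "IIIS6", _intron_edit(iiis6, w3, subs=(30,))),
        PanelHaplotype("3s6_03", "IIIS6", _intron_edit(iiis6, w3, subs=(80,))),
        PanelHaplotype("3s6_11", "IIIS6", mutate_haplotype(iiis6, {1532: "T"}),
                       aa_changes=((1532, "T"),)),
        PanelHaplotype("3s6_17", "IIIS6", mutate_haplotype(iiis6, {1605: "A"}),
                       aa_changes=((1605, "A"),)),
    ]
    _panel_cache = (models, panel)
    return _panel_cache


def panel_index(panel: list[PanelHaplotype]) -> dict[str, PanelHaplotype]:
    return {h.name: h for h in panel}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _homopolymer_mask(seq: str) -> np.ndarray:
    """Boolean mask: True where the base belongs to a homopolymer run >= 3."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 3:
            mask[i:j] = True
        i = j
    return mask


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator,
                 hp_mask: np.ndarray | None = None) -> str:
    """Apply per-base substitution and (homopolymer-weighted) indel errors."""
    n = len(seq)
    if hp_mask is None:
        hp_mask = _homopolymer_mask(seq)
    indel_p = np.where(hp_mask, model.indel_rate * model.homopolymer_multiplier,
                       model.indel_rate)
    u_sub = rng.random(n)
    u_ind = rng.random(n)
    out: list[str] = []
    for i, c in enumerate(seq):
        if u_ind[i] < indel_p[i]:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(c)
            out.append(c)  # duplication-style insertion
            continue
        if u_sub[i] < model.substitution_rate:
            alts = [b for b in _BASES if b != c]
            out.append(alts[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)


def simulate_pool(config: PopulationConfig, panel: list[PanelHaplotype],
                  error_model: ErrorModel, seed: int) -> list[SimulatedRead]:
    """Simulate one population pool: barcoded single-end reads per segment.

    Read counts per haplotype are a multinomial draw from the configured
    frequencies; each read is barcode + full amplicon, passed through the
    error model (errors may hit the barcode and primers too).  Deterministic
    for a fixed (config, panel, error model, seed).
    """
    index = panel_index(panel)
    config.validate(set(index))
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for seg in SEGMENTS:
        if seg not in config.frequencies:
            continue
        names = sorted(config.frequencies[seg])
        freqs = np.array([config.frequencies[seg][n] for n in names])
        counts = rng.multinomial(config.reads_per_segment, freqs / freqs.sum())
        i_read = 0
        for name, count in zip(names, counts):
            template = config.barcode + index[name].sequence
            hp_mask = _homopolymer_mask(template)
            for _ in range(count):
                seq = apply_errors(template, error_model, rng, hp_mask)
                qual = chr(error_model.quality_mean + 33) * len(seq)
                reads.append(SimulatedRead(
                    read_id=f"{config.population_id}:{seg}:{i_read:05d}",
                    sequence=seq, quality=qual, origin=name,
                    population_id=config.population_id, segment_id=seg))
                i_read += 1
    return reads


# ---------------------------------------------------------------------------
# barcodes and manifest
# ---------------------------------------------------------------------------

def default_barcodes(n: int, length: int = 10, min_distance: int = 4) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(7)
    out: list[str] = []
    while len(out) < n:
        cand = _random_bases(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance for bc in out):
            out.append(cand)
    return out


MANIFEST_COLUMNS = ["barcode", "population_id", "country", "continent", "year"]


def write_manifest(configs: list[PopulationConfig], path) -> None:
    """Write the barcode manifest TSV (one row per population)."""
    barcodes = [c.barcode for c in configs]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in manifest")
    import pandas as pd

    df = pd.DataFrame(
        [[c.barcode, c.population_id, c.country, c.continent, c.year]
         for c in configs],
        columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path):
    """Read a barcode manifest TSV; returns a DataFrame with MANIFEST_COLUMNS."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty manifest")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in manifest")
    lengths = df["barcode"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError("manifest barcodes must have equal length")
    return df


# ---------------------------------------------------------------------------
# packaged demo scenario
# ---------------------------------------------------------------------------

def _logistic(year: int, midpoint: float = 2008.0, rate: float = 0.45) -> float:
    return float(1.0 / (1.0 + np.exp(-rate * (year - midpoint))))


def demo_populations(reads_per_segment: int = 2000) -> list[PopulationConfig]:
    """The packaged multi-population scenario.

    Encodes (i) the five localities fixed for the F1534C IIIS6 haplotype
    3s6_01 while segregating clade-B 2s6_B_00 against clade-A 2s6_A_02 —
    the configuration from which two independent origins of F1534C are
    inferred; (ii) an Asian population fixed for the S989P+V1016G IIS6
    haplotype; (iii) an older population carrying I1011M; and (iv) a
    Brazilian temporal series 2001-2015 in which the kdr haplotypes sweep
    upward along a logistic trajectory.  Pools emulate ~30 individuals
    each; read depth defaults to 2000 per segment.
    """
    specs: list[tuple[str, str, str, int, dict, dict]] = []
    fixed_01 = {"3s6_01": 1.0}
    for pop, country, cont, year, f_b00 in [
        ("PuertoRico", "Puerto Rico", "North America", 2012, 0.60),
        ("NewOrleans", "USA", "North America", 2014, 0.50),
        ("Iguala", "Mexico", "North America", 2012, 0.30),
        ("Amacuzac", "Mexico", "North America", 2012, 0.70),
        ("RibeiraoPreto", "Brazil", "South America", 2015, 0.45),
    ]:
        specs.append((pop, country, cont, year,
                      {"2s6_B_00": f_b00, "2s6_A_02": round(1 - f_b00, 10)},
                      dict(fixed_01)))
    # Asian population: IIS6 fixed for the S989P+V1016G haplotype -> phaseable
    specs.append(("Bangkok", "Thailand", "Asia", 2013,
                  {"2s6_A_06": 1.0}, {"3s6_01": 0.5, "3s6_13": 0.5}))
    # old New-World population carrying I1011M, monomorphic wild-type IIIS6
    specs.append(("Boavista", "Brazil", "South America", 1998,
                  {"2s6_A_01": 0.3, "2s6_B_00": 0.55, "2s6_A_03": 0.15},
                  {"3s6_00": 1.0}))
    # Brazilian temporal series: kdr haplotypes rise along a logistic curve
    for year in (2001, 2004, 2007, 2010, 2013, 2015):
        p = round(_logistic(year), 4)
        specs.append((f"Brazil{year}", "Brazil", "South America", year,
                      {"2s6_A_02": p, "2s6_B_00": round(0.8 * (1 - p), 10),
                       "2s6_A_03": round(0.2 * (1 - p), 10)},
                      {"3s6_01": p, "3s6_00": round(1 - p, 10)}))

    barcodes = default_barcodes(len(specs))
    configs = []
    for bc, (pop, country, cont, year, f2, f3) in zip(barcodes, specs):
        configs.append(PopulationConfig(
            population_id=pop, country=country, continent=cont, year=year,
            frequencies={"IIS6": f2, "IIIS6": f3}, barcode=bc,
            reads_per_segment=reads_per_segment))
    return configs
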