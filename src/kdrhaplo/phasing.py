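"""Cross-segment phasing in monomorphic populations and origin counting.

The two amplified Na_V segments sit ~44.5 kb apart — too far for any read
to span both — but within the range over which linkage disequilibrium in
*Aedes aegypti* decays only partially (~50-80 kb).  When a population is
monomorphic for one segment, every chromosome in the pool must carry that
segment's single haplotype, so each haplotype of the other (polymorphic)
segment can be phased with it combinatorially.  Phased haplotypes are
named ``Phased_<IIS6 id><clade>-<IIIS6 id>``.

A kdr mutation observed phased onto IIS6 backgrounds from *different*
intron clades cannot descend from a single mutational event, so the number
of distinct clades among its phased backgrounds is a lower bound on its
number of independent origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import HaplotypeAnnotation
from .clades import CladeAssignment


@dataclass
class TwoSegmentPopulation:
    population_id: str
    iis6: dict[str, float]
    iiis6: dict[str, float]
    country: str = ""
    continent: str = ""
    year: int = 0

    def __post_init__(self):
        for seg, freqs in (("IIS6", self.iis6), ("IIIS6", self.iiis6)):
            if not freqs:
                raise ValueError(f"{self.population_id}: empty {seg} map")
            if abs(sum(freqs.values()) - 1.0) > 1e-6:
                raise ValueError(f"{self.population_id}: {seg} frequencies "
                                 f"sum to {sum(freqs.values())}")


@dataclass(frozen=True)
class PhasedHaplotype:
    name: str
    iis6_name: str
    iis6_clade: str
    iiis6_name: str
    frequency: float
    population_id: str


@dataclass
class OriginReport:
    mutation: str
    backgrounds: set[tuple[str, str]]  # (IIS6 clade, IIS6 haplotype)
    min_origins: int | None
    supporting_populations: list[str]
    unobserved: bool = False


def _short_id(name: str) -> str:
    """Trailing numeric id of a haplotype name (2s6_B_00 -> 00)."""
    return name.rsplit("_", 1)[-1]


def is_phaseable(pop: TwoSegmentPopulation,
                 monomorphism_threshold: float = 1.0) -> bool:
    """True iff at least one segment is monomorphic.

    Strictly, monomorphic means exactly one haplotype; a threshold below
    1.0 relaxes this to "one haplotype at frequency >= threshold", a knob
    for pooled data where trace noise haplotypes can survive filtering.
    """
    def mono(freqs: dict[str, float]) -> bool:
        if monomorphism_threshold >= 1.0:
            return len(freqs) == 1
        return max(freqs.values()) >= monomorphism_threshold

    return mono(pop.iis6) or mono(pop.iiis6)


def phase_population(pop: TwoSegmentPopulation, clades: CladeAssignment,
                     monomorphism_threshold: float = 1.0
                     ) -> list[PhasedHaplotype]:
    """Phase one population: pair each polymorphic-segment haplotype with
    the fixed haplotype of the monomorphic segment, carrying frequencies.
    """
    if not is_phaseable(pop, monomorphism_threshold):
        raise ValueError(f"{pop.population_id} is not phaseable "
                         "(both segments polymorphic)")

    def fixed_name(freqs: dict[str, float]) -> str | None:
        if monomorphism_threshold >= 1.0:
            return next(iter(freqs)) if len(freqs) == 1 else None
        top = max(freqs, key=freqs.get)
        return top if freqs[top] >= monomorphism_threshold else None

    iis6_fixed = fixed_name(pop.iis6)
    iiis6_fixed = fixed_name(pop.iiis6)

    pairs: list[tuple[str, str, float]] = []
    if iiis6_fixed is not None and iis6_fixed is None:
        pairs = [(h2, iiis6_fixed, f) for h2, f in pop.iis6.items()]
    elif iis6_fixed is not None and iiis6_fixed is None:
        pairs = [(iis6_fixed, h3, f) for h3, f in pop.iiis6.items()]
    else:  # both fixed
        pairs = [(iis6_fixed, iiis6_fixed, 1.0)]

    phased = []
    for h2, h3, freq in sorted(pairs):
        clade = clades.labels.get(h2, "")
        name = f"Phased_{_short_id(h2)}{clade}-{_short_id(h3)}"
        phased.append(PhasedHaplotype(name, h2, clade, h3, freq,
                                      pop.population_id))
    return phased


def _parse_mutation(mutation: str) -> tuple[int, str]:
    """``F1534C`` -> (1534, 'C')."""
    import re

    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", mutation)
    if not m:
        raise ValueError(f"cannot parse mutation label {mutation!r}")
    return int(m.group(2)), m.group(3)


def _carries(annotation: HaplotypeAnnotation, residue: int, alt_aa: str) -> bool:
    return any(c.residue_number == residue and c.alt_aa == alt_aa
               for c in annotation.exon_changes)


def infer_min_origins(phased: list[PhasedHaplotype], mutation: str,
                      annotations: dict[str, HaplotypeAnnotation],
                      segment_id: str | None = None) -> OriginReport:
    """Lower-bound the number of independent origins of a kdr mutation.

    For an IIIS6 mutation, backgrounds are the distinct IIS6 clades seen
    phased with it (with the IIS6 haplotype recorded alongside); the bound
    is the clade count.  For an IIS6 mutation, the bound is the number of
    distinct IIS6 haplotypes carrying it among the phased set.  A mutation
    never observed phased yields an "unobserved" report, not zero.
    """
    residue, alt_aa = _parse_mutation(mutation)
    if segment_id is None:
        segment_id = next(
            (a.segment_id for a in annotations.values()
             if any(c.residue_number == residue for c in a.exon_changes)),
            None)
        if segment_id is None:
            # fall back on the catalogue convention: IIS6 residues < 1500
            segment_id = "IIS6" if residue < 1500 else "IIIS6"

    backgrounds: set[tuple[str, str]] = set()
    supporting: list[str] = []
    for ph in phased:
        if segment_id == "IIIS6":
            ann = annotations.get(ph.iiis6_name)
            if ann is not None and _carries(ann, residue, alt_aa):
                backgrounds.add((ph.iis6_clade, ph.iis6_name))
                supporting.append(ph.population_id)
        else:
            ann = annotations.get(ph.iis6_name)
            if ann is not None and _carries(ann, residue, alt_aa):
                backgrounds.add((ph.iis6_clade, ph.iis6_name))
                supporting.append(ph.population_id)

    if not backgrounds:
        return OriginReport(mutation, set(), None, [], unobserved=True)
    if segment_id == "IIIS6":
        min_origins = len({clade for clade, _ in backgrounds})
    else:
        min_origins = len({hap for _, hap in backgrounds})
    return OriginReport(mutation, backgrounds, min_origins,
                        sorted(set(supporting)))


def hypothesis_edges(phased: list[PhasedHaplotype],
                     sequences: dict[str, str]) -> list[tuple[str, str]]:
    """Narrative edges between phased haplotypes differing by one mutation.

    Connects phased haplotypes whose combined two-segment sequences are one
    mutational step apart — the descent hypotheses a reader would draw, not
    an inference.
    """
    from .network import mutational_steps

    uniq = {}
    for ph in phased:
        uniq[ph.name] = sequences.get(ph.iis6_name, "") + "|" + \
            sequences.get(ph.iiis6_name, "")
    names = sorted(uniq)
    edges = []
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            a2, a3 = uniq[u].split("|")
            b2, b3 = uniq[v].split("|")
            if mutational_steps(a2, b2) + mutational_steps(a3, b3) == 1:
                edges.append((u, v))
    return edges
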