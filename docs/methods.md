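# Methods

## The biological problem and the packaged references

The package analyses two short amplicons of the *Aedes aegypti*
voltage-gated sodium channel gene: the IIS6 region (352 bp amplicon) and
the IIIS6 region (354 bp), each consisting of a forward primer site, a
first exon window, a single intron, a second exon window and a reverse
primer site. Residues are numbered by homology to the *Musca domestica*
channel, the convention used throughout the insecticide-resistance
literature. The kdr catalogue covers S989, I1011 and V1016 (IIS6;
resistant alleles P, M, and I/G respectively) and T1520, I1532 and F1534
(IIIS6; resistant alleles I, T, C). Codons at catalogued sites are fixed
to the field-reported wild types (989 TCC, 1011 ATA, 1016 GTA, 1520 ACC,
1532 ATT, 1534 TTC); remaining exon codons are arbitrary sense codons.
In each exon window the first complete codon carries an explicit residue
number, so the two IIIS6 exon windows can map to non-contiguous protein
coordinates (1515… and 1595…, putting residue 1605 in the second window).

The real haplotype sequences from field studies are deposited in public
archives rather than printed, so the packaged panel is **synthetic**: it
reproduces the *relational* structure of the field panel — the kdr
haplotypes `2s6_A_01` (I1011M), `2s6_A_02` (V1016I) and `2s6_A_06`
(S989P+V1016G) are one- or two-codon derivatives of the widespread
wild-type `2s6_A_03`; a second IIS6 lineage (`2s6_B_00`, `2s6_B_04`) is
separated from clade A by a 4 bp intron deletion plus four intron
substitutions; IIIS6 carries the F1534C haplotype `3s6_01`, its Asian
derivative `3s6_13` (T1520I+F1534C, one further step), intron-only
variants `3s6_02`/`3s6_03`, the I1532T haplotype `3s6_11` and the V1605A
haplotype `3s6_17`. Panel sequences are generated from a fixed internal
seed and are identical across sessions.

## Read simulation

Pools emulate ~30 diploid individuals per population. Each simulated read
is barcode + full amplicon passed through a per-base error model:

- `substitution_rate` (default 0.005/base) — uniform random substitutions;
- `indel_rate` (default 0.001/base), multiplied by
  `homopolymer_multiplier` (default 3) inside homopolymer runs ≥ 3 — the
  dominant single-end semiconductor-sequencing failure mode; indels are
  single-base deletions or duplications;
- `quality_mean` (default Phred 30) written as a flat quality string.

Haplotype counts per pool are one multinomial draw from the configured
frequencies. One `numpy` generator per `simulate_pool` call, seeded
explicitly, makes output byte-reproducible. Default depth is 2000 reads
per segment per population — enough that multinomial noise on a 1/60
allele is small, while keeping the full demo pipeline to ~15 s.

What the simulator does *not* emulate: PCR chimeras and polymerase errors,
quality-score heterogeneity along the read, strand mixtures, depth
variation across pools, and contamination. Passing recovery tests on this
generator therefore demonstrates correctness of the pipeline's logic under
a realistic error magnitude, not robustness to every real-data artefact.

## Haplotype calling

Demultiplexing assigns a read to a population iff exactly one manifest
barcode lies within `barcode_max_mismatch` (default 1) of its prefix;
ties go to the unassigned bin. Filtering requires both primers (each
within one mismatch, at the read ends, after orienting the read forward),
a primer-trimmed length inside `length_window` (default 300–380 bp) and
mean quality ≥ 20.

The denoiser is deliberately simple and fully specified:

1. exact dereplication into (sequence, count);
2. iterated absorption, visiting minor sequences in ascending count (ties
   broken lexicographically): a minor is merged into the *nearest*
   surviving sequence within `collapse_distance` edits (default 2,
   Levenshtein) that is at least `abundance_ratio` (default 20) times more
   abundant, breaking distance ties by abundance. Nearest-first matters:
   with haplotypes only 1–2 SNPs apart, absorbing into the most abundant
   in-range sequence drains a minor haplotype's one-error cloud into a
   neighbour one extra edit away and biases frequencies by several
   percent. Sequences differing from a more abundant one only by one
   homopolymer-run length are merged regardless of the ratio (platform
   error profile);
3. survivors below `frequency_floor` (default 0.01) are dropped and
   frequencies renormalised.

The floor sits below 1/60, the smallest real allele frequency in a pool of
30 diploids, so a single resistant chromosome remains callable. The
abundance ratio of 20 implies a known sensitivity limit: a true haplotype
within 2 edits of a ≥20-fold more abundant neighbour (e.g. a kdr
derivative at < ~5% against a fixed wild type) is absorbed as if it were
error. Under the default error model, measured recovery for three
haplotypes at 0.6/0.3/0.1 across 20 seeded pools is precision = recall = 1
with frequency RMSE ≈ 0.012–0.017.

Shared sequences across populations receive one name: segment prefix
(`2s6_`/`3s6_`) plus zero-padded rank by total read count; sequences
matching the packaged panel keep their panel names.

## Annotation

Each haplotype is globally aligned to its primer-trimmed reference with
affine gaps (match +1, mismatch −2, gap open −4, extend −1; identity
< 70% raises a foreign-sequence error). Exon codons are compared in frame;
a codon with any number of changed bases yields one amino-acid change,
reported as e.g. `V1016I` (synonymous changes as `V1016V`), labels joined
with `+` in ascending residue order. Intron differences are listed but
never translated. Any exonic indel flags the haplotype as a putative
artifact and excludes it from translation — the amplified exons are under
strong purifying selection and a frameshift there is essentially always a
sequencing artefact. Coordinates are 0-based half-open internally and
1-based in reports.

## Parsimony networks

The mutational-step distance between two haplotypes is the number of
substitution columns plus the number of contiguous gap runs (one indel
event may insert or delete several bases) in their optimal alignment. Two
subtleties are handled explicitly:

- *Which alignment:* a literal minimisation of substitutions + gap runs
  over all alignments is degenerate — deleting one sequence entirely and
  inserting the other costs two "events", collapsing every pair to ≤ 2
  steps. Steps are therefore counted on the **score-optimal** alignment
  under the standard scoring above; among score-tied alignments the step
  count is minimised. This is computed exactly by a three-state affine DP
  over the pair (score, steps), optimised lexicographically.
- *Connection limit:* the probability that j observed differences are
  parsimonious is modelled by a multiple-hit argument in the spirit of
  statistical parsimony: mutations strike m sites uniformly and
  independently, and the observed differences reflect the true events iff
  no site is struck twice, so P_j = ∏_{i=1}^{j−1}(1 − i/m). The limit is
  the largest j with P_j ≥ the confidence (default 0.95), giving 6 steps
  for both packaged segments. P_j is monotone in j and the limit monotone
  in m; as confidence → 0 the limit approaches m.

Edges at or below the limit are added in ascending step order; within one
step tier every edge joining components that were distinct at the start of
the tier is kept, so equal-step alternative connections survive as
reticulations, while edges internal to an earlier-connected component are
skipped — each component then carries a minimum-step spanning structure.
No median (inferred intermediate) haplotypes are added; a multi-step edge
carries its count instead, keeping the graph exactly checkable against
brute force. Networks serialise to GraphML with node frequency/label and
edge step attributes.

## Clade partition

IIS6 haplotypes are bipartitioned on intron distance: the bases each
haplotype aligns into the reference intron window (insertions included),
compared by Levenshtein distance normalised by the longer intron string.
Average-linkage hierarchical clustering is cut into two groups at the
root. The group containing the anchor — a haplotype with a catalogued kdr
exon change — is labelled A; failing that, the group nearest the packaged
clade-A reference intron. The partition is deterministic, independent of
input order, and blind to exon variation by construction. A
maximum-likelihood tree would recover the same bipartition for
intron-indel-separated lineages; the distance formulation trades the
bootstrap machinery for an exactly testable contract. IIIS6 intron
variation does not support clades and is rejected with an error.

## Phasing and origin counting

The two segments lie ~44.5 kb apart on the chromosome — far beyond any
read — but population fixation substitutes for read-backed phasing: if a
population carries exactly one haplotype at one segment, every chromosome
in the pool carries it, and each haplotype of the other segment phases
with it at its own frequency. "Monomorphic" is strict (exactly one called
haplotype) by default; a `monomorphism_threshold` knob (< 1.0) relaxes
this to a dominant haplotype above the threshold, for pooled data where
trace noise survives filtering.

For a IIIS6 mutation, each phased occurrence contributes its IIS6 partner
(clade, haplotype) as a background; the minimum number of independent
origins is the number of distinct clades observed — haplotypes within one
clade can share descent, haplotypes across the intron-defined clades
cannot. For an IIS6 mutation the bound is the number of distinct IIS6
haplotypes carrying it. A mutation never observed phased yields an
"unobserved" report rather than zero. Descent hypotheses (edges between
phased haplotypes one mutational step apart) are emitted as annotation
only, never as inference.

## Temporal trends

Within a country with ≥ 2 collection years, each haplotype's trajectory is
the set of (year, population, frequency) points, with frequency 0 where
the haplotype is absent; the trend statistic is Spearman's rho of year vs
frequency, classified as increasing (> 0.3), decreasing (< −0.3) or flat.
Rank correlation was chosen because the temporal claim of interest is
qualitative (a sweep), making regression slopes and their error models
unnecessary; constant trajectories are reported as flat (rho 0). In the
packaged Brazilian series (logistic sweep of the F1534C haplotype,
2001–2015) the measured rho is ≈ +0.99 for `3s6_01` and ≈ −0.99 for the
wild type.

## Problem sizes and determinism

The packaged scenario has 13 populations (five fixed for `3s6_01` and
segregating clade-A vs clade-B IIS6 haplotypes, one Asian population fixed
for `2s6_A_06`, one older population carrying I1011M, six Brazilian
populations spanning 2001–2015), 2000 reads per segment per pool. The
recovery experiment uses 20 seeded pools. All randomness descends from a
single integer seed via `SeedSequence` spawning; identical configuration
and seed reproduce every output byte for byte.

## Known limitations

- The panel is synthetic; analyses of real amplicon data depend on the
  packaged references matching the sequenced region, and real haplotype
  diversity (dozens of intron variants) is represented only structurally.
- The denoiser's abundance ratio bounds sensitivity to rare variants near
  abundant neighbours (see above); it performs no chimera detection and
  no per-base quality weighting.
- The two-clade partition assumes exactly two intron lineages; more
  structured intron variation would still be forced into two groups.
- Origin counts are lower bounds: identical backgrounds cannot exclude
  recurrent mutation on the same haplotype.
- The parsimony probability model ignores rate heterogeneity across sites
  and back-mutation; its limit should be read as a conventional
  connection cut-off, not a calibrated error rate.
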