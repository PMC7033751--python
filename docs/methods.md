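# Methods

`repnatal` analyzes immunoglobulin heavy-chain (Igh) V(D)J rearrangement
repertoires of the kind produced by amplicon sequencing of sorted pro B
cell subsets, and ships a ground-truthed recombination simulator so that
every analysis stage can be exercised end to end without external data.
This note records the models, conventions, and numerical choices, and what
the synthetic test bed does and does not establish about real data.

## Coordinates, anchors, and the CDR-H3

All coordinates are 0-based, half-open. A germline reference is a set of
V, D, and J segments; each V carries the offset of its conserved FR3
cysteine codon (position 96 of the heavy chain), each J the offset of its
conserved FR4 tryptophan codon. The junction of a read is the nucleotide
stretch from the Cys codon start through the Trp codon end. The CDR-H3 is
the translated junction with the flanking Cys and Trp removed.

CDR-H3 residues are numbered by linear offset from the FR3 cysteine:
Cys = 96, first CDR-H3 residue = 97, so position 101 is the fifth CDR-H3
residue. PDB/Kabat-style insertion codes for long loops are deliberately
not reconstructed — they are not derivable from a linear amplicon without
a full numbering scheme — so the linear rule is the package-wide
convention and 101 always means "fifth residue of the loop". Loops shorter
than five residues have no position 101 and are excluded from Y101
denominators only; they still count toward productivity and length
statistics.

Reads are assumed to span the V segment's 5' end through the J segment's
3' end (the amplicon structure of family-consensus forward primers with a
constant-region reverse primer). This fixes the V reading frame at read
offset 0 and lets the Trp codon end be located from the read end and the
germline J length, independent of the unknown J 5' trim.

## Productivity

A rearrangement is **productive** iff

1. the junction length is divisible by 3 (the V reading frame carries
   through into FR4),
2. translation of the read in the V frame contains no stop codon, and
3. both anchors are present (Cys at 96, Trp opening FR4).

Calls are **undetermined** — reported separately, never silently dropped —
when the anchors cannot be resolved (unknown gene calls, coordinates
outside the read, read not starting on a V codon boundary) or when an
ambiguous nucleotide would force a guess: a codon containing N is treated
as non-stop, and any N in the frame downgrades the call to undetermined
rather than fabricating a stop/non-stop decision. Anchors that resolve but
encode the wrong residue make the record non-productive.

## Dereplication

Reads collapse by exact full-length nucleotide identity; the
representative keeps the first-seen annotations and a `duplicate_count`
equal to the summed input counts. Output is ordered by descending count,
ties by sequence, making tables reproducible. Whether the original study
dereplicated full amplicons or trimmed V regions is not stated anywhere we
could rely on; full-read identity is the documented choice here because it
keeps the unique/productive quotient well defined.

## Y101 statistics and biochemical classes

Per V gene and subset, Y101 frequency is the fraction of unique productive
CDR-H3s (with a position 101) carrying tyrosine there. Genes enter the
cross-subset comparison only when their unique-productive count strictly
exceeds `min_n` (default 50) in *both* subsets; the strict inequality
follows the ">50" convention, and the flag is configurable because "at
least 50" appears as an alternative reading. The modal residue at 101
decides predominance (Y101 vs non-Y101); ties involving Y resolve to Y —
conservative toward the null of tyrosine enrichment — and ties among
non-Y residues resolve lexicographically.

The biochemical partition of the modal residue follows the
Kyte–Doolittle hydropathy convention with histidine counted as charged:
charged = {D,E,K,R,H}, hydrophobic = {A,V,L,I,M,F,C}, neutral =
{G,S,T,N,Q,P,W,Y}. Tyrosine sits in the neutral class; its special role at
position 101 is tracked by the Y101 statistic, not the partition.

## Diversity

The Shannon index is H = −Σ pᵢ ln pᵢ in nats (a `base=2` flag yields
bits). Rarefaction subsamples *replicated reads* (duplicate-count
weighted) without replacement at a grid of depths — by default 10
log-spaced depths from 10 to the total — with 200 replicate subsamples per
depth in the library default (50 in the shipped pipeline configuration,
which trades Monte-Carlo error for runtime at toy scale). Species are
unique CDR-H3 amino-acid strings for in-frame reads; out-of-frame reads
fall back to the nucleotide junction so that total replicated sequences
remain comparable across subsets, and a nucleotide-level species option
exists. Whether diversity should be computed on amino-acid or nucleotide
species is genuinely open; amino-acid is the documented default because
the quantity of interest is loop diversity.

## J trimming

The J 5' trim of a read is the smallest germline J offset whose suffix
exactly matches the read end (minimal-trim convention). When a junctional
N nucleotide happens to extend the germline match the estimate is biased
low by that coincidence — the same identifiability limit every annotator
faces — which is why parameter-recovery checks compare against simulator
truth rather than re-annotation.

## The simulator

Each clone draws V, D, J genes from configurable weight maps (`d_weights`
may include a `"D-less"` pseudo-gene for direct V–J joins), geometric trim
lengths (support 0,1,2,…) with configurable means for the V 3', D 5',
D 3' and J 5' ends, and — when `tdt_on` — Poisson-length N blocks of
uniform A/C/G/T at each joint. Geometric trimming is the simplest
memoryless model and is a placeholder: no quantitative trimming or
insertion-length distributions exist for these subsets, so the defaults
are study conditions, not fits. Trims that would remove an anchor codon
are resampled (capped at 100 tries, then clamped), so anchors always
survive; consequently configured trim means are recovered slightly
truncated when they approach the available germline tail (the toy J
prefixes are 12–15 nt, keeping the truncation bias of a mean-2 trim under
~3%). Clone read counts follow a geometric distribution (mean 3 by
default), producing the skewed replicate structure rarefaction needs.

`y101_target` sets the probability that a productive clone with a
position 101 carries tyrosine there. It is enforced by rejection sampling
whole rearrangements: each such clone is assigned Y/non-Y status by a
Bernoulli(`y101_target`) coin and redrawn until the realized residue class
matches. Clones that are non-productive or too short on first draw are
accepted as-is, so marginal productivity, usage, and trimming statistics
are essentially untouched; sequences are never edited, keeping all joint
statistics internally consistent. Exceeding `max_rejections` (default
5000) raises with the achieved acceptance rate.

### The toy reference

`build_toy_reference(seed)` synthesizes 8 V genes across 7 families
(including VH81X-, J558-, Ighv11- and Ighv12-like stand-ins), 3 D genes
(DFL16.1-like tyrosine-rich, DSP-like, short DQ52-like) and 4 J genes. V
cores are random stop-free codons (seeded); every V ends with the Cys
codon plus a 3-nt tail, every J starts with a codon-aligned 12–15-nt
CDR3 prefix before the FR4 W-G-x-G motif, so untrimmed joins are in frame
and stop-free by construction. Equal V tail lengths keep the residue
distribution at position 101 independent of the V gene, which keeps the
Y101 rejection sampler from tilting V usage.

Locus domains are assigned as contiguous blocks of the proximal-to-distal
gene order (two genes per domain), so the distal block (domain 4) holds
the J558-like Ighv1 family, mirroring the CTCF-delimited four-domain
organization of the real locus. For real data the domain map is a
user-supplied table, since published domain boundaries are not bundled.

### Subset presets

Four presets (`FL_FCRL6pos`, `FL_FCRL6neg`, `BM_FCRL6pos`, `BM_FCRL6neg`)
encode the contrasts the pipeline is built to expose: FL presets are
Tdt-off, BM presets Tdt-on with mean 4-nt N blocks; FCRL6+ presets carry
heavier junctional trimming, stronger distal/domain-4 V usage, more
D-less joins, and lower `y101_target` than their FCRL6− counterparts.
Trimming intensity is the preset dial for productivity because, with
codon-aligned germline segments, the probability that the total of trims
and insertions is ≡ 0 (mod 3) — and hence the in-frame fraction — falls
from near 1 toward 1/3 as junctional entropy grows.

## Productivity accounting at toy scale

Dereplication collapses probability mass but not support: the unique
sequences of a small combinatorial space are close to an enumeration of
its distinct junctional variants, of which ~1/3 are in frame regardless of
how the probability mass is distributed. At the scale of a real dataset
(hundreds of thousands of reads over >100 genes) the unique-level
productive fraction is informative; at toy scale it is pinned near 1/3.
The pipeline therefore reports both: `unique_productivity_fraction` (the
per-unique-rearrangement quotient) and the headline
`productivity_fraction`, which is read-weighted (equivalently,
per recombination event), where the subset contrast is visible at any
scale.

## Locus accessibility

Count normalization is median-of-ratios: for genes with positive counts
in every sample, each sample's size factor is the median ratio of its
counts to the per-gene geometric mean. This is the standard size-factor
algorithm and a documented stand-in for a full differential-expression
normalization; exact equality with any particular tool's output is not
claimed, though the unit tests cross-check the factors against an
independent implementation. Factors are defined only up to a common
scale, so "scale invariance" of normalized columns holds up to a single
global constant. Per sample group, normalized counts are averaged across
replicates per gene, then summed into domain and family totals and
frequencies. Genes absent from the domain or family map are excluded and
logged; matching is case-insensitive and allele-stripped. All-zero gene
rows are preserved and carry no ratio information; a matrix with no
all-positive gene row is an error suggesting a pseudo-count.

## Pipeline determinism and problem sizes

A run is configured by one YAML with an explicit base seed; subset
simulation seeds derive as `base*100 + index`, the rarefaction seed is the
base seed, and all outputs are plain TSVs written in deterministic order,
so reruns are byte-identical. The shipped demonstration compares the two
FL presets at 4,000 clones per subset (~12,000 reads each) with 50
rarefaction replicates and a shared-gene threshold of `min_n = 20` — the
>50 cut is calibrated to datasets three orders of magnitude larger, and
with 8 toy genes and fetal (Tdt-off) junctional entropy the per-gene
unique-productive counts sit proportionally lower. Parameter-recovery
checks use 2,000 clones, where binomial noise on a Y101 target of 0.15 is
±0.016 (1 s.d.) and multinomial 99% simultaneous bounds on V usage are
±0.02–0.03.

## What the synthetic test bed does and does not show

The generator reproduces the *structure* of subset amplicon data —
clonally replicated reads over a small V panel, mixed productive and
non-productive joins, D-less joins, subset-specific productivity, distal
V usage and Y101 composition — with known truth, so it validates the
correctness of every analysis stage and the direction of the engineered
contrasts. It does not emulate: somatic hypermutation or sequencing
error (exact dereplication and exact suffix matching would both need
relaxing); realistic trimming/insertion length laws; GC bias in
N-addition; primer or amplification bias; or light chains. One known
inversion at toy scale: heavier trimming *increases* junctional entropy,
so the FCRL6+ preset shows a higher Shannon curve than FCRL6−, whereas
real FCRL6+ repertoires are less diverse — constrained diversity in vivo
arises from clonal structure and locus restriction, not from trimming, and
the rarefaction machinery is validated instead by its closed-form and
ordering properties. Passing tests therefore certify the analysis code
and the simulator's internal consistency, not biological parameter
values.
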