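# Methods

## Data model

An amplicon reference is the genomic, pre-bisulfite plus-strand sequence of
a PCR-defined segment together with its primer pair and a CpG coordinate
map. Internally every CpG is addressed by the 0-based offset of its C in
the amplicon; all user-facing output uses the integer TSS-relative labels
under which the locus's CpGs are conventionally reported (e.g. DDO CpG
105). Labels are names, not coordinates: the synthetic references place
CpGs at label-derived offsets but enforce ≥ 2 nt spacing where labels are
adjacent. Minus-strand amplicons are independent references with their own
maps; strands are never merged, since strand-specific methylation is a real
observable at some loci.

Bisulfite chemistry is modeled as total conversion of unmethylated C to T
with methylated C (including hydroxymethyl-C, which bisulfite cannot
distinguish) protected. Conversion of the reference for alignment therefore
replaces every non-CpG-context C by T and leaves CpG Cs as C/T-ambiguous
positions.

## Read QC

Reads are aligned semi-globally (reference overhangs free, read overhangs
penalized) to the converted reference with Biopython's `PairwiseAligner`
under match +2, mismatch −3, gap open −5, gap extend −2; CpG-context
positions score as matches against both C and T, and N is neutral. The
scoring values are configurable; they are ordinary short-read alignment
weights and the pipeline's decisions depend on them only through the
aligned-fraction filter. The first optimal traceback is taken, so results
are deterministic. The test suite checks the aligner against an independent
affine-gap dynamic-programming oracle on small references.

Four retention filters run in a fixed order — length, primer, conversion,
aligned fraction — and each read is counted against the first filter it
fails, which makes attrition reports comparable across runs and forces the
counts to sum to the input. All thresholds are inclusive (≥), defaulting to
0.5 × reference length, 0.80 primer identity (best ungapped placement of
the converted forward primer within the first 1.5 primer-lengths of the
read), 0.98 conversion efficiency and 0.60 aligned fraction. Reads longer
than 3× the reference are rejected as non-amplicon material and counted as
alignment failures. Conversion efficiency is the fraction of covered
non-CpG-context reference cytosines read as T, computed on the aligned span
only; reads covering no such cytosine are uninformative and fail the
filter. The mean efficiency over retained reads is reported as the sample's
conversion-rate estimate.

One consequence worth knowing: a hard per-read cutoff of 0.98 under a
realistic per-base conversion rate of 0.985 rejects roughly a third of
reads (a read with ~75 non-CpG cytosines fails as soon as 2 conversions
miss). This is faithful to the filter as specified; the loss is unbiased
with respect to methylation patterns, so downstream frequencies are
unaffected beyond depth.

## Epialleles

At each reference CpG the aligned read base is called M (C), U (T) or
ambiguous (A/G/N, a gap, or an uncovered CpG). Reads with any ambiguous
call are dropped when the methylation matrix is built — patterns are always
full-length — and that drop count is folded into the QC report. Patterns
are rendered as strings over {1,0} with 1 = methylated, in reference CpG
order.

## Population statistics

Per-CpG methylation is the count-weighted column mean; the overall mean
weights CpGs equally. Shannon entropy is computed over epiallele
frequencies in bits (base 2; the base is a convention and is stated in
output headers). Because attainable entropy is capped by both the pattern
space 2^k and the read depth n, a normalized value H / log₂(min(n, 2^k))
is emitted alongside the raw one; both are reported since either
normalization convention is defensible. Group comparison is the classical
two-sided unpaired t test; stage-to-stage similarity is the Pearson
correlation of epiallele frequency vectors over the union pattern space
with absent patterns at 0. PCA operates on the samples × patterns
frequency matrix (frequencies, not counts, so depth differences do not
masquerade as biology), column-centered, via a full SVD; identical samples
are reported as zero explained variance rather than NaN.

## Core discovery

### Null model

Under the null hypothesis, CpGs methylate independently with probabilities
equal to their observed marginal frequencies m_j/n. The evidence for a core
S is the upper tail probability of the observed joint count k_obs
(molecules methylated at every CpG of S). Two computations are provided:

* **binomial** (default): X ~ Binomial(n, p0), p0 = Π m_j/n, evaluated
  through the regularized incomplete beta function so p-values far below
  10⁻¹⁰⁰ are resolved. This plug-in null treats the margins as known
  probabilities.
* **conditional**: the exact distribution of the intersection size of
  independent uniformly random m_j-subsets of n molecules — precisely the
  null sampled by independently permuting each CpG column of the matrix.
  It is built by iterated hypergeometric convolution: after one column the
  intersection is m_1; conditional on intersection s, adding a column with
  margin m gives Hypergeometric(n, s, m). Cost is O(k·n²) in the worst
  case, so it is the reference computation rather than the screening
  default.

The two nulls are not interchangeable in the middle of the distribution:
conditioning on the margins removes their sampling variance, so the
permutation null is under-dispersed relative to the plug-in binomial (for
two CpGs at margin n/2 the variance ratio approaches 3). In the far upper
tail — the only regime where cores are called at α = 10⁻¹⁰ — the binomial
tail is the larger of the two, i.e. conservative, which the test suite
asserts. The permutation-agreement checks therefore validate the
conditional computation against Monte-Carlo column permutation (they agree
to MC accuracy because they compute the same distribution), while a
separate check documents the conservative ordering of the binomial
screen. Earlier designs that compared the plug-in binomial directly to a
permutation band conflate the two nulls and fail for mid-range p-values.

### Search and reporting

All CpG subsets of size 2..max_size (default 6) are evaluated depth-first
with prevalence pruning: joint frequency is monotone non-increasing under
label addition, so a subset below the prevalence floor cannot itself be
reported nor can any superset, and the branch is cut. The suite verifies
against exhaustive all-subset evaluation that pruning never changes the
output. A core is significant when p < α (default 10⁻¹⁰), f_obs > f_exp,
and f_obs ≥ min_prevalence (default 0.25, "a relevant fraction of
molecules"; 0.5 is the stricter "majority" preset). α is deliberately
extreme; with at most Σ C(18, s) ≈ 2.6 × 10⁴ subsets on the largest
design, no multiplicity correction is needed at that level, though a
Bonferroni toggle over the subset count is available. Output order is
deterministic: size descending, then p ascending, then label order.
Tables under 50 reads are processed but flagged low-depth.

Nested significant cores whose joint frequencies agree within a tolerance
(default 0.05) are collapsed to the largest — the superset explains the
subset at essentially the same prevalence — yielding the maximal cores
used for reporting, profiles and trees.

A property of the independence null worth noting: as a core family
approaches fixation, the member CpGs' marginals rise, the independence
expectation rises with them, and the relative enrichment shrinks — a fully
methylated population contains no detectable core at all (f_exp = 1).
Detectability is maximal at intermediate prevalence; at shallow depth a
very prevalent core can escape the α threshold even though its joint
frequency is high.

### Trajectories

Significant cores are grouped across ordered time points by label-set
identity, and label sets related by inclusion (composition changes such as
105-138-150 → 105-138) are linked into one lineage by union-find. Every
trajectory carries the joint frequency of its label set at *all* time
points, including times where the set is not significant, so frequency
series are complete. A trajectory is stable when its set is significant at
two or more consecutive time points.

## Identity tree

Each sample's profile is the union of labels over its maximal significant
cores; samples with no cores are flagged and omitted from the tree.
Dissimilarity is the Jaccard distance on label sets (1 − |A∩B|/|A∪B|),
which directly encodes shared methyl-CpG arrangement and is a proper
metric (property-tested). Clustering is UPGMA — the tree's semantics are
"groups sharing core composition", which average linkage with an
ultrametric output expresses, and which neighbor joining does not — with a
deterministic tie-break: among tied minimal pairs, the pair whose sorted
leaf-name tuples compare lexicographically lowest is merged, making the
newick output invariant under input reordering. UPGMA is implemented
directly (a few dozen lines) because library linkage functions do not
expose this tie-break; the suite validates it against a hand-computed
example and checks ultrametricity by parsing the newick with dendropy.
Distance choice and algorithm are explicit reconstructions validated by
grouping behavior; no claim is made about matching any particular published
figure's unstated construction.

## Synthetic data

The generator emulates the statistical structure of deep bisulfite amplicon
sequencing of a differentiating population:

* **Families.** Molecules are drawn from a mixture: one or more epiallele
  families, each defined by a core label set and a prevalence, plus
  core-free background. Family molecules methylate at their core CpGs with
  fidelity 0.95 (cores are stable, not perfectly clonal) and elsewhere at
  the background marginal (default 0.1); background molecules use the
  marginals throughout.
* **Chemistry and noise.** Reads are the full amplicon (no fragmentation,
  as in amplicon sequencing). Non-CpG cytosines convert with probability
  0.985 per base, inside the 98–99% range expected of a successful
  treatment; substitution errors occur at 10⁻³ per base; each CpG is
  replaced by N at 10⁻² to model ambiguous calls.
* **Time courses.** Per-time overrides of the family structure encode
  schedules: the DDO-like preset is a transient (prevalence 0.3, 0.4, 0.7,
  0.4, 0.3 across T0–T14 for core 105-138-150), the NANOG-like preset a
  late gain (core 365-375 absent until T8, then 0.5 → 0.6, with rising
  background). Per-time seeds derive arithmetically from the master seed,
  and identical seeds give byte-identical FASTA output.

Default depths (800–5000 reads per sample, hundreds retained after QC) are
chosen for statistical power at α = 10⁻¹⁰ at desk scale; closed-form
mixture expectations (`expected_joint_frequency`) provide the ground truth
the tests compare against, always within 3 binomial standard errors.

What the generator does *not* model — PCR duplicates and chimeras,
position-dependent quality, paired-end structure, multiple interleaved
families with overlapping cores beyond the configured mixture, strand
asymmetries — bounds what passing tests demonstrate: the pipeline's
statistical machinery is correct on populations with planted structure,
not that any particular biological locus behaves like the simulation.

## Numerical and degenerate-input conventions

All probability thresholds are inclusive. P-values are serialized at full
text precision so 10⁻³⁰⁰ survives a round trip; binomial tails are
computed via the incomplete beta function and conditional tails in linear
probability space with support trimming. Empty read files are valid (empty
outputs, not errors); empty epiallele tables raise on statistics that are
undefined without reads. Zero-variance distributions raise in correlation;
identical samples yield zero explained variance in PCA. `max_size` above
the CpG count is clamped with a warning. The conditional p-value of a
count beyond its finite support is exactly 0.
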