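# Methods

This note records the models, conventions and numerical choices behind
`coibarcode`, in the order the pipeline runs.

## Input model and quality control

The unit of analysis is an aligned, equal-length set of COI barcode
sequences (IUPAC DNA, gap symbol `-`) with a four-rank taxonomy
(species ⊂ genus ⊂ family ⊂ order). Rank consistency is enforced at
load time: a genus must map to exactly one family and a family to one
order across all records. The package deliberately implements no
multiple alignment — COI barcodes amplified with the standard fish
primer sets are expected indel-free, and unequal post-QC lengths are a
hard error rather than something to be silently patched.

QC applies, in order: a minimum ungapped length (default 600 sites, the
conventional floor below which vertebrate NUMTs become likely
confounders), reading-frame detection, and stop-codon screening. The
frame is the offset in {0, 1, 2} minimising the total count of
vertebrate-mitochondrial stop codons (TAA, TAG, AGA, AGG — translation
table 2, the appropriate code for a vertebrate mitochondrial gene)
across all sequences, ties broken toward the smallest offset. Records
with any in-frame stop at the chosen offset are flagged NUMT-suspect and
excluded by default; exclusion is reversible (`exclude_numts=False`)
because the flag is a screen, not a verdict.

Gaps and ambiguity codes are retained in the stored sequences and
treated as missing data downstream (pairwise deletion). Ambiguity codes
are never fractionally attributed (no ½R = ½A + ½G bookkeeping): the
simplicity and testability outweigh the tiny information loss at typical
barcode quality. Coordinates are 0-based internally; the codon position
of column c is ((c − offset) mod 3) + 1 and reports are 1-based.

## Composition statistics

Base frequencies are means over sequences of per-sequence percentages
(each sequence weighted equally), not pooled nucleotide counts, so
records with more missing data are not down-weighted; for equal-length,
gap-free data the two conventions coincide. Site classification uses
unambiguous characters only: a column is conserved with ≤ 1 distinct
state, variable with ≥ 2, parsimony-informative when ≥ 2 states each
occur in ≥ 2 sequences, singleton otherwise. Pair frequencies (ii, si,
sv) are means over all unordered sequence pairs of the counts of
identical, transitional (A↔G, C↔T) and transversional site pairs among
sites unambiguous in both sequences; R = si/sv is undefined when sv = 0.
Everything is computed and stored at full precision; ii/si/sv round to
integers and R to two decimals only in the writers.

## K2P divergence

The Kimura two-parameter distance distinguishes transition proportion P
from transversion proportion Q over the comparable sites of a pair:

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]   [substitutions/site]

The distance is *undefined* when 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0
(saturation). Undefined pairs are recorded and excluded from all
summaries, and tree building refuses to run on them — substituting a cap
would bias tier summaries invisibly. A pair with zero comparable sites
is a distinct, hard error. Distances are stored as proportions and
rendered as percentages only at the reporting boundary.

Tier summaries stratify unordered pairs as conspecific; congeneric
heterospecific; confamilial across genera; conordinal across families.
These strata partition all defined pairs that share an order. The
`n_taxa` column counts the distinct taxa at the stratum's grouping level
contributing at least one pair; pair counts are reported alongside,
since taxon counts alone understate the evidence. The SE column is the
sample standard deviation of pair distances divided by √n_pairs — a
definition chosen explicitly because survey tables print "S.E." without
defining it; pair distances within a stratum are correlated through
shared tree paths, so this SE understates sampling variation and is
reported as a descriptive, not inferential, quantity.

The barcoding gap of a species is its minimum heterospecific
(nearest-neighbour) distance minus its maximum conspecific distance;
negative values mean overlap. Singletons get a nearest neighbour but no
gap. A congeners-only neighbour search (the minimum-congeneric
convention) is available as a flag.

## Neighbor joining and bootstrap

Classic Saitou–Nei agglomeration: join the pair minimising
Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with branch lengths
from the standard two-point formulas and the final three lineages
resolved by the three-point closed form, yielding an unrooted tree whose
internal nodes all have degree three. Two conventions are fixed for
determinism rather than inferred from any published tree figure:
Q-criterion ties break toward the smallest (row, column) pair in current
matrix order (real ties occur with duplicated sequences), and a negative
branch length is clamped to zero with the deficit moved to its sister so
the joined pair's path length is preserved. NJ is exact on additive
matrices; the tests verify topology recovery against an exhaustive
least-squares oracle and path-length reproduction to 1e−9.

The bootstrap resamples alignment columns with replacement (the standard
barcoding convention; codon-triplet blocks are available via
`block=3`), recomputes the K2P matrix and NJ tree per replicate, and
assigns each internal branch of the *original* tree the percentage of
replicates containing the same bipartition — no consensus tree is
built. Replicates containing a saturated distance are dropped and
counted; more than 10% dropped aborts the run. All resampling flows
from one integer seed.

Monophyly is tested unrooted: a species is monophyletic iff its
individuals are exactly one side of some branch. Singletons are
trivially monophyletic with no support value.

## Diagnostics

Three flag types mirror the recurring failure modes of barcode
libraries, with thresholds exposed rather than hard-coded:

* deep conspecific divergence, default 2.0% — the empirical ceiling of
  conspecific variation in regional fish surveys; above it, suspect a
  mislabelled voucher or a cryptic species;
* near-zero heterospecific distance, default 0.1% — roughly one
  substitution in a 655-site barcode, tolerating sequencing error, so
  "zero" does not require exact identity; such pairs are labelled
  misidentification-*or*-introgression candidates because COI alone
  cannot separate the two causes;
* unresolved species complex — a genus whose minimum interspecific
  distance falls at or below the deep-divergence threshold, collapsing
  the barcoding gap genus-wide (the recent-speciation signature).

Non-monophyly flags from the tree join these in a per-species report
that always lists every species.

## Synthetic data generator

The generator's role is to produce data with the statistical structure
the analysis assumes, at survey scale, with known truth. Divergence
tiers are imposed by a fixed-depth ultrametric rank tree, star-like
within each rank: conspecific individuals coalesce at height
t_species/2, congeneric species at t_genus/2, and so on, so the expected
number of substitutions per site between two leaves of a tier equals the
configured tier divergence exactly. Defaults follow the tier structure
published for regional fish COI surveys — 0.21%, 6.50%, 23.70%, 25.60%
for species/genus/family/order, with cross-order pairs at 28%
(divergence growth flattens at high ranks as substitutions saturate,
so a value just above the conordinal tier is the realistic choice) —
and a default scale of 4 orders × 2 families × 2 genera × 5 species × 3
individuals = 80 species, 240 sequences, matching the ~85-species ×
3-individuals scale of such surveys at sizes a desk machine analyses in
seconds.

Sequences evolve by a continuous-time K2P process: per branch of length
t each site receives Poisson(t) events, each a transition with
probability κ/(κ+2) (default κ = 4, so si/sv → 2 at low divergence).
The root sequence is drawn from per-codon-position base profiles with a
third-position anti-G bias (G₃ ≈ 9.5%), and any event that would create
an in-frame stop codon is resampled among the remaining target bases, so
the no-stop invariant holds by construction. Tier distances in the
config are model distances (expected substitutions per site); branch
lengths are differences of tier half-depths, computed directly in the
code.

What the generator does *not* emulate — and what passing tests on it
therefore cannot show about real data: coalescent variance and shared
polymorphism, rate heterogeneity across sites (no Γ, no invariant-site
class), selection, and indels. The most visible consequence is site
classification: real COI has most first/second codon positions frozen by
purifying selection (≈ half of all sites conserved in a real survey),
while the uniform-rate simulation at these depths leaves only ≈ 2% of
sites conserved. Composition also drifts slightly toward uniform on the
deepest branches because the K2P process is composition-blind, so the
realised AT content (~52–53%) sits just below the root profile's 53.2%.
Pair-level quantities (tier means, ii/si/sv, monophyly, supports) are
the generator's fidelity targets, and those it controls well.

Planted errors: a mislabel reassigns one record's full taxonomy to a
random other species (modelling a misidentified voucher — the sequence
is real, the label is wrong); a NUMT overwrites one random in-frame
codon with TAA. A truth table records every plant for recovery tests.

## Numerical and reporting choices

* Percentages appear only in report objects and writers; all internal
  math is on proportions.
* Branch lengths serialise with 6 significant digits, supports as
  integers; Newick children order by the lexicographically smallest leaf
  in each subtree, so serialisation is deterministic.
* Leaf names with Newick-special characters are underscored by default,
  quoted on request.
* The run manifest records parameters, seed, filter counts and package
  versions; two runs with the same config and seed produce byte-identical
  numeric outputs (the manifest differs only in its timestamp).

## Reproducing the published survey

The package ships the accession-level taxonomy of the Taiwan Strait fish
COI reference library (354 accessions, 86 species; two accessions are
transcribed verbatim from the source table although their prefixes look
truncated, and one duplicated accession is kept once). Reproducing the
survey's numbers requires fetching those accessions from GenBank and
aligning them (external `mafft`; whole-mitogenome records contribute
their annotated COI CDS), after which the ordinary pipeline applies.
Exact agreement with the published values additionally depends on
editing and filtering choices the survey does not fully specify, so the
reproduction path asserts agreement at tolerances of a few percent
rather than to the printed digit. Offline, that path fails fast with a
clear network error; nothing else in the package touches the network.

## Known limitations

* K2P and NJ only — no other distance models and no likelihood trees;
  p-distance exists internally solely to sanity-bound the K2P correction.
* Saturated pairs make tree construction fail rather than degrade; for
  barcode-depth data this is the right default but it means the tool
  will not produce trees across, say, phylum-scale distances.
* The SE definition and the `n_taxa` accounting are stated conventions;
  other software may print differently defined columns under the same
  names.
* Monophyly support reports the defining branch only; it does not search
  for near-monophyly or compute rogue-taxon diagnostics.
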