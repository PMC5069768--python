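# Methods

`panlink` implements an integrated comparative-genomics / untargeted-
metabolomics mining workflow for groups of closely related bacterial
strains, together with a seeded synthetic-data generator that plants
recoverable ground truth so every stage can be tested end to end without
external data. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic world does and does not
emulate.

## The workflow

Thirteen (by default) strains are profiled on two axes:

* **Genome side.** Predicted proteomes are compared all-vs-all. Gene
  *families* link two genes when pairwise identity exceeds 50% over at
  least half the length of the longer gene (strict `>50%`, coverage `≥0.5`
  of the longer sequence measured on alignment columns); families are the
  connected components (single linkage). Separately, *1:1 orthologs* are
  found as non-greedy bidirectional best hits (BBH): q is p's best-scoring
  hit in strain B and p is q's best in A, with exact score ties yielding no
  pairing. Each protein receives a fixed-width presence/absence **barcode**
  over strains (own bit always set; bit B set iff a BBH exists in B), and
  full 1:1 ortholog groups are BBH cliques with one member per strain.
  Because the clique requirement is stricter than family membership, the
  group count is at or below the core-family count.
* **Metabolome side.** Per-sample feature lists (neutral mass, retention
  time, intensity, ESI mode) are blank-subtracted against medium controls,
  aligned across samples by single linkage within 20 ppm / 0.2 min (both
  configurable), merged across ESI+/ESI− within the same tolerances
  (presence OR-ed, one-to-one greedy matching on ascending mass difference,
  so |merged| = |P| + |N| − |matched|), and reduced to a strains × features
  boolean presence matrix. A strain counts as producing a feature when any
  of its replicate extracts contains it (`any_replicate`, default) or all
  do (`all_replicates`).

Both matrices feed the same pan/core machinery: cumulative union (pan),
cumulative intersection (core), and per-position new-entity counts along a
strain order that defaults to the leaf order of an average-linkage Jaccard
dendrogram of the presence profiles (ties broken lexicographically by
strain id; a random-permutation averaging mode is also available).

The discovery core links the two sides by pattern: the strain distribution
of a chemotype (e.g. the consensus pattern of mass-defect-flagged
halogenated features) is used to select genes with a matching barcode
(Hamming distance ≤ `max_hamming`, default 0), and matching genes are
assembled into candidate clusters as maximal runs on one contig with at
most `max_gap` (default 2) intervening non-matching genes and at least
`min_cluster_genes` (default 3) members, ranked by size. A permutation
test (gene order shuffled within each contig, preserving contig lengths)
gives an empirical p-value `(1 + #perms with max run ≥ observed) / (1 +
n_perms)` for the largest run. Gap tolerance matters for this null: in a
small world where a tenth of a contig's genes match, gap-tolerant runs
chain by chance, so significance is best assessed at `max_gap=0` (the
analysis driver does exactly that); at realistic densities (hundreds of
genes per contig) the default gap tolerance is also significant.

The reverse direction — gene cluster pattern to metabolite family — is a
plain barcode query of the feature presence matrix. A cluster present in
more strains than its product (a disrupted pathway) surfaces as the
`extra_strains` diagnostic on the candidate, never as a silent merge.

## Halogen screening

Monoisotopic masses use standard most-abundant-isotope values (≥6
decimals). The mass-defect screen passes a neutral mass m when
`|defect(m) − (0.0937 − 0.02·m/100)| ≤ 0.0100` Da. The defect convention
is configurable: `nearest_integer` (m − round(m), default) or
`fractional_part` (m − floor(m)). The published window parameters do not
reproduce the nearest-integer defects of heavily brominated formulas
(C10H5Br4NO has defect −0.2895), so the window is honored verbatim and the
convention is exposed; the synthetic generator places its halogenated
masses inside the configured window, and everything else outside a 1.5×
guard band, which is what makes sensitivity/false-positive statements
testable. Isotope envelopes are multinomial convolutions of per-element
isotope distributions on the integer mass-offset grid (truncated at 1e−6
of the base peak, normalized to max = 1), and observed envelopes are
scored against theory by cosine over aligned isotopologue slots.

## Molecular networking

The modified cosine pairs fragment peaks either directly (|Δm/z| ≤ 0.3 Da)
or offset by the precursor mass difference, chooses a one-to-one pairing
greedily by descending product of √-transformed intensities, and
normalizes by the two spectra's transformed intensity norms. An exhaustive
maximum-weight assignment (`scipy` linear sum assignment) is kept as the
test oracle; on small spectra the greedy pairing agrees to 1e−9. Edges
with cosine strictly above 0.7 and at least 6 matched peaks are retained
(the peak floor follows common networking practice; the threshold is the
workflow's stated cutoff), and molecular families are connected components
with ≥2 members.

## GA/SVM feature selection

The 500 most intense merged features (log1p-transformed intensities,
standardized per training fold) are searched for a 50-feature subset that
discriminates all strains. Fitness is leave-one-out accuracy of a linear
soft-margin SVM with cost 100 and balanced class weights. Multiclass
reduction uses libsvm's pairwise voting: on these panels — tiny sample
counts, near-duplicate classes — a one-vs-rest reduction costs ~7× more
per fit for an identical decision, which matters at ~3,700 fits per
selection run.

The GA keeps the published search envelope: population 25, 10 generations,
mutation rate 1 (one random gene replacement per offspring per
generation). The operator details are not published anywhere, so they are
explicit knobs; the defaults were chosen after instrumented runs on
planted panels showed that naive operators lose planted features to
selection drift:

* crossover is uniform with **two complementary children** (shared genes to
  both, the symmetric difference split in half), so crossover itself never
  discards an allele;
* parents are paired **round-robin over the shuffled elite half**, so every
  elite chromosome transmits every generation;
* the elite half survives unchanged (hence best-ever fitness is
  nondecreasing), offspring refill the other half.

The validation panel (`synthetic_strain_panel`) plants five pairs of
otherwise-identical strains, each pair separated only by one informative
feature (+3 log-intensity units), plus three freely separable strains, two
replicates per strain. Replicates are exact technical duplicates by
default: with i.i.d. replicate noise, a wrapper that directly optimizes a
frozen leave-one-out outcome can find noise columns that happen to resolve
a pair, which blurs what recovering the planted features means. With
duplicates, a missing informative feature costs a fixed 2/26 accuracy and
no noise column can repay it, making recovery a clean property of the
search.

## OBU grouping

Two predicted pathways are the same operational biosynthetic unit when at
least 80% of the genes of the *smaller* pathway (tolerant of contig-split
partials) have a best homologue in the other at ≥60% identity; both
thresholds inclusive. OBUs are connected components of that relation, so
chains through intermediates can join pathways that are pairwise
dissimilar — intended, and covered by a three-pathway chain test. OBUs
consisting solely of partial (contig-truncated) pathways whose strain
barcode duplicates another OBU's are folded into it.

## The synthetic world

`WorldConfig()` defaults mirror the study conditions: 13 strains in a
7+6 clade split with one near-clonal pair (99% gene-family copy
probability, reduced singletons), 3,322 core + 4,328 accessory gene
families + 179 singletons per strain (pan ≈ 9,979; ~5,100 genes/strain),
~2,000 features per strain targeting 2% core and 30% strain-unique
features (~7,190 total with ESI mode fractions chosen to mirror
6,736 positive / 2,151 negative / 1,697 shared), one planted 11-gene
halogenated cluster conserved in seven strains with a 6-member product
family, 40 additional halogenated features restricted to the same strains,
50 medium-blank features, duplicate extracts with 5% per-replicate feature
dropout, 2 ppm mass and 0.02 min RT measurement noise.

Protein sequences are mutated copies of per-family random ancestors
(length 150–600, per-site substitution rate 0.12, no indels), giving
within-family identities ~77% (> 50% rule) and cross-family local
identities well below the family rule; BBH additionally ignores hits below
30% identity or 50% coverage of the longer sequence, because when a true
ortholog is absent the best remaining hit is a short twilight-zone
alignment and two such accidents are readily reciprocal. Cluster genes are
planted contiguously on one contig per carrier strain; a cluster can be
marked broken in specific strains (genes present, product features
absent). Feature masses are kept ≥0.05 Da or ≥0.5 min apart so the planted
catalogue is unambiguous at the default alignment tolerances. Fragment
spectra of a family share a scaffold whose designated peaks shift by the
analogue mass difference, so the modified cosine links the family.

Tests and the reproduction harness run `WorldConfig.small()`: the same
13-strain structure and planted content with 30 core + 60 accessory
families, 3 singletons/strain, 40-gene contigs, 120 features/strain and
ancestor lengths 120–300 — sized so one world's all-vs-all alignment takes
seconds. These sizes are this package's choice of test scale; the
full-scale defaults remain available.

What the generator does **not** emulate: real enzyme sequences or
nucleotide-level genomes, indels (optional rate exists but defaults off),
paralogs within a strain, chromatographic peak shapes, adduct/dimer
chemistry in the feature tables, batch effects, or cross-family sequence
similarity gradients. Passing the planted-recovery suite therefore shows
the *logic* of the workflow is sound under its stated assumptions — not
that the thresholds are optimal for any particular real dataset.

## Known limitations

* The builtin alignment engine is exact Smith–Waterman (BLOSUM62, gap open
  −11 / extend −1) behind a shared-5-mer prefilter (≥3 shared words); truly
  twilight-zone homologs below the prefilter are not aligned. The external
  engine accepts 12-column tabular reports from BLAST+ and agrees with the
  builtin on the synthetic worlds.
* The feature aligner's single-linkage grouping can chain features through
  intermediates across more than one tolerance width; the generator's
  separation guard sidesteps this, real data may not.
* The permutation null conditions on which genes match the pattern and on
  contig lengths, not on gene-family sizes.
* Full-scale reproduction from deposited assemblies (prodigal + BLAST+ on
  thirteen ~6 Mb genomes) is implemented (`analysis/09_deposited_genomes.py`)
  but requires the assemblies on disk and hours of CPU; it is not part of
  the test suite's routine run.
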