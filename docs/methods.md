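# Methods

This note documents the models, numerical choices and limitations behind
each stage of the workflow, in the order the pipeline runs them.

## Synthetic communities

The generator emulates a cultivable-isolate collection at the level the
downstream stages care about, not at the level of real evolutionary
processes.

**16S structure.** Each genus is an independent uniform-random template
(default 1,300 nt, the typical length of an assembled partial 16S contig);
random templates differ at ~75% of sites, far above the 5% floor the
generator verifies. Each isolate's 16S is the genus template with i.i.d.
per-site substitutions, uniform over the three alternative bases and never
silent, so identity to the template is analytically 1 − rate. The
`divergence_within_genus` parameter (default 0.004) is defined as the
approximate *pairwise* divergence between genus mates; each isolate is
therefore mutated at half that rate. This is the quantity identity
thresholds act on: with the default, genus mates sit at ~99.6% identity,
comfortably inside a 99% OTU, while different genera can never merge. There
are no indels, chimeras, sequencing-error profiles or rRNA operon copy
variation; consequently the OTU stage's alignment machinery is exercised on
length differences only when real data are supplied, and passing planted
tests says nothing about alignment quality on messy reads.

**Marker loci.** A carried locus is a random-flank construct
`flank + realize(forward) + insert + revcomp(realize(reverse)) + flank`,
where `realize` samples one concrete base per IUPAC code so a perfect
binding site is guaranteed. The insert is sized so the product is exactly
the expected amplicon (480 bp NRPS, 350 bp PKS-II); flanks are 60 bp. The
construct is verified by in-silico PCR and deterministically re-sampled in
the (vanishingly rare) event of a spurious site.

**Carriage, morphology, activity.** Genus counts use largest-remainder
apportionment (ties by config order). Default per-genus carriage rates
reproduce collection-wide prevalences of 67.7% (NRPS) and 45.1% (PKS-II),
with PKS-II absent from Glycomyces, Micromonospora and Nocardia; aerial
mycelium is Bernoulli(0.851). Activity is drawn conditional on gene
content — P(active) = 0.53 / 0.25 / 0.45 for both / exactly-one / no loci,
the category-wise rates implied by the screened collection's counts — and
an active isolate inhibits one uniformly chosen test strain plus each other
strain independently (p = 0.3). The association is a label model only; it
encodes no biology beyond the configured conditional rates.

**Reproducibility.** One global seed; per-isolate streams come from
`SeedSequence(seed, spawn_key=(isolate_index,))`, so appending isolates
never changes earlier ones, and identical configs give byte-identical
communities.

## Pairwise identity and OTUs

Identity uses an end-gap-free global alignment (match +1, mismatch −1, gap
open −2, gap extend −0.5) over the 15-letter IUPAC alphabet, scoring two
codes as a match when their base sets intersect. Columns lying in terminal
gap runs of either sequence are excluded from the denominator (sequences
are trimmed to different lengths in practice); internal gap columns count
as mismatches. Because co-optimal alignments can differ between argument
orders, the pair is canonicalized (lexicographic order) before aligning,
making the reported identity symmetric; the value is then one optimal
alignment's identity, and near score ties it can differ by ~1 column from
another tool's choice — the reason headline OTU counts on real data carry a
±1–2 uncertainty.

OTUs are complete-linkage clusters on d = 1 − identity cut at 1 − t
(+1e−9 for float safety), chosen over single/average linkage because it is
the only linkage for which "every within-OTU pair ≥ t" holds by
construction. Representatives are the longest member (ties: lexicographic
id). Dereplication is the t = 1.0 partition; duplicates = sequences minus
clusters. Reported percentages use one rule everywhere: round half-up to
one decimal.

## Phylogenetics

Distances are p-distance over comparable columns (gaps and ambiguity codes
excluded pairwise) with optional Jukes–Cantor correction
−(3/4)ln(1 − 4p/3); the distance model is recorded in output metadata, and
p-distance is the default because the trees here are for structure, not
dating. NJ follows the Q-criterion with ties broken toward the smallest
active index pair; negative branch-length estimates are clamped to zero
with the deficit logged. The root is the final trifurcation of the unrooted
tree. Bootstrap resamples alignment columns with replacement, rebuilds the
NJ tree per replicate (vectorized distance computation), and scores each
internal bipartition as a percentage; supports are invariant to leaf order
because the column resampling stream does not depend on row order.
Maximum-likelihood inference and multiple sequence alignment are out of
scope: trees are built from pre-aligned input, and synthetic alignments are
generated gapless.

Biosynthetic fragments are translated in all six frames with the standard
code; the frame with the longest stop-free run wins (ties: +1, +2, +3, −1,
−2, −3), with a warning below 10 stop-free residues. Protein trees use
uncorrected protein p-distance.

## Degenerate-primer screening

Binding requires base-set intersection at every position up to a mismatch
budget; the default budget is 0 because the degeneracy already encodes the
tolerated variation (real degenerate PCR also tolerates 5′-side mismatches,
so the budget is configurable and the positive set grows monotonically with
it). Both template orientations are searched; product coordinates are
reported 0-based half-open on the plus strand, and lengths include both
primer footprints, matching how product sizes are conventionally stated.
The size window is ±20% of the expected product: the screening protocol
scores "a strong unambiguous amplicon of the right size", and the window is
this package's operationalization of "right size" — configurable and
logged, with no attempt to model band intensity or melting temperature.

## Fingerprinting and grouping

Digestion cuts at every occurrence of the recognition site (AluI AG^CT,
HaeIII GG^CC — catalogue data carried in config, not code); overlapping
sites each cut, and fragment lengths always sum to the template length. The
gel model drops fragments below 50 bp, merges bands within
max(5 bp, 2% of size) (single-linkage, mass-weighted mean size), and
assigns areas proportional to total fragment mass — the behaviour of
ethidium-bromide staining, and the choice that makes the area rule
deterministic from fragment lengths alone. Scoring keeps bands whose area
fraction strictly exceeds 0.05 of the pre-filter lane total (the protocol's
wording is "higher than 5%", hence the strict inequality), and is
idempotent. Band matrices pool scored sizes across lanes and bin them with
the same tolerance rule, so a band shared by two lanes lands in one column;
dual-enzyme matrices are column-wise concatenations with enzyme-tagged
labels (computing similarity on the concatenation rather than averaging
per-enzyme similarities is a choice; averaging is available via the
library by combining per-enzyme reports).

Jaccard ignores joint absences and is undefined for two empty lanes (the
pipeline excludes empty lanes before clustering). UPGMA works on
d = 1 − J with unweighted arithmetic-mean linkage, deterministic
lexicographic tie-breaks, and merge heights guaranteed monotone; tree
branch lengths use the ultrametric convention (height = distance/2) while
cuts are specified on the cophenetic distance scale, so "similarity 0.93"
unambiguously means "joined at distance ≤ 0.07". The gel resolution and
binning tolerance are free parameters of this model — real gel-derived
distinct-fragment and group counts depend on the physical gels and are not
reproducible from sequence data, which is why the pipeline reports them
per run without asserting any particular values.

## Activity correlation

Activity tables are binary isolate × strain inhibition calls (agar-plug
semantics; no zone quantitation). Gram classification of the test panel
lives in config. The cross-tabulation partitions *active* isolates into
both / exactly-one / neither gene categories — "either" always means
exactly one locus — and separately counts silent carriers. The network is a
tripartite graph with one edge per positive table cell; exports (edge-list
TSV, GraphML) are sorted for determinism.

## Problem sizes and determinism

The default study conditions are 66 isolates in 7 genera, 1,300-nt 16S
markers, and 1,000 bootstrap replicates; `scripts/acceptance.py` runs these
in a few minutes on one CPU. The test suite exercises the same code paths
at reduced sizes (hundreds of base pairs, tens of isolates, tens of
replicates) chosen so the whole suite stays fast while every oracle
comparison (naive digestion scan, primer-expansion search, scipy UPGMA,
scikit-bio NJ, closed-form Jukes–Cantor) runs at the scale its check is
specified for. All randomness flows from explicit seeds; reruns are
byte-identical, including pipeline run directories (no timestamps are
written).

## Known limitations

- Identity-based OTU counts can differ by ±1–2 from other tools near score
  ties and threshold-straddling pairs; the linkage of the original online
  clustering tools is undocumented, so cross-tool agreement is approximate.
- The gel model is an idealization: no diffusion, no partial digestion, no
  lane-to-lane mobility variation; planted fingerprint tests validate the
  bookkeeping, not densitometry of real images.
- The activity model is a conditional-probability label generator, not a
  metabolite model; network analyses on synthetic data demonstrate the
  plumbing only.
- Taxonomy assignment (database searches) and ML tree inference are
  deliberately out of scope.
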