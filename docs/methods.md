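# Methods

This note documents the models, parameter choices and numerical details
behind `binsift`, and what the synthetic benchmark does and does not show.

## Splits and sequence statistics

Scaffolds below a minimum length (default 1,000 bp, inclusive) are dropped
before any profiling.  Scaffolds strictly longer than the split threshold
(default 40,000 bp) are cut into `n = ⌊L / 20,000⌋` sections whose lengths
differ by at most one base; shorter scaffolds pass through as a single
split.  The even-partition rule is our choice for the unstated remainder
policy: it guarantees no section shorter than the 20 kbp target, so every
split carries a statistically comparable amount of sequence.  Coordinates
are 0-based half-open; split names append a 1-based zero-padded ordinal
(`scaffold_7_split_00002`).

GC-content is computed over unambiguous bases only.  Tetranucleotide
frequencies slide a k=4 window, skip any window containing a non-ACGT
character (the simplest unbiased treatment of ambiguity codes), and
collapse each 4-mer with its reverse complement to the lexicographically
smaller of the pair, giving 136 canonical features (120 complement pairs +
16 palindromes).  Collapsing is our choice because assembly strand is
arbitrary; `tnf_vector(..., collapse=False)` restores the raw 256
features.  Frequencies sum to one whenever at least one valid window
exists, else the vector is all zeros.

## Coverage profiling

Mean coverage is per-base depth averaged over the split (pysam pileup
counts; deleted reference positions in a read contribute nothing,
insertions are ignored), and detection is the fraction of positions with
depth ≥ 1.  All primary alignments are counted regardless of mapping
quality; secondary and supplementary records are excluded.  RNA-seq is
profiled identically; only its detection is used downstream.  Detection
and mean coverage computed on splits are aggregated to scaffolds by
length-weighted means wherever a scaffold-level number is reported.

## Clustering model

Features have two blocks.  Composition enters as-is (frequencies on a
common scale).  Coverage per DNA library is transformed `log10(x + 1)` —
coverage is roughly log-normally distributed and the +1 keeps zero
coverage at zero — then min–max scaled per column to [0, 1] (a constant
column becomes all zeros), and the whole block is multiplied by
`sqrt(136 / n_libraries)` so that the squared-distance contribution of the
coverage block is commensurate with the 136 composition columns rather
than drowned out by them.  Clustering is Ward linkage on Euclidean
distance (deterministic for fixed input; scipy's linkage resolves distance
ties by lowest merge index).  These choices — linkage, metric, transform
and block weight — are not prescribed anywhere and are exposed as
arguments; equivalence with any other tool's trees is not claimed.  Flat
bins come from cutting the tree at the `k − 1` highest merges, with
cluster ids renumbered by first appearance along the row order so labels
are stable.

## Single-copy-gene census

The bundled collection lists 139 Pfam-style identifiers for protein
families found once in nearly all bacterial genomes (ribosomal proteins,
aminoacyl-tRNA synthetases, RNA-polymerase subunits, core
replication/translation machinery).  Only gene *names* are shipped; users
run `hmmsearch` with their own profile HMMs and point the parser at the
`--tblout` file (or a plain `gene ⇥ split ⇥ evalue` TSV).  Hits with
e-value above the cutoff are discarded; the cutoff is not prescribed
upstream, so we default to 1e-10 and record it in the CLI report header.
Every retained hit row counts — tandem duplications are genuine extra
copies.  The genome-count estimate is the mode of the per-gene hit-count
array; when several counts tie for the maximal frequency we return the
smallest and set `multimodal`, which never overstates contamination.
Completeness and redundancy of a bin are the percentage of the collection
hit at least once, respectively at least twice, within the bin's splits.
The occurrence report plots `sqrt(hits)` per gene so that a few
high-copy genes do not dominate the panel.

## Bin curation

Split-level selections are lifted to scaffolds by split-length majority;
ties leave the scaffold unassigned with a warning.  RNA recruitment of a
bin is its share of the assembly-wide `detection × length` mass over RNA
samples (0/0 defined as 0) — a proxy for "fraction of RNA reads
recruited" that needs no read counts and sums to one over bins plus the
unassigned remainder.  Library-restriction flags compare the maximum
scaffold detection across user-declared *core* libraries (the ones any
true host scaffold must appear in, e.g. standard short-read libraries)
against *auxiliary* libraries (e.g. synthetic long-read preparations): a
scaffold is `aux_only` when core detection stays below `detection_min`
(default 0.5 — at least half the scaffold covered counts as "present")
while some auxiliary library reaches it.  FASTA export always writes whole
original scaffolds, never split fragments, and conserves total assembly
length across bins plus unassigned.

## Synthetic data model

The generator's defaults define the reference scenario used by the test
suite and the acceptance script: a 2 Mbp host plus three complete 0.5 Mbp
bacterial contaminants; three core and six auxiliary libraries; host depth
30× in every library; each contaminant at 30× only in its own pair of
auxiliary libraries (auxiliary libraries dealt round-robin), emulating
distinct library-specific contamination sources; lognormal per-split depth
noise with CV 0.2; one SCG hit per gene per contaminant plus
Poisson(0.05) spurious host hits per gene; RNA detection ≈ 0.9 on host
splits and 0 on contaminants.

Sequences are order-2 Markov chains whose 16×4 transition matrices are
drawn from a symmetric Dirichlet with concentration 1.0; smaller
concentrations give more divergent compositions (a seeded sweep in the
tests confirms monotonicity).  Scaffold lengths are lognormal (median
≈ 20 kbp, σ = 0.7, clamped to [2 kbp, genome/5]) so a realistic share of
scaffolds exceeds the 40 kbp split threshold and none falls below the
1 kbp profiling filter.  Coverage is simulated at the profile level rather
than as reads: per-split mean depth is lognormal around the intended
depth, and detection follows the Poisson-coverage approximation
`1 − exp(−depth)` (depth 1 → ≈ 0.63).  The BAM code path is exercised
separately with programmatically built read sets checked against a
per-base depth oracle.

What this emulates — and what it does not: the simulator reproduces the
*statistical* structure the workflow exploits (compositional coherence
within genomes, library-restricted differential coverage, once-per-genome
marker genes, host-only transcription).  It does not model read-level
error, mappability artifacts, repeats shared between host and
contaminant, chimeric scaffolds, GC-dependent coverage bias, or partial
bacterial genomes.  Passing the end-to-end benchmark therefore
demonstrates that the implementation is correct and the statistics behave
as designed under their assumptions, not that curation of a real assembly
is automatic: real data have weaker separations and still warrant the
second-pass composition-only re-clustering and human review of the bin
reports.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the reference scenario
(3.5 Mbp, ~200 splits, 10 samples), 100 census replicates per planted
genome count in {0, 1, 3, 10}, and 20 replicate assemblies for the
flagging benchmark — sizes chosen so the whole suite completes in well
under a minute per component on one CPU while keeping every estimate
comfortably away from its decision boundary.  All randomness flows from a
single integer seed through `numpy.random.SeedSequence` spawns;
regenerating with the same seed reproduces every output file byte for
byte.

## Known limitations

* Only the Euclidean metric is implemented for clustering; Ward is the
  default and the only linkage tested at scale.
* The mode estimator is integer-valued and conservative under ties; it
  cannot see partial genomes (a half-present bacterium shifts counts
  toward 0 for half the genes).
* `profile_alignment` trusts the aligner: no deduplication or
  mapping-quality filter beyond excluding secondary/supplementary records
  (a flag exists to change this policy upstream of profiling, not within
  it).
* The archaeal/eukaryotic marker collections are pluggable
  (`load_collection(path)`) but not bundled.
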