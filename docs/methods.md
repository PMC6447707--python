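# Methods

`cellguild` re-implements, as a tested pipeline over fully synthetic data, a
culture-independent analysis that classifies the dominant genera of a
cellulose-rich alkaline niche into cellulolytic **helpers** (producers of
extracellular endoglucanases, hence of the cellodextrin "public good") and
**beneficiaries** (taxa that lack endoglucanase but carry the intracellular
assimilation enzymes and cross-feed on the released cellodextrins). This note
documents the models, the defaults and why, what the simulator does and does
not emulate, and the numerical choices.

## Synthetic community model (`synth`)

The simulator generates the study conditions every downstream stage is
validated against: a two-sample community of six genera spanning three phyla
(two Bacteroidetes, three Firmicutes, one Proteobacteria), with log-normal
per-sample abundances.

**Genomes.** Each genome is an order-1 Markov chain background on a GC ladder
(0.33–0.63 in 0.06 steps, satisfying pairwise GC gaps ≥ 0.05) with a small
log-normal jitter on the transition matrix so each genome has a k-mer signature
beyond its GC. Planted into the background are: one 16S locus (one copy per
genome, avoiding copy-number confounding of abundances), the role-defining
gene cassette, and ten universal single-copy marker genes used later for bin
taxonomy votes. Genome length defaults to 30 kb — a deliberate desk-scale
miniature; the analysis depends on coverage and signature statistics, not
absolute genome size. Coordinates are 0-based half-open; minus-strand
features are stored on forward coordinates with a strand flag.

**Gene cassettes.** The cassettes mirror the reported gene content of the six
dominant genera: Clostridium (endoglucanase, β-glucosidase,
6-phospho-β-glucosidase, PTS transporters) and Paludibacter (endoglucanase,
β-glucosidase, cellobiose phosphorylase, *no* characterized transporter) are
helpers; Cloacibacterium (downstream glucosidases only), and Exiguobacterium,
Acetivibrio and Tolumonas (downstream glucosidases plus PTS) are
beneficiaries. Cassette proteins are planted at 80% amino-acid identity to
the packaged per-genus references, inside the 61–86% mean-identity regime the
best-hit taxonomy is expected to operate in. Proteins are reverse-translated
with synonymous codons weighted toward the host GC, so coding regions carry a
muted version of the genome signature, as in real genomes. Substitutions
only — no indels — which keeps reference profiles ungapped.

**Packaged references.** All reference material (GH/CBM family seed proteins,
marker proteins for the enzymes and the PTS Cel / ABC Ceb-MsiK transporter
systems, single-copy markers, 16S templates) is generated deterministically
from one fixed internal seed, so the simulator and the annotator always share
one reference set and the package needs no downloads. These are synthetic
curated toys: they reproduce the *structure* of the real databases (family
profiles with thresholds, per-genus sequence variants at ~80% identity to a
family base), not their content.

**16S and amplicons.** Genus templates are 1.2 kb derivatives of a common
backbone mutated at 10% per genus outside the primer sites (inter-genus
identity ≈ 82%, intra-genus reference sets at 99%). The v3–v4 primer pair is
matched under IUPAC degeneracy, the reverse primer against the reverse
complement of the template. Paired 250 bp reads cover the 360 bp inter-primer
insert from both ends (overlap ≈ 140 bp ≥ the 50 bp minimum), with Phred
qualities drawn from a mildly decaying profile (≈ Q38 → Q33) and substitution
errors at 0.5% by default. Primers and barcodes are considered already
trimmed. Not emulated: indels, chimeras, multi-copy 16S operons, fungal
genomes, plasmids — so passing tests demonstrate correctness of the pipeline
logic under clean community assumptions, not robustness to those artifacts.

**Abundances.** Per-sample log-normal (σ = 1.0 by default) normalized to sum
to one. The log-normal choice is ours: no abundance model is prescribed for
the real community. σ ≤ 0 is rejected; the σ → 0 limit (equal abundances) is
exercised with a tiny positive σ.

## 16S pipeline (`amplicon`)

Pairs are merged at the best ungapped overlap ≥ 50 bp maximizing
matches − mismatches, requiring ≥ 75% agreement inside the overlap;
disagreements resolve to the higher-quality call and merged quality is the
pairwise maximum at agreements. Filtering keeps sequences with length ≥ 300,
expected error Σ10^(−Q/10) ≤ 0.5, and mean Q > 30. "Q > 30" is interpreted as
the mean over the merged sequence: per-base Q > 30 at every position would
reject nearly all merged reads under realistic quality profiles.

Classification is a word-based naive Bayes model in the RDP tradition: 8-mer
words, P(word|genus) = (m + prior)/(M + 1) with m the number of reference
sequences of the genus containing the word, M the genus size, and
prior = (n_w + 0.5)/(N + 1) the pseudocounted overall word frequency (the
pseudocount keeps unseen words at positive probability). Each of 100
bootstrap replicates draws ⌊W/8⌋ of the W distinct query words with
replacement and votes for the maximum-likelihood genus, ties broken
lexicographically for determinism. The per-sequence bootstrap fraction *is*
the confidence value used against the 0.5 threshold — there is no second
per-sequence distribution to take a median over; an OTU-grouped median mode
was considered and left out as out of scope. Rank confidences are sums of
genus confidences over the taxonomy, which makes ancestor ≥ descendant hold
by construction; a read is accepted at the most specific rank reaching 0.5,
displayed as `FamilyName_genus-like` when escalated, `unclassified` on total
failure.

Abundance tables are per-sample relative frequencies of display taxa; taxa
present in only one sample are dropped *after* normalization and the
remaining columns are deliberately not rescaled, matching the use of
relative abundances downstream. PCA is covariance PCA of the
samples × taxa table (common scale across columns), components sign-fixed so
the largest-magnitude loading is positive.

## Annotation (`annotate`)

ORF calling is a deliberately simple six-frame maximal ATG-to-stop caller
(minimum 100 aa, longest-ORF wins among same-strand overlaps) — a stand-in
for a trained metagenomic gene finder, adequate because the simulator plants
complete genes.

Genus assignment is Smith–Waterman local alignment (BLOSUM62, gap open −11 /
extend −1, via `Bio.Align.PairwiseAligner`) against the packaged per-genus
references, best hit by score with ties broken by identity then reference id.
Significance uses a normalized score (score / query length) against a
shuffle-null calibrated threshold packaged with the references (null
mean + 10 SD) — a self-contained replacement for database-relative e-value
cutoffs, which are meaningless against a toy database. Two pure-speed
shortcuts that cannot change results: identical ORF translations (contigs
oversample the same loci) are annotated once and shared, and references
sharing fewer than three exact 4-mers with the query are skipped before
alignment (genuine hits at these identity levels share dozens).

Domain detection uses per-family position-specific scoring matrices built
from ten seed variants (85% identity to the family base), log-odds over a
uniform background, with per-family thresholds calibrated against a
composition-preserving shuffle null (mean + 5 SD of best-window scores over
50 shuffles). Per family the best non-overlapping windows are reported;
different families may overlap. The endoglucanase EC label additionally
requires a GH domain from the 13-family cellulase set; cellobiose
phosphorylase carries its own label (EC 2.4.1.20 is the usual number but is
not asserted). Multiple same-family hits are each reported; families count
once per gene in tallies.

## Binning (`binning`)

Contigs ≥ 1000 bp are represented by canonical (strand-pooled) 5-mer
frequency vectors (512 dimensions, k-mer and reverse complement pooled into
the lexicographically smaller form, so signatures are assembly-orientation
independent), reduced to 50 linear dimensions, then embedded in 2D with
Barnes–Hut t-SNE at perplexity 30, angle (theta) 0.5, seed 0 — the standard
composition-binning parameterization. Contigs from both samples are pooled
before embedding. Rows are processed in sorted-contig-id order so the
embedding is exactly invariant to input order at a fixed seed; perplexity is
auto-reduced with a warning below 3 × perplexity points.

Cluster extraction is DBSCAN. The density radius defaults to **5% of the
embedding bounding-box diagonal** rather than a k-NN distance quantile:
sheared contigs oversample identical loci, the embedding collapses those
near-duplicates into tight clumps, and a 5-NN-derived radius then measures
duplicate spacing (fragmenting each genome into dozens of micro-bins) instead
of cluster separation. The 5-NN 95th-percentile radius remains available as
`binning.knn_eps`. Marker genes vote genus onto bins; bins with both
endoglucanase and downstream-enzyme contigs are helper candidates,
downstream-only bins beneficiary candidates. Validation against simulator
truth reports per-bin purity (largest genus fraction) and per-genome
completeness (fraction of a genome's embedded contigs captured by its best
bin). Coverage-based binning and completeness refinement against single-copy
gene sets are out of scope.

## Role classification (`roles`)

From the taxon × feature presence matrix (feature present iff ≥ 1 gene in
the group carries the label): **helper** iff endoglucanase is present
(an endoglucanase-only row is still a helper, flagged `no-assimilation` —
the reference analysis never observed that gene content, so the rule is our
stated choice); **beneficiary** iff endoglucanase absent and ≥ 1 of
{β-glucosidase, 6-phospho-β-glucosidase, cellobiose phosphorylase} present;
otherwise non-participant. Transporter absence never demotes a role — only
two bacterial cellodextrin transporter families are characterized, so a
helper/beneficiary without either is flagged `unclassified_possible`
(plausibly an uncharacterized transporter), the Paludibacter/Cloacibacterium
situation. Classification is row-local: deleting taxa cannot change other
taxa's calls. Bin-level and taxon-level classification share the same code
path via the grouping column.

The interaction network places one cellodextrin pool node: helpers produce
into it, helpers and beneficiaries with downstream enzymes consume from it,
and — when any helper exists — one inhibition edge runs from the pool to an
`endoglucanase_expression` process node (product inhibition of the
cellulolytic step). The process node is a pseudo-node added so inhibition is
represented once rather than per helper. Quantitative flux or game-theoretic
modeling of the cross-feeding is explicitly out of scope.

## Protein properties (`protprops`)

Pepstats-style statistics with the EMBOSS default pKa table (N-term 8.6,
C-term 3.6; C 8.5, D 3.9, E 4.1, Y 10.1, H 6.5, K 10.8, R 12.5), overridable.
Net charge is the Henderson–Hasselbalch sum over ionizable residues plus
termini; pI is found by bisection on (0, 14) to |charge| < 1e-4, which
matches a 1 mpH grid search within 0.01 pH units (the charge curve is nearly
flat near the pI, so the charge tolerance dominates the pH precision). The
default reporting pH is 7.0 unless a stage states otherwise (the survey of
marker proteins uses pH 9.0, the alkaline regime of interest). Residue-usage
comparison flags a residue "decreased" when the query count is below every
reference and "doubled" at ≥ 2× the reference mean — the Lys-depletion and
Glu-enrichment signatures of alkaline-adapted cellulases.
Structure-based pKa shifts and homology modeling are out of scope.

## Orchestration and reproducibility (`pipeline`, `cli`)

One master seed fans out to per-stage sub-seeds via a CRC32 stage-name hash
(< 2^31), so disabling a stage does not shift the randomness of the others.
Every run writes a manifest (version, seed, all parameters) sufficient to
reproduce it; rerunning with the same seed reproduces every table
byte-for-byte. Stage defaults follow the published analysis values wherever
one exists: merge overlap 50 bp, length 300 bp, expected error 0.5,
confidence threshold 0.5, 100 bootstraps, binning minimum 1000 bp, k = 5,
50 intermediate dimensions, perplexity 30.0, theta 0.5, seed 0.

## Problem sizes

The shipped configurations are desk-scale by design: 30 kb genomes, 150
contigs per genome per sample, 2 samples, 200 read pairs per sample, and the
ten-seed benchmark in the test suite. These sizes keep every statistic in
its intended operating regime (≈ 80% best-hit identities, ≥ 1 kb binning
fragments at high coverage) while letting the full suite run in minutes.

## Known limitations

- The ORF caller requires complete ATG-to-stop genes; genes truncated by
  contig ends are invisible (compensated by coverage in the benchmark).
- Reference toys are ungapped relatives; the domain profiles would need
  proper HMMs (insert/delete states) for real indel-rich homology.
- The binning radius default assumes a single global embedding scale; highly
  uneven communities may need an explicit `eps`.
- Role calls are presence/absence per group; a single mis-assigned gene can
  flip a feature, which is why the benchmark reports recovery across seeds
  rather than asserting per-seed perfection.
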