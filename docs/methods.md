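# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Genome I/O and proteomes

Coordinates are 0-based half-open internally; GFF3 is read and written
1-based inclusive. Proteomes are translated with bacterial/archaeal code
(table 11), minus-strand CDS reverse-complemented first, trailing stop
removed. Start codons are translated as encoded (no forced methionine; a
`force_met_start` flag exists) — reproducibility is preferred over
biological nicety. A CDS with an internal stop is flagged *disrupted* and
excluded from protein-level analyses by `usable_proteins`; a CDS whose
length is not a multiple of 3 is flagged *partial* and translated on its
longest in-frame prefix. GC% excludes N from numerator and denominator so
draft assemblies remain comparable; pseudogene features are never
translated.

## Synthetic genomes: what is emulated

`simulate_dataset` evolves an annotated ancestor along a two-cluster
topology whose branch lengths are fractions of the configured per-branch
substitution probability `substitution_rate` (default 0.20): leaves 0.9–0.95
of the rate, internal branches 0.05. Substitutions are per-site Bernoulli
draws with the new base uniform over the three alternatives, so one
branch's realized mismatch fraction equals its rate; between two diverged
genomes multiple hits accumulate and the truth table's expected pairwise
identity applies the exact two-channel composition
q = p₁ + p₂ − (4/3)p₁p₂ — the same saturation Jukes–Cantor corrects for.
Indels (geometric lengths, max 10) fall only in intergenic DNA, so
annotations stay exact. Defaults (five genomes, 120 kb, ≥150 genes, GC
target 0.58) put cross-cluster nucleotide identities at ~70–72%, the level
reported for real *Desulfuromonas* genome pairs; `gene_count` is a floor —
enough neutral filler genes are always generated to keep planted features
separated by at least three intervening genes, which the cluster-detection
rule requires to resolve distinct clusters.

Planted constructs are built to make the classifiers' assumptions literal:

* **Cytochromes** — a C/H-free random background with exactly k
  non-overlapping CXXCH motifs, so the canonical scan returns k by
  construction.
* **Chemoreceptors (MCPs)** — 25-residue hydrophilic N-terminus, two
  20-residue transmembrane (TM) segments of fixed composition
  (`AASAVAASAV…`, mean Kyte–Doolittle 1.76) around a 10-residue loop, and a
  hydrophilic cytoplasmic tail of exactly 7·H residues. The TM composition
  is tuned so the window-19 hydropathy detector ends the last helix exactly
  at the helix/tail boundary; each heptad class uses its own tail-unit
  permutation (same composition) so classes are distinct sequence families
  rather than nested prefixes.
* **Chemotaxis operons** — fixed gene orders per architecture type, with
  annotation products that the keyword catalog recognises; the *E. coli*-
  like type carries two receptors and one interleaved non-che gene, the
  *Dif*-like type a 44H receptor.
* **Transposases** — copies of per-family prototype proteins; the same
  prototypes form the labelled reference library written with the dataset,
  and all copies of a family share one truth family id.
* **Flagellar cluster** — a contiguous block of ≥25 genes with flagellar
  gene products.

Planted (non-neutral) genes are protected from substitutions and indels by
default so their role parameters survive arbitrary divergence; this is what
makes the 100%-recovery guarantees testable. `mutate_planted=True` removes
the protection for robustness stress-tests. Two consequences are documented
rather than hidden: expected pairwise identities count protected spans as
identical (the truth table corrects for this), and AAI computed on default
synthetic data is upward-biased because frozen planted genes dominate the
surviving RBH pairs. AAI's divergence behaviour is therefore validated on
neutral-only plans, where it is strictly decreasing over
p ∈ {0.02, 0.05, 0.10, 0.20}. Not emulated: codon-usage structure,
recombination, rearrangement, gene gain beyond the planted plan — so
passing tests demonstrate correctness of the measurement machinery, not
performance on real annotation noise.

## Orthology, AAI

All-vs-all search pairs a shared-5-mer prefilter with gapped local
alignment (BLOSUM62, gap open 11 / extend 1); identity is
matches/aligned-columns, coverage per-sequence aligned fraction, and a pair
is kept only when identity ≥30% and coverage ≥0.5 hold in both directions
(hit content is symmetric by construction). Best hits maximise score with
ties broken by identity then lexicographic subject id, making RBH pairs
invariant under input order. OGs are connected components over RBH edges
plus within-genome edges at least as strong as either endpoint's best
inter-genome score (in-paralog rule); components of size 1 are singletons.
This deterministic construction replaces normalized-score + MCL machinery,
so absolute OG counts on real genome sets are approximate while
presence/absence structure, sharing tables and single-copy selection are
stable. AAI is the unweighted mean identity over RBH pairs passing the
common two-way convention (30% identity, 70% coverage), reported to one
decimal with the pair count.

## ANI

ANIb-style fragment recruitment: 1020-bp non-overlapping fragments (the
terminal short fragment discarded), each placed at its best location on
either strand of the subject by edlib's banded bit-vector infix alignment;
identity is matched/aligned columns from the extended CIGAR. The infix
aligner consumes the whole fragment, so the coverage filter binds through
the identity filter; retained fragments need ≥30% identity. The reported
ANI is the mean of the two direction means (directionality of published
single-value tables is unstated; both directions are always reported). On
50-kb pairs with indels off, ANI matches the exact per-column identity
within 0.5–0.6 points at p up to 0.20; the residual bias is positive
(best-placement alignments slightly beat the true diagonal) and stays
within the ±1-point tolerance used in tests.

## Phylogenomics

Single-copy OGs (exactly one member in every genome at
`required_fraction=1.0`; lower admits missing taxa) are aligned per gene by
progressive alignment — guide order from 3-mer distances, profile-profile
merges scored by mean BLOSUM62 column score with a linear gap-column
penalty (−6), ties resolved diagonal-first — and concatenated; a hook
accepts externally aligned FASTA per gene instead. No column trimming is
applied by default. Distances use pairwise deletion of gap columns and the
Poisson correction −ln(1−p); saturated pairs (p ≥ 1) are errors rather than
silently clamped. Neighbor joining follows Saitou–Nei with deterministic
tie-breaking by taxon label; negative branch estimates are clamped to zero
with the deficit moved to the sibling. Bootstrap resamples columns with
replacement (seeded); support is the fraction of replicate trees containing
each internal bipartition of the full-data tree. NJ on additive matrices
provably returns the generating topology, which the tests verify against
random additive trees and an independent implementation. Distance-NJ here
deliberately stands in for maximum-likelihood inference: at the clade level
the topology is robust for the divergences this pipeline targets, and a
user-supplied Newick can replace the stage entirely.

## Cytochrome profiling

Canonical mode matches C-X-X-C-H and C-X-X-X-C-H; literal mode (strictly
more permissive) matches C-X-X-H and C-X-X-X-H for compatibility with
looser pattern notations. Scanning is non-overlapping, shortest-match
first, resuming after the matched histidine, so tandem motifs are not
inflated; an `overlapping` switch restores position counting and every
report records the mode. "Multiheme" means more than 3 motifs (threshold 4,
configurable — some literature uses ≥3). The OGC matrix holds per-genome
counts of multiheme members for every OG containing at least one, with
singleton multiheme proteins appended as their own rows.

## Chemotaxis mapping

Identification is keyword-driven (with a user locus→kind table overriding,
and provenance recorded per assignment) rather than HMM-based; exact counts
on real genomes are therefore approximate while planted-truth recovery is
exact. Operons are maximal same-strand runs with intergenic gaps ≤200 bp
(the published predictor's rule is unavailable; configurable). Chemotaxis
clusters allow at most 2 intervening non-che genes and require at least 3
che genes — the "major cluster" criterion in the source analyses is
undefined, so this default is flagged in reports. MCP classes: TM helices
from Kyte–Doolittle hydropathy (window 19, mean ≥1.6, merged); cytoplasmic
domain C-terminal of the last helix; H = round(length/7); class = nearest
of {24, 28, 34, 36, 38, 40, 44, 64} within ±2 heptads, distance ties broken
toward the larger class; proteins without a detected helix are unclassified
with H computed on the full length. Classes 28H/38H stay in the valid set
although rarely observed. Cluster typing is a pure function of member kinds
and MCP classes, first match wins: cheAY fusion → Frz-like; 44H receptor
plus cheA/C/D/W/Y → Dif-like; cheA/B/R/W without receptor → β group,
refined to the cheC/D/X variant; ≥2 receptors plus an interleaved non-che
gene → *E. coli*-like type 2. The flagellar census calls a cluster complete
when its largest locus holds ≥25 flagellar genes, the scale of a full
biosynthesis cluster.

## Mobilome

A CDS is a transposase when its product mentions one (census fractions are
percent of CDS, one decimal); counts on draft assemblies are flagged as
likely underestimates. Family assignment is best-hit against any labelled
protein library (`family=` FASTA tags) with thresholds 25% identity / 60%
coverage and deterministic tie-breaking; the packaged synthetic library is
generated with each dataset, and a curated IS-database export can be
substituted for real genomes.

## Signature clustering and orchestration

Bray–Curtis dissimilarity on count vectors; agglomerative clustering with
average linkage by default (the source analyses name only the distance;
complete and single linkage are available), labels pre-sorted so scipy's
index-order tie-break is a label-order tie-break, and both axes can be
clustered. `run_pipeline` executes genome I/O → orthology → ANI/AAI →
phylogenomics → cytochrome/chemotaxis/mobilome → clustering, writing every
section as TSV/Newick/JSON plus an index; expensive stages (similarity
hits, ANI) are cached under a content hash of the configuration so
interrupted runs resume. Outputs are a pure function of inputs, config and
seed.

## Problem sizes and defaults

Test and acceptance runs use 40–150 genes on 50–220 kb replicons with 5
genomes, 25–100 bootstrap replicates, 1020-bp ANI fragments — sizes chosen
so every recovery statement is exercised end-to-end in minutes on one core
while keeping ≥200 genes behind each percentage-style recovery estimate.
The same code paths run unchanged on full bacterial genomes (3–4.4 Mb);
absolute OG/OGC counts there depend on the orthology construction as noted
above, and a 1000-replicate bootstrap is a flag away.

## Known limitations

Unconstrained nucleotide evolution cannot reproduce the empirical
ANI-vs-AAI relationship of real genomes (purifying selection keeps real AAI
near 63–66% at 70% ANI; neutral simulation drives protein identity far
lower, protected genes keep it at 100%). Orthology is graph-based, not
tree-aware; paralog resolution beyond the in-paralog rule is out of scope.
The ANI aligner's infix placement slightly overestimates identity at high
divergence. Keyword-based gene identification inherits the annotation's
vocabulary; the user-table override is the escape hatch.
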