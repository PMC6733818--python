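# Methods

## Alignment kernels and identity definitions

One scoring scheme is used throughout the toolkit: match +1, mismatch −1,
gap open −2, gap extension −1 (Biopython `PairwiseAligner` is the engine
everywhere). Two kernels are derived from it:

* **global with free terminal gaps** — monomer-vs-monomer comparisons
  (clustering, identity matrices, consensus construction). Identity is
  the number of matched columns divided by the **length of the shorter
  sequence**, maximised over the two strands of the second sequence.
* **local (Smith–Waterman)** — repeat masking, read anchoring and
  inter-cluster similarity. Identity/similarity is matched columns over
  the columns of the local alignment itself.

The shorter-length denominator for the global kernel is deliberate and
load-bearing. Shotgun fragments sample a tandem array at arbitrary
phases of the monomer; two fragments whose phases barely overlap share
almost no homologous sequence, yet under free terminal gaps their
score-optimal alignment is a short, near-perfect terminal overlap. A
per-column denominator would call that pair ~100% identical and collapse
all clusters into one; dividing by the shorter sequence length instead
requires a fragment to be matched along (essentially) its full length to
join a cluster, which is also the convention of greedy clusterers of the
cd-hit-est family. For near-full-length alignments of similar-length
monomers the two definitions agree.

Where consensus sequences containing IUPAC ambiguity codes are compared,
an ambiguity code counts as a match whenever its base set intersects the
other symbol's (R matches A or G, and so on), implemented as a
substitution matrix over the IUPAC alphabet.

## Read merging

Every candidate 3′ overlap length k (min_overlap ≤ k ≤ min of the two
read lengths) is scored ungapped as matches − mismatches after
reverse-complementing the reverse mate; the best-scoring overlap with a
mismatch rate within the cap wins, ties going to the longer overlap (the
single-fragment interpretation). Inside the overlap the higher-quality
base is emitted, with forward-base preference on ties. Defaults
min_overlap = 10, max mismatch rate = 0.1. Scoring is purely
count-based; base qualities affect only the emitted consensus base, not
the overlap choice. A pair with no qualifying overlap is a normal
no-merge outcome counted in run statistics.

## Repeat screening

Repeat content is estimated by direct local alignment of each library
monomer (both strands) against the read, replacing a general-purpose
repeat masker: the only masking target here is the user-supplied
satellite set, so a library-restricted aligner is sufficient and exactly
testable. Alignments qualify at identity ≥ 0.7 over ≥ 25 columns; the
qualifying best hit's read interval is hard-masked (a symbol that can
never match) and the search repeats, so a read spanning a monomer
junction — two partial copies — is fully covered by successive hits. The
repeat fraction is the union length of qualifying intervals over the
read length, and the default retention threshold is 0.99.

Two practical notes, both verified by the oracle tests: local alignment
trims or overshoots interval boundaries by a few columns, so fractions
near a boundary value (e.g. a half-repeat read) deviate from the naive
expectation by a few percent; and at the 0.7/25 cutoffs a ~100-bp random
sequence occasionally contains a chance-level qualifying hit. Neither
affects retention at the 0.99 threshold, which only full-length repeat
reads reach.

The anchor-window scan assigns each read the leftmost reference
coordinate of its best local alignment (strand-symmetric) and returns
the 25-bp window containing the most start coordinates, ties broken
toward the smallest window start. Note the tie-break's consequence: when
a single coordinate is modal, the scan returns the *leftmost* window
containing it, not the window starting at it.

## Greedy clustering and cluster statistics

Sequences are sorted by length (descending, ties by id); the first
founds cluster 0; each subsequent sequence is compared against existing
representatives whose length ratio is ≥ 0.8 and joins the one of highest
identity ≥ the threshold (best-assignment), else founds a new cluster.
The full identity is computed against every eligible representative —
no word-filter heuristics — which keeps the procedure exactly
reproducible by a brute-force oracle at desk scale.

Cluster composition tallies members by source library; Shannon's H is
reported in natural log (the base is declared in output headers).
Normalised counts divide the raw count by the total reads entering the
pipeline and by the total passing the repeat filter, summed over
sources; per-source denominators are available from the composition and
the per-source totals when a per-library normalisation is wanted.

## Cluster graph and mixing

All representative pairs are compared by the local kernel over both
strands; similarity = 100 × matches / alignment columns. The MST is
Kruskal over distance = 100 − similarity with a deterministic tie-break
(equal-distance edges ordered by smaller then larger node id), validated
against exhaustive spanning-tree enumeration for small graphs. Edges may
be pruned below 85% similarity for display only, never before MST
construction. The mixing summary reports the fraction of clusters with
two or more source libraries and the size-weighted mean Shannon's H.

## Monomer statistics

**Consensus.** Center-star progressive alignment: the clone with the
highest mean pairwise identity anchors the alignment; every other clone
is oriented to the anchor's strand, aligned to it with the global
kernel, and merged under once-a-gap-always-a-gap. Per column, the
majority base wins; ties become the IUPAC code of the tied set; columns
with more than 50% gaps are dropped. A hand-written progressive aligner
(rather than an external MSA tool) keeps the package self-contained at
the ≤ 70-sequence scale this analysis needs; one test cross-checks the
consensus against a mafft-based majority consensus on substitution-only
clones.

**Identity matrices.** Intraspecific identity is the mean over all
unordered clone pairs within a species (mean-pairwise was chosen over
alignment-consensus identity; the definition is declared rather than
assumed). Interspecific identity compares species consensuses with
ambiguity-aware matching. The concerted-evolution test flags every
ordered pair (i, j) with inter(i, j) > intra(i): under homogenising
drive no pair should be flagged; a conserved satellite flags many.

**CENP-B box.** The 17-bp motif (default: the human consensus
YTTCGTTGGAARCGGGA with critical positions 1–4, 9, 12–15, 0-based) is
configuration data, not a constant. Every window on both strands is
scored by conserved critical positions; ties prefer more total motif
matches, then the smaller forward-strand offset, then the + strand.
Critical-base counting is the scoring surface; no motif p-values are
computed.

**Digest.** Complete digestion at every exact site occurrence, with the
fragment boundary one base into the site (MspI's C^CGG). The ladder bins
fragments by round(length / monomer length). For an array whose copies
lose their site independently with probability q, the rung-k fraction
per monomer follows (1−q)²·q^(k−1), which the simulator reproduces
within Monte-Carlo error.

## The simulator

The simulator defines the study conditions for all end-to-end tests: a
four-species tree `((maniculatus:1,polionotus:1):1,(californicus:1,
leucopus:1):1)` (branch lengths in arbitrary units), a random 345-bp
ancestral monomer carrying exactly one restriction site (kept site-free
across tandem junctions), and a library of 20 monomers per lineage.
Substitutions follow a uniform three-way model (no indels by default —
the monomer-length conservation typical of such satellites suggests
indel-sparse evolution). Branches are discretised into 0.1-unit
segments so substitution and homogenisation interleave as an ongoing
balance rather than phase by phase.

* **drive** — substitution rate 0.05/site/unit; homogenisation 10
  events/monomer/unit, each copying a uniformly chosen donor over a
  uniformly chosen recipient (the simplest gene-conversion analog).
  These rates put within-species identity near 94–96% and cross-species
  identity near 80–90%: comfortably astride the 95% clustering
  threshold, so drive-mode clusters are species-pure.
* **frozen** — no homogenisation; 90% of sites constrained (immutable),
  the rest at the same nominal rate, giving ~98% identity both within
  and between species, so clusters intermingle all species.

Arrays concatenate library draws with replacement (60 copies by
default); each copy's restriction site can be ablated by an in-site
substitution with probability q, redrawn if the substitution would
recreate a shifted site against the flanking bases. Reads are 100-bp
pairs from 160-bp inserts placed uniformly on the array (40-bp true
overlap for the merger), substitution errors at 0.5%, constant Q30
qualities. Everything is byte-deterministic under the configured seed.

What the simulator does *not* emulate: real base-quality profiles,
indels, higher-order repeat structure, library-preparation biases, and
genomic background sequence beyond the arrays. Passing end-to-end tests
therefore demonstrates that the pipeline separates the two evolutionary
regimes under clean, known conditions — not that it is robust to every
artefact of real shotgun data.

## Problem sizes and numerical choices

End-to-end tests and the acceptance script run 12 monomers per species
and 60 read pairs per species through the full pipeline, cluster at the
95% threshold, and summarise identities over subsets of monomer pairs;
the digest ladder uses 10,000 copies. These sizes give stable statistics
(binomial standard errors well inside the asserted margins) while
keeping a full run in minutes on one core. Degenerate inputs are
errors, not silent results: empty reads, empty libraries, unpairable
mate files, disconnected similarity graphs and sub-minimum clone counts
all raise typed exceptions naming the offending item.

## Known limitations

* Greedy clustering is order-dependent by design (length, then id); it
  reproduces the reference greedy partition, not an optimal one.
* The center-star consensus is a heuristic MSA; for clone sets with
  substantial indel variation a dedicated aligner would be preferable.
* Cluster similarity uses representatives, not cluster consensuses.
* The screening step's 0.7/25 local-alignment cutoffs are declared
  stand-ins for a repeat-masking engine's internal defaults; they are
  part of this toolkit's contract rather than a reproduction of any
  specific engine.
* File-based runs need an explicit read-to-source mapping (`--sources`)
  to compute composition; FASTQ itself carries no library label.
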