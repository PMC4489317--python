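# Methods

This note documents the models and procedures implemented in `zgene`, the
parameters that matter, the synthetic data the package is validated on, and
the numerical choices made where the design was genuinely open.

## The Z-curve encoding of an ORF

The Z transformation maps the four frequencies of a nucleotide slot
(f_A, f_C, f_G, f_T) onto three chemically meaningful axes:

    x = (f_A + f_G) − (f_C + f_T)     purine vs pyrimidine
    y = (f_A + f_C) − (f_G + f_T)     amino vs keto
    z = (f_A + f_T) − (f_G + f_C)     weak vs strong hydrogen bonding

Since the four frequencies of a slot sum to a constant, every group of 4
frequencies contributes 3 independent variables (the 3/4 reduction that
appears in all the block arithmetic below).

An ORF is described by *phase-specific* k-mer statistics: the phase of a
k-mer is the codon position (1, 2 or 3) of its leading base. For k ≥ 2 the
frequencies fed to the transform are conditional within a *prefix group* —
the distribution of the final base given the preceding k−1 bases and the
phase. This makes each group a proper probability quad and yields exactly
the advertised dimensionality:

| block | k | phases                      | prefix groups | variables |
|-------|---|-----------------------------|---------------|-----------|
| mono  | 1 | codon positions 1, 2, 3     | 3             | 9         |
| di    | 2 | positions 1–2, 2–3, 3–1     | 12            | 36        |
| tri   | 3 | leading base at 1, 2, 3     | 48            | 144       |
| tetra | 4 | leading base at 1, 2, 3     | 192           | 576       |

Total: 765. The legacy 33-variable encoding keeps the mono block and the
two within-codon dinucleotide phases only (9 + 24). Design choices:

* The stop codon is excluded from counting — its composition is constant
  across ORFs and carries no discriminative signal.
* A prefix group with zero occurrences emits (0, 0, 0), the uninformative
  point of the Z space; this keeps short ORFs well-defined.
* k-mer windows containing N are skipped.
* Block order is mono → di → tri → tetra, phase-major, lexicographic prefix
  (A < C < G < T), (x, y, z) innermost. Any fixed order would do; this one
  is documented and asserted structurally in the tests.

## Self-trained linear classifier

The classifier is built from the anonymous genome itself; no external
labels are used.

**Positives.** Canonical ORFs of length ≥ 480 nt (`seed_min_len`) that are
not dominated by a longer overlapping candidate. Random ORFs of that length
are vanishingly rare under a null composition model (probability of a
stop-free run of 160 codons ≈ (61/64)^160 ≈ 5·10⁻⁴ per stop), so the seed
set is almost pure coding sequence in gene-dense prokaryotic genomes. At
least 50 positives are required; fewer is an error advising a relaxed
threshold.

**Negatives.** Two sources, both tagged in the training-set provenance:

* *Shuffled*: nucleotide-order shuffles of each positive (the stop codon is
  left in place), preserving base composition exactly while destroying all
  phase structure. Additional shuffles are truncated to lengths sampled
  from the sub-seed candidate pool, so the decision boundary sees the
  higher feature variance of short ORFs during training.
* *Shadow*: opposite-strand ORF candidates overlapping a positive by ≥ 60%
  of their own length. These teach the model that merely being an ORF
  (stop-depleted in frame) is not evidence of coding.

**Fit.** A linear max-margin classifier (squared-hinge SVM, C = 1) on
features standardized to zero mean / unit variance; the standardization is
folded back into the stored weights so scoring is a plain dot product and
serialized models reproduce scores bit-for-bit. One optional self-training
refinement pass (default: one iteration) relabels by confident scores
(|score| > 1) and refits; if either refined class empties, the previous
model is kept with a warning.

**Length-calibrated decision rule.** Raw margins of noncoding ORFs scatter
with a spread that grows as ORF length shrinks (frequency estimates of an
L-nt sequence have standard error ∝ 1/√L). A single margin cutoff therefore
either floods the output with short false calls or starves it of short true
genes. After training, the package fits a null model of the raw score from
shuffled draws across the candidate length distribution:

    μ(L) = a₀ + a₁/√L        σ(L) = b₀ + b₁/√L

(least squares; σ from absolute residuals scaled by √(π/2)). A candidate is
called a gene when its raw score exceeds `threshold` (default 0, the
max-margin boundary) **and** its null z value (score − μ(L))/σ(L) exceeds
`null_z_min` (default 3). The 3σ default keeps the expected number of
null false calls per genome near Φ(−3)·N ≈ 3 for N ≈ 2000 candidates,
independent of the genome's ORF length profile.

## Overlap resolution

Retained genes may pairwise overlap by at most `max_overlap_nt` (default
30 nt) on either strand. Two candidates conflict exactly when their
intervals shrunk by half the cap on each side overlap, so the conflict
graph is an interval graph and the *maximum-total-score* conflict-free
subset is computed exactly by the classic endpoint dynamic program in
O(n log n). A greedy score-descending sweep was evaluated first and fell to
0.85× the optimum on adversarial candidate clusters, so the exact solver is
the default; it is just as deterministic (score ties prefer the longer,
then leftmost candidate). Origin-wrapping candidates of circular contigs
are added afterwards in score order when compatible.

## Translation start relocation

The stop codon fixes gene identity; the start is chosen among the in-frame
candidate starts recorded at enumeration time (at most
`max_start_candidates` = 20, counted from the 5′ end). Each candidate start
is scored as

    coding_score(truncated ORF) + λ · SD_score

where SD_score is the best ungapped identity count of the Shine–Dalgarno
motif (default AGGAGG) in a window 5–13 nt upstream of the candidate start
(strand-aware, wrapping on circular contigs). λ defaults to 0.25 so that
the SD term (identity counts 0–6, spread ≈ 1 between random and perfect
sites) and the coding term (margins with spread ≈ 1–2 on typical genomes)
move the decision comparably. The 3′ terminus never changes; with no
scoreable candidate the canonical longest start is kept. On the synthetic
benchmark below this relocator places 92–94% of matched starts exactly.

## Joint application of two gene finders

Two prediction sets are partitioned by the 3′-terminus key
(contig, strand, stop coordinate) — the same matching rule the evaluation
module uses. Shared predictions are retained outright; program-specific
predictions pass a pluggable homology-confirmation predicate standing in
for a protein-database search with the query's own genus excluded
(a whitelist oracle and always-true/false oracles are provided; a live
database search is deliberately out of scope). The final set is the union
of shared predictions and confirmed specifics: sensitivity can only match
or exceed the better input, and retained extras can only match or undercut
the better input, which the acceptance tests verify on synthetic data.

## Essentiality scoring

Each query protein is looked up in n reference organisms with known
essentiality labels and an evolutionary distance dᵢ to the query organism.
With eᵢ = 1 when reference i reports an essential ortholog and 0 otherwise,

    score = Σᵢ wᵢ eᵢ / Σᵢ wᵢ,      wᵢ = exp(−dᵢ) by default,

a convex combination of {0, 1} evidence, hence in [0, 1]; genes scoring
≥ cutoff (default 0.5, the neutral midpoint) are called essential. The
ortholog matcher is a contract: an exact-id fixture matcher for tests, and
a reciprocal-best-hit matcher over BLOSUM62 local alignment scores
(minimum score 50) for real proteomes. Distances are inputs; the package
does not estimate phylogeny.

## Evaluation statistics

Coding predictions are correct iff they share an annotated gene's
3′ terminus, never requiring start agreement. With counts of annotated (A),
predicted (P) and correct (C) genes:

    Sn = C/A    PPV = C/P    Accuracy = (Sn + PPV)/2    APR = (P − C)/A

Essentiality calls are scored per annotated gene; a gene is correct only if
it was found *and* given the right class, so genes missed by the caller
count as incorrect for their class:

    Sn = correct essential / annotated essential
    Sp = correct nonessential / annotated nonessential
    OA = all correct / all annotated

Counts are integers and statistics are exact rationals internally; display
rounding is 4 decimals for coding and 3 for essentiality reports.
Aggregation over genomes reports mean and sample SD (population SD by
flag). `length_stratified_auc` compares two score sets only within ORF
length bins, isolating compositional discrimination from the length–score
correlation that any frequency-based classifier carries.

## Synthetic data: what it emulates and what it does not

`SyntheticGenomeSpec` defaults define the reference study conditions used
throughout the tests and the acceptance script: 200 kb linear genome,
150 planted genes, codon bias strength 0.5, intergenic GC 0.5, essential
fraction 10% (the strong class imbalance of real bacterial essentiality
screens), seed-driven and byte-reproducible.

* Codon table: softmax of bias × a fixed standard-normal logit vector over
  the 61 sense codons; bias 0 is exactly uniform and the divergence from
  uniform is monotone in the bias for a fixed seed.
* Genes: start codon (ATG/GTG/TTG at 85/10/5%), iid codon-table interior,
  uniform stop; lengths 300 + 3·(Geometric − 1) nt with mean 900. Genes sit
  on both strands, never overlap, and carry a planted AGGAGG at a 5–13 nt
  spacer upstream of the true start.
* Intergenic background: order-0 iid nucleotides at the specified GC — the
  simplest structure that makes phase-specific statistics discriminative,
  which is precisely what the encoder must detect.
* Essentiality references: every query protein is present in every
  reference proteome; a reference labels it essential with probability 0.9
  (truly essential genes) or 0.1 (others), a Bernoulli pattern that lets
  the weighted integration be tested end-to-end with the id fixture
  matcher.

Not modelled: operon structure, overlapping genes, ribosome-binding-site
sequence variation beyond the planted motif, horizontal-transfer
composition mosaics, annotation errors, and codon usage that varies along
the genome. Passing the synthetic benchmarks therefore demonstrates that
the machinery recovers phase-specific compositional signal under
controlled conditions; it does not by itself establish accuracy figures
for real genomes, where those unmodelled features dominate the error
budget.

A note on the no-signal control: at bias 0, intergenic ORFs are iid-uniform
sequence conditioned on being stop-free, which is exactly the distribution
of the planted genes' interiors — so gene vs intergenic-ORF discrimination
at matched length is a true null (AUC ≈ 0.5). A pooled AUC without length
stratification is ≈ 0.9 even at bias 0, purely because scores correlate
with length; the stratified statistic is the honest control. A small
residual (≈ +0.05) remains from start-codon composition and upstream ORF
extensions that swallow the planted ribosome-binding motif.

## Determinism, problem sizes, degenerate inputs

All randomness (shuffling, solver, generator, calibration draws) flows from
one seed per run; identical inputs and seed give byte-identical output
files. The default test suite and the acceptance script use 200 kb × 10
replicate genomes for the coding benchmark, 8 (script) or 5 (suite)
replicates for the null control, and 150-gene fixtures for consensus and
essentiality — sizes chosen to exercise every stage at full fidelity while
keeping a complete run in tens of seconds on one CPU. Degenerate inputs are
contracts, not crashes: empty FASTA, non-nucleotide characters, end < start
annotations, too few seed positives, single-class training collapse,
zero-weight reference panels and out-of-range cutoffs all raise (or warn,
where the spec of the operation prefers degradation) with messages naming
the offending record.

## Known limitations

* The start relocator is a deliberate simplification of dedicated
  start-site tools (positional weight matrices, spacer-length priors,
  leaderless transcript handling are absent).
* The reciprocal-best-hit matcher is O(n²) pairwise alignment — fine for
  fixture-scale panels, slow for full proteomes; a k-mer prefilter or an
  external search tool behind the matcher contract is the upgrade path.
* Per-genome self-training assumes a gene-dense genome with enough long
  ORFs; tiny plasmids or heavily fragmented drafts need a pretrained model
  passed in explicitly.
* GC-skewed genomes with strong strand-specific mutation pressure may
  weaken the shadow-negative heuristic; the negative policy is pluggable
  for that reason.
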