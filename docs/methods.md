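# Methods

This note records the models, parameter choices and numerical decisions
behind `paleodup`, and what the synthetic-data experiments do and do not
demonstrate.

## NG86 Ka/Ks

Site counting, pathway averaging and Jukes–Cantor correction follow the
classical Nei–Gojobori method with the standard genetic code:

* Synonymous sites per codon: for each position, the fraction of the 3
  possible single-nucleotide changes that preserve the amino acid; changes
  to stop codons are excluded from the numerator but remain in the
  denominator of 3. S + N = 3 per codon exactly.
* Differences for a codon pair differing at k ∈ {1,2,3} positions are the
  unweighted average over the k! single-step pathways. Pathways through
  stop codons are excluded from the average; in the (rare) case that every
  pathway is blocked, each differing position is classified by the
  single-position swap in the context of both end codons, with an equal
  syn/nonsyn split when neither swap is a sense codon. This choice is
  deterministic and matches common implementations; the original method
  description does not pin it down.
* Codons containing gaps or N, and stop codons, are excluded from the
  alignment and counted in `n_excluded`.
* Jukes–Cantor: d = −(3/4)·ln(1 − 4p/3), applied independently to pₛ and
  pₙ; p ≥ 0.75 sets the `saturated` flag. No gamma rate correction and no
  ML codon model — NG86 is deliberately the method implemented.

Per-codon site counts and per-codon-pair pathway averages are precomputed
into 64 and 64×64 tables at import, making `ng86_pair` a table lookup per
codon; the tests re-derive both tables with exact Fraction arithmetic by
independent enumeration.

Pairwise protein alignment uses global affine Needleman–Wunsch
(BLOSUM62, gap open −10, extend −0.5 by default) via Biopython's
PairwiseAligner; a gap of length k costs open + (k−1)·extend. The first
optimal traceback is returned, which is deterministic for fixed inputs.

## Synthetic genomes

The generator plants every structure the pipeline is meant to recover.

* **Coding sequences** are drawn from the four fully 4-fold-degenerate,
  stop-safe codon families GCN/GTN/CCN/ACN (Ala, Val, Pro, Thr). Every
  codon then contributes exactly one synonymous site (the third position)
  and two nonsynonymous sites, and synonymous evolution is an exact
  Jukes–Cantor chain at the third position — so NG86 + JC estimation of a
  planted Ks is asymptotically unbiased by construction, which is what
  makes Ks-recovery experiments meaningful. Substitution counts are
  Poisson per site with multiple hits allowed; a transition bias parameter
  (default 1.0 = unbiased, required for the exact-JC fast path) weights
  the substitution spectrum. Nonsynonymous divergence (default Ka/Ks =
  0.2, a typical purifying-selection ratio) walks between the safe
  families so the site structure of every codon is invariant; planted Ka
  is therefore approximate, planted Ks exact. Real coding sequences have
  mixed degeneracy classes, codon-usage bias and rate heterogeneity, so
  passing recovery tests here demonstrates correctness of the estimator
  chain, not robustness to those real-data features.
* **WGDs** duplicate every chromosome and then delete each duplicated gene
  independently with probability 1 − retention. Divergence is applied
  along the implied lineage tree so that copies split at an event with
  target Ks t end up at pairwise divergence t. No rearrangement is
  simulated (an explicit simplification; inverted-block handling is
  exercised separately by the chaining tests). Defaults plant two events,
  Ks 1.0 (retention 0.6) and Ks 0.113 (retention 0.4) — the two-peak,
  4:1-depth regime of a twice-duplicated Caryophyllales genome, with ages
  66.3 and 7.5 My under r = 7.54 × 10⁻⁹/site/year.
* **Tandem arrays** insert 1–2 adjacent copies of a source gene
  (probability 0.05 per gene, pair divergence Ks 0.02). All members of a
  planted array are labelled TD in the truth table, matching the
  classifier's TD-before-WGD precedence.
* **Companion genomes**: a pre-WGD ancestor snapshot (`anc_*`
  chromosomes) for syntenic-depth experiments, and a duplication-free
  outgroup (`ort_*`) at ortholog divergence Ks 0.28 — the printed
  purslane/*P. amilis* ortholog peak — for clock-rate calibration.
* **Expression**: group-mean TPM profiles per diel class (C4-like:
  CK-day 200 vs CK-night 10, stress-day 20; CAM-like: drought-night 1000
  vs CK-night 5, a 200-fold induction consistent with the
  hundreds-to-thousands-fold stress-night induction of CAM copies; none:
  flat 20) with lognormal replicate noise of CV 0.3 and 3 replicates per
  condition × time across CK/D/H/DH × day/night.
* **Promoters and motifs**: uniform-composition promoters; one PWM's
  consensus is inserted at a uniform offset with probability 0.6 in module
  promoters vs 0.1 in background promoters (equal rates give the null
  calibration experiment).

Determinism: a `SimulationConfig` (including seed) fixes every output
byte-for-byte.

## Synteny

Anchors are homolog pairs located by gene rank. Homolog search uses a
shared-8-mer prefilter (≥ 5 shared protein 8-mers) and rescoring by global
alignment, reporting the score normalised by the smaller self-score; pairs
with normalised score ≥ 0.5 within the top-5 partners of either gene are
kept. Chaining maximises Σ anchor scores − gap_penalty·Σ(rank gaps) by
longest-path DP per chromosome pair and orientation with rank deltas in
[1, max_gap] on both axes, extracting chains greedily best-first
(MCScanX-like, not a globally optimal disjoint cover); min_block=5 and
max_gap=25 are the MCScanX defaults. Tandem pairs are removed from the
anchor list before self-comparison chaining — otherwise arrays chain into
spurious near-diagonal "blocks" that contaminate the Ks distribution with
a low-Ks component. Tandem arrays themselves are connected components of
same-chromosome homolog pairs with ≤ 1 intervening gene (configurable).

Duplicate-origin classification: TD if in a tandem array (TD wins over
WGD); else WGD if the gene anchors ≥ 1 self-synteny block and its family
retains ≥ `min_copies` syntenic copies; else dispersed (family ≥ 2) or
singleton. `min_copies` defaults to 3 — the "at least 3 copies after two
WGD rounds" criterion, counting the focal gene. Note the synthetic truth
labels a gene WGD whenever at least one duplicate partner survives, i.e.
family size ≥ 2; recovery experiments therefore evaluate at
`min_copies=2`, and with the stricter default a large fraction of
two-copy families is reported dispersed by design, not by error. Whether
the 3-copy criterion counts the focal gene is genuinely ambiguous; the
parameter exposes both readings.

## WGD inference

Anchor Ks values (0 < Ks ≤ 3.0 by default, saturated pairs dropped) are
fitted with 1..4-component Gaussian mixtures on log Ks (EM, 10
initialisations, fixed seed, covariance floor 1e-6; degenerate all-equal
input short-circuits to one component with an sd floor of 1e-3).
Model selection is BIC **restricted to candidates whose fitted density has
as many local maxima as components**: EM otherwise splits a single skewed
peak (per-pair Ks at a few hundred codons is discrete and right-skewed
within a peak) into two heavily overlapping components that do not
represent separate duplication events. Component means are reported
back-transformed to the Ks scale; per-block median Ks is also computed and
can be fitted instead of per-pair values to reduce block-size bias.

Dating is exact arithmetic: T = Ks/(2r)/10⁶ My, with
r = 7.54 × 10⁻⁹/site/year as the Caryophyllales default;
`estimate_rate(ks, T)` is the algebraic inverse (round-trips to machine
precision). With the implied peak positions Ks ≈ 1.0 and ≈ 0.1126 these
give 66.31 and 7.47 My.

## C4/CAM classification

Expression phasing operates on group means with a pseudocount of 0.1 in
ratio denominators. C4-like: CK-day ≥ 4× CK-night, CK-day ≥ 1 TPM, and
≥ 4-fold day downregulation under some stress; CAM-like: stress-night
≥ 10× CK-night, ≥ 4× that stress's day mean, and ≥ 1 TPM. The fold
thresholds (4, 4, 10) are this package's operationalisation of
qualitative descriptions ("highly expressed during the day",
"hundreds to thousands of times higher at night under stress") — they are
documented defaults, not reproductions, and all are exposed as
parameters. When both rules fire, CAM wins: stress-night induction is the
discriminating CAM signature. The expressed-gene filter is TPM > 1 in ≥ 2
replicates of ≥ 1 condition.

Residue diagnostics read alignment columns mapped from ungapped reference
numbering (maize PEPC Zm00001d046170). Position 780 alone drives the
residue call (S → functional C4/CAM type, A → non-photosynthetic,
otherwise ambiguous) because the S780 rule is known to admit exceptions;
890 (R tight inhibitor binding vs M/G low affinity) and 519 (malate
sensitivity, D509 in *Kalanchoë* numbering — the cross-numbering offset is
taken as given) are recorded as evidence only. Final classes are the
conjunctions residue-functional ∧ C4-like → C4-specific and
residue-functional ∧ CAM-like → CAM-specific.

## Motif enrichment

PWMs are normalised with a background-weighted pseudocount of 0.1 and
scored in log2-odds bits against a 0-order background (estimated from the
scanned promoter set unless supplied). Window p-values are exact tail
probabilities of the discretised score distribution (granularity 10⁻³
bits), computed by dynamic programming; zero-probability cells (possible
with pseudocount 0) are handled as unreachable mass. Hits are windows
with p ≤ 10⁻⁴ on either strand, overlaps allowed, N-containing windows
skipped. Both the batch scanner and the single-promoter scanner share the
same integer scoring, and tests compare the DP tails against brute-force
enumeration over all 4^L windows.

Enrichment counts genes with ≥ 1 hit (gene-level occurrence — chosen over
hit-level counts for compatibility with the Fisher test; hit counts are
still available from the scanner). The module is its genes with
membership > 0.8 among expressed genes; the background is **all** expressed
genes, module included. The one-sided (greater) Fisher p-value is the
hypergeometric tail, with a 0.5 Haldane correction on the odds ratio when
a cell is zero; q-values are Benjamini–Hochberg; `enriched` means
q < 0.1; the enrichment score is log2 of the module/background frequency
ratio; clusters with > 3 enriched member motifs are highlighted.

## Problem sizes and tolerances in the experiments

Recovery experiments simulate 2 × 500 ancestral genes of 200 codons with
the default two-WGD regime (five fixed seeds), which is large enough that
the planted Ks modes are recovered within ±0.05, modal syntenic depth is
exactly 4, and duplicate-origin accuracy exceeds 90% among genes whose
partners survive. Ks-estimator consistency uses 10,000-codon pairs.
Motif-enrichment calibration uses modules of 200 genes against
backgrounds of 1,500–5,000 promoters of 300–500 bp; promoter length only
scales the number of scanned windows and does not affect the statistics
under test. The acceptance script re-runs all of this from scratch at a
single seed.

## Known limitations

* NG86 only; no ML codon models, no rate heterogeneity, no transversion
  weighting in the distance correction.
* The chaining stage reproduces MCScanX-like greedy behaviour, not an
  optimal disjoint chain cover; oracle guarantees cover the single best
  chain.
* The simulator omits rearrangements other than optional inversions at
  the anchor level, intergenic sequence evolution, and codon-usage
  realism; see above for what that implies about test evidence.
* Promoters overlapping upstream genes are not masked before motif
  scanning.
* GFF support is the gene-feature subset (one model per locus), by scope.
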