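# Methods

This note documents the models, conventions and numerical choices behind
operon-dms, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite does not itself compute.

## The measurement model

The pipeline targets selection screens of single-codon saturation (NNK)
libraries of a gene inside an operon. Each variant's abundance is measured
by amplicon sequencing before selection (permissive host) and after
selection (host in which the phenotype couples to survival). The survival
score of mutant *i* in one replicate is

    S_i = (n_i,post / N_post) / (n_i,pre / N_pre)

where `N` counts all identified single mutants plus WT in that sample, and
the enrichment score normalizes to the wild type:

    ES_i = S_i / S_WT = (n_i,post / n_WT,post) / (n_i,pre / n_WT,pre)

The condition totals cancel, so ES is invariant under uniform rescaling of
either condition's counts (tested as a property). ES(WT) = 1 identically.
No pseudocounts are used anywhere: a variant with zero post-selection reads
but adequate pre-selection coverage has ES = 0, a meaningful "fully
depleted" value, while a variant below the pre-selection read cutoff
(default 20 reads per replicate) is *missing*, not zero. Replicate ES values
are averaged arithmetically over the replicates that pass the cutoff, and
the number used is recorded.

Fitness per generation is w = ES^(1/g). The generation count is
g = floor((t_total − t_lag) / t_doubling); with the default plate-growth
parameters (14 h total, 1.4 h lag, 20.2 min doubling) this gives g = 37.
Floor is the conservative rounding; for these defaults round() agrees.

Phenotype classes partition [0, ∞) with closed boundaries chosen so the
boundary values 0.1 → inactive and 0.7, 1.5 → active: inactive ES ≤ 0.1,
marginal 0.1 < ES < 0.7, active 0.7 ≤ ES ≤ 1.5, hyperactive ES > 1.5.
A property test verifies the bins have no gaps or overlaps.

Per-position summaries report the class fractions among scored mutants,
flagging positions with ≤ 10 scored mutants as excluded, and the average
pairwise codon ES difference: for codons encoding the same *mutant* amino
acid at a position, the mean of |ES_a − ES_b| over all unordered pairs,
pooled across mutant amino acids (the pair count is the denominator). The
pooled reading (rather than averaging per-amino-acid means) follows the
formula as written; with equal pair counts per amino acid the two coincide.

## Read processing conventions

- **Demultiplexing** requires an exact match of the read's first six bases
  to a condition MID tag (both mates must carry the same tag); unmatched
  pairs go to an `unassigned` bin and are reported, never silently dropped.
  Every input pair ends in exactly one fate (counted, filtered, merge-
  rejected, rejected-with-reason, unassigned) — a conservation property
  checked by tests.
- **Quality filter**: the Phred cutoff of 20 is interpreted as *mean* read
  quality ≥ 20 (a per-base mode is available); minimum length 75 nt.
- **Merging**: the reverse mate is reverse-complemented and the maximal
  exact suffix/prefix overlap (≥ 10 nt) is sought. Any mismatch in the
  overlap disqualifies it; pairs with no exact overlap are discarded. This
  is the strictest reading of "merge only identical overlaps" and trades
  yield for accuracy.
- **Alignment**: Smith–Waterman local alignment with EDNAFULL-equivalent
  scores (match +5, mismatch −4) and affine gaps, opening penalty 20,
  extension 0.5. A gap of length L costs open + (L−1)·extend. The
  implementation is Biopython's `PairwiseAligner`; the test suite checks it
  against an independent brute-force Gotoh dynamic program on hundreds of
  random short sequence pairs.
- **Variant calling** keeps only gapless alignments spanning the entire
  reference; reads with indels, ≥ 2 differing codons, or an N inside the
  differing codon are rejected with an explicit reason. The batch driver
  takes a direct codon-comparison path when the merged read length equals
  the reference length (provably equivalent to align+call for gapless
  full-coverage reads) and memoizes calls by merged sequence; this keeps a
  depth-10^5, three-replicate round trip in seconds without changing any
  result.
- **Error thresholds**: a specific erroneous single-base variant among
  `N` reads at quality Q is Poisson with rate λ = N·10^(−Q/10)/4. The
  division by 4 follows the convention that all four bases are equally
  likely to be assigned in error; a /3 mode (three alternative bases) is
  available. The minimum-read threshold uses the strictly-greater tail
  criterion (smallest k with P(X > k) < α) by default, which gives 13 at
  N = 100,000, Q35, α = 0.05; the P(X ≥ k) reading gives 14 and both
  conventions are exposed, plus a normal approximation. The default was
  chosen to match the strictly-greater reading of "at least the observed
  number"; the ambiguity is documented rather than resolved.

## The synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for all downstream validation.

- **Library structure**: all 32 NNK codons at each mutagenized position
  (2,272 variants for 71 positions), equimolar positions and equimolar
  variants within a position (the real pooled balance is unknown; equimolar
  is the neutral default). The WT fraction defaults to 10%, matching the
  library composition modelled (≈ 2.7% NNK-regenerated WT plus ≈ 7.3%
  template carryover); `expected_wt_fraction` computes the NNK-borne part
  exactly from which reference codons end in G/T. NNK variants whose codon
  equals the reference codon are WT sequence, indistinguishable by
  sequencing, and are folded into the WT count row.
- **Effect model** (invented, minimal): log true survival is
  `log(baseline) + β·log(RCU) + region offsets + N(0, σ²)` noise, with a
  fixed strongly-deleterious multiplier (default 10⁻³) for nonsense
  variants, where RCU is undefined. This is the smallest model that
  reproduces a codon-optimality-driven phenotype for testing; it makes no
  mechanistic claim. WT survival is the baseline exactly.
- **Counts**: unselected counts are one multinomial draw per replicate at
  the library proportions (default depth 10^5, the order of usable reads
  per replicate in the experiments modelled); selected proportions are the
  unselected proportions reweighted by true survival, drawn independently.
  Replicates are independent; everything is seeded and byte-reproducible.
- **Reads**: each counted molecule yields a forward read (MID tag + gene
  sense strand) and reverse read (tag + reverse complement), covering the
  full gene, constant Phred qualities, substitution errors at a
  configurable rate (default 0). No PCR bias, chimeras, indel errors or
  quality decay are simulated — so passing round-trip tests demonstrates
  the correctness of the accounting, not robustness to those artifacts.

What the simulations do show: with error-free reads the processing stack
reproduces the simulated count table *exactly* (count-for-count), and at
depth 10^5 with true survivals spanning [10⁻³, 10] the estimated log-ES
correlates with true log-survival at r ≥ 0.95, with ≥ 95% of variants of
true survival ≤ 0.05 classified inactive. Variants with zero or missing
estimated ES are excluded from the log–log correlation (log undefined).
What they do not show: behaviour under real error profiles, context-
dependent machine error, or amplification bias.

## Codon feature tables

RCU, relative tRNA abundance, relative stalling and relative CAI all follow
the mutant-over-WT convention and equal 1 when mutant = WT. The packaged
codon usage table carries standard E. coli K-12 per-amino-acid usage
fractions. The packaged tRNA-abundance and ribosome-stalling tables are
**synthetic stand-ins** (seeded random per-codon values, marked as such in
their filenames and headers): measured tables are external datasets not
shipped here, and no test or result depends on the packaged values — all
correctness tests use small toy tables, and all operations accept user
tables. Where multiple tRNA species decode one codon, a user building a
real table should sum their abundances. CAI uses Sharp–Li weights
w_c = CUF_c / max CUF in the synonymous family, excluding Met, Trp and
stops from the geometric mean. Nonsense variants get no RCU/tRNA/CAI value
and carry an explicit flag; nothing is silently dropped.

## Anti-SD hybridization model

Window energies use a transparent nearest-neighbor RNA/RNA duplex model:
the best contiguous complementary run (Watson–Crick or G·U wobble) across
all antiparallel registrations of the 8-nt window against the anti-SD
5'-CCUCCUAU-3', scored as one duplex-initiation penalty (+4.09 kcal/mol)
plus the sum of stack free energies. Watson–Crick stacks use standard
Turner-style values; all wobble-containing stacks use a single
representative value (−1.3 kcal/mol), adequate because the analyses consume
energy *differences* and rankings induced by complementarity changes, which
the simplification preserves by construction (a mismatch can only shorten a
run, strictly weakening it — tested exhaustively for single mismatches of
the perfect complement). Windows with no complementary run achieving
negative energy score 0 (no stable duplex). Full secondary-structure or
suboptimal-ensemble energies are out of scope; the energy backend is a
plain callable and can be swapped for e.g. ViennaRNA duplex energies.

The internal pause-site scan evaluates the ten 8-nt windows whose spans
intersect the mutated codon (starts from 7 nt left of the codon to 2 nt
into it) and reports per-window ΔG and the mean ΔΔG (mutant − WT); it
requires 7 nt of flanking context. The RBS-strength calculation returns the
most negative window energy within the annotated RBS codon interval,
extended by 3 nt of flank on each side (two codons alone are shorter than
one window). Reported energies are rounded to one decimal in output tables.

## Association statistics

Variants are split at ES ≤ 0.1 (inactive) vs > 0.1 (active), excluding
missing scores; per feature, variants missing that feature are excluded for
that feature only. The two-sided Mann–Whitney U test uses exact enumeration
when n_x + n_y ≤ 12 with no ties, and the tie-corrected normal
approximation with continuity correction otherwise (both via scipy; an
independent enumeration oracle checks the exact path in tests). No
multiple-testing correction is applied to the per-feature calls, matching
the per-feature reporting convention; a Bonferroni column is emitted for
transparency. Box statistics use linear-interpolation quartiles and
1.5·IQR whiskers clamped to the data range.

A calibration caveat established while designing the tests: features
derived from a *fixed* 61-codon table (tRNA, stalling, CAI) inherit
whatever chance correlation that table has with the effect-driving feature
across the codon alphabet. With thousands of variants, even |r| ≈ 0.1 at
the codon level is highly significant — such features are then genuinely,
if weakly, associated, and are *not* valid negative controls. Calibration
tests therefore use per-variant permutation or iid controls (null by
construction) and check rejection counts against binomial bounds over 20
independently seeded libraries, alongside a 1,000-replicate type-I-error
check of the test itself (expected rejection 0.05 ± 0.02 at α = 0.05).

## Pipeline and reproducibility

The `operon-dms` CLI orchestrates simulate → process → score → features →
sd-scan → associate. One global seed fans out to per-stage seeds through
fixed offsets, so stages are independently reproducible; identical
config + seed gives byte-identical outputs (checksummed in the manifest).
All tabular outputs are TSV with a `#` metadata preamble; the manifest
records version, parameters, seed, per-stage record counts and output
checksums. Stage failures abort with the stage name; missing dependencies
between stages (e.g. associate without features) raise explicit errors.

## Test problem sizes

The suite exercises: the full 2,272-variant NNK set over 72-codon toy genes
for the FASTQ round trip (3 replicates, depth 10^5, error rate 0); a
640-variant, 20-position library at depth 10^5 for parameter recovery;
200 random pairs ≤ 30 nt for aligner/oracle equivalence; all sample sizes
3–5 for exact Mann–Whitney enumeration; λ = 1..20 for the Poisson threshold
oracle; and 20 libraries plus 1,000 null draws for statistical calibration.
These sizes were chosen to match the depth and library scale of the
experiments modelled while keeping the default suite fast.

## Known limitations

- The aligner path is exercised mainly for length-mismatched reads; local
  alignment clips terminal mismatches by design, so a substitution in the
  first or last reference base of a read with no flanking context is
  reported as partial coverage by the alignment route (the equal-length
  fast path calls it correctly). Amplicons with flanking context, as in
  real designs, do not hit this corner.
- The duplex model ignores terminal AU penalties, dangling ends, internal
  loops and bulges; absolute ΔG values are approximate and only differences
  and rankings should be interpreted.
- Replicate ES averaging is unweighted; no shrinkage or count-based error
  model is applied (regularized estimators are out of scope).
- The generator's effect model is a test harness, not a biological claim.
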