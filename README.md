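# operon-dms

Analysis toolkit for deep mutational scanning (DMS) of single-codon
saturation libraries in **operonic genes**, modelled on selection screens of
toxin–antitoxin (TA) antitoxins such as CcdA in the *E. coli* ccdAB operon.
In an operon, even synonymous codon changes can be strongly deleterious —
through codon optimality, altered translation efficiency, and changes to the
downstream gene's ribosome-binding site (RBS) that lies inside the upstream
coding sequence. This package provides the full computational pipeline for
such experiments, plus a synthetic-data generator with known ground truth so
every stage is testable without any sequencing download.

## What it computes

For an NNK site-saturation library (N = A/C/G/T, K = G/T; 32 codons per
position, all 20 amino acids and one stop) sequenced before and after
selection:

**Read processing.** Demultiplexing on 6-base MID condition tags; quality
filtering (mean Phred ≥ 20, length ≥ 75); merging of read pairs only when
the overlap is base-identical; Smith–Waterman alignment to the reference
coding sequence (match +5, mismatch −4, affine gaps with opening penalty
20); single-codon variant calling that rejects indels, multi-codon reads and
partial coverage; and a Poisson model of Phred sequencing error giving the
minimum read count at which a variant cannot be explained by error alone
(13 reads at Q35 with 100,000 total reads, P < 0.05).

**Enrichment scoring.** The survival score of mutant *i* is its normalized
read fraction after selection over before selection; the enrichment score
normalizes to wild type:

    ES_i = (n_i,post / n_WT,post) / (n_i,pre / n_WT,pre)

so ES(WT) = 1. Scores require ≥ 20 unselected reads per replicate and are
averaged over replicates. Fitness per generation is w = ES^(1/g) with
g = ⌊(t_total − t_lag)/t_double⌋ (37 for 14 h plate growth, 1.4 h lag,
20.2 min doubling). Phenotypes bin the averaged ES: inactive (≤ 0.1),
marginally active (0.1–0.7), active (0.7–1.5), hyperactive (> 1.5).

**Codon features.** Relative codon usage
RCU = (CUF_mut / CUF of the mutant amino acid's most common codon) /
(CUF_wt / CUF of the WT amino acid's most common codon), relative tRNA
abundance, relative GC content, base changes (codon Hamming distance),
relative ribosome stalling, and relative CAI (Sharp–Li geometric-mean
weights, Met/Trp/stop excluded).

**Anti-SD hybridization.** Nearest-neighbor RNA/RNA duplex free energies of
8-nt mRNA windows against the anti-Shine-Dalgarno tail 5'-CCUCCUAU-3':
a ten-window scan around any mutated codon (internal pause-site creation)
and the best-window ΔG_bind of a downstream gene's RBS region.

**Association statistics.** Two-sided Mann–Whitney rank-sum comparison of
each feature between active (ES > 0.1) and inactive (ES ≤ 0.1) variants,
with box-plot summaries (quartiles, 1.5·IQR whiskers, outliers).

## Worked example

Simulate a 72-codon gene saturated at positions 2–72 (2,272 NNK variants),
with true survival log-linear in log-RCU plus lognormal noise, sequence it
to 100,000 reads per condition in 3 replicates, score it, and test features:

```python
import numpy as np
from operon_dms import synthetic_data as sd, enrichment as en
from operon_dms import codon_features as cf, association_stats as assoc
from operon_dms.core import OperonSpec

gene = sd.random_gene(72, seed=7)
spec = OperonSpec("toy_gene", gene, list(range(2, 73)), rbs_region=(70, 71))
variants = sd.enumerate_nnk_variants(spec)
usage = cf.UsageTable.default()
rcu_map = {v.variant_id: cf.rcu(v.wt_codon, v.mut_codon, usage)
           for v in variants if v.kind not in ("nonsense", "wt")}
model = sd.EffectModel(rcu_coefficient=1.5, noise_sd=0.4, seed=7)
lib = sd.assign_true_effects(variants, model, rcu_map, wt_fraction=0.10, spec=spec)
lib.true_survival *= 0.3
counts = sd.simulate_counts(lib, sd.SimConfig(depth_per_replicate=100_000,
                                              n_replicates=3, seed=7))
records = en.score_table(counts)
feats = cf.feature_table(records, spec.coding_sequence, usage)
report = assoc.feature_association_report(records, feats)
```

This prints (`records["phenotype"].value_counts()` and the report):

```
scored variants: 2230 of 2230
phenotype
marginal       1091
inactive        473
hyperactive     381
active          285

                n_active  n_inactive  median_active  median_inactive  p_value  significant
rcu                 1757         402         1.2143           0.3077   0.0000         True
rel_trna            1757         402         0.9428           0.8604   0.5478        False
rel_gc              1473         351         1.0000           1.0000   0.6301        False
n_base_changes      1757         473         2.0000           2.0000   0.1121        False
rel_stall           1757         473         1.0818           0.7246   0.0000         True
rel_cai             1757         402         1.0025           0.9840   0.0000         True
```

Reading the output: the injected driver, RCU, separates the classes
(inactive variants have median RCU 0.31, i.e. much rarer codons; active
median 1.21). `rel_cai` follows because a single-codon CAI ratio is a
monotone transform of RCU under the same usage table. `rel_stall` is flagged
here because any *fixed* 61-codon table carries some chance correlation with
codon usage, which thousands of variants readily detect — a real caveat of
codon-table features, and the reason the calibration tests use per-variant
permutation controls instead (see `docs/methods.md`). Features truly
independent of the effect (`rel_trna`, `rel_gc`, `n_base_changes`) are not
significant.

The same analysis is available from the shell:

```sh
operon-dms run --outdir myrun --seed 7       # full pipeline, YAML-configurable
operon-dms simulate --outdir sim --seed 1    # counts + truth + paired FASTQ
operon-dms process R1.fastq R2.fastq --reference ref.fasta --mid-map mids.tsv
operon-dms score counts.tsv --generations 37
operon-dms features scores.tsv --reference ref.fasta
operon-dms sd-scan --sequence ref.fasta --codon 70 --wt-codon CGG --mut-codon AGG
operon-dms associate scores.tsv features.tsv
```

## Layout

- `operon_dms.core` — variants, operon/gene description, count tables
- `operon_dms.synthetic_data` — NNK library and FASTQ simulation
- `operon_dms.read_processing` — FASTQ → variant counts
- `operon_dms.enrichment` — ES, fitness, phenotypes, position summaries
- `operon_dms.codon_features` — RCU, tRNA, GC, stalling, CAI
- `operon_dms.sd_hybridization` — anti-SD duplex energies, RBS strength
- `operon_dms.association_stats` — Mann–Whitney tests, box stats
- `operon_dms.pipeline` / `operon_dms.cli` — orchestration and `operon-dms`
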