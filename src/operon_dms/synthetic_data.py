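"""Synthetic NNK saturation libraries with known per-variant survival effects.

Emulates the structure of a single-codon saturation mutagenesis experiment on
an operonic gene: every mutagenized codon is replaced by all 32 NNK codons
(N = A/C/G/T, K = G/T), the pool carries a WT fraction (~10% in the kind of
library modelled here: NNK-borne WT plus template carryover), and selection
multiplies each variant's sampling proportion by its true survival. Both
count tables and paired FASTQ reads (with 6-base condition MID tags) can be
emitted, so the whole downstream pipeline is testable against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    NNK_CODONS,
    WT_ROW_ID,
    CountTable,
    OperonSpec,
    Variant,
    revcomp,
)

DEFAULT_MID_TAGS = {"unselected": "ACGTAC", "selected": "TGCAGT"}


@dataclass
class EffectModel:
    """Generative model for true survival effects.

    Survival is log-linear in log relative codon usage (RCU), with optional
    additive log-survival offsets for codon-index regions (e.g. a downstream
    RBS overlap) and lognormal per-variant noise. Nonsense variants, for which
    RCU is undefined, get a fixed strongly-deleterious multiplier. WT survival
    is ``baseline_survival`` exactly.
    """

    baseline_survival: float = 1.0
    rcu_coefficient: float = 0.0
    region_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    nonsense_survival: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.baseline_survival <= 0:
            raise ValueError("baseline_survival must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SimulatedLibrary:
    """Variant pool with true survivals and unselected sampling proportions."""

    spec: OperonSpec
    variants: list[Variant]
    true_survival: np.ndarray  # aligned with variants
    wt_fraction: float
    unselected_proportions: np.ndarray  # variants + WT (last entry)

    def __post_init__(self):
        if not 0 <= self.wt_fraction <= 1:
            raise ValueError("wt_fraction must lie in [0, 1]")
        if len(self.unselected_proportions) != len(self.variants) + 1:
            raise ValueError("proportions must cover all variants plus WT")
        if abs(self.unselected_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("unselected proportions must sum to 1")
        if (self.true_survival < 0).any():
            raise ValueError("true survivals must be >= 0")

    @property
    def wt_survival(self) -> float:
        return self._wt_survival

    _wt_survival: float = 1.0

    def truth_json(self, path) -> None:
        payload = {
            "wt_fraction": self.wt_fraction,
            "wt_survival": self.wt_survival,
            "variants": {
                v.variant_id: s for v, s in zip(self.variants, self.true_survival)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimConfig:
    """Sequencing-run parameters for the simulator.

    Usable read depths in the experiment modelled here were on the order of
    1e5-5e5 per replicate; the default matches the lower end.
    """

    depth_per_replicate: int = 100_000
    n_replicates: int = 3
    q_score: int = 35
    sequencing_error_rate: float = 0.0
    mid_tags: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MID_TAGS))
    seed: int = 0

    def __post_init__(self):
        if self.depth_per_replicate <= 0:
            raise ValueError("depth_per_replicate must be positive")
        if not 0 <= self.sequencing_error_rate <= 1:
            raise ValueError("sequencing_error_rate must lie in [0, 1]")
        tags = list(self.mid_tags.values())
        for t in tags:
            if len(t) != 6 or any(b not in "ACGT" for b in t):
                raise ValueError(f"MID tag {t!r} is not a 6-base ACGT string")
        if len(set(tags)) != len(tags):
            raise ValueError("MID tags must be pairwise distinct")


def enumerate_nnk_variants(spec: OperonSpec) -> list[Variant]:
    """All NNK codon substitutions at the mutagenized positions.

    Each position contributes 32 variants (including the WT-identical codon
    when the reference codon itself ends in G/T, flagged ``wt``). The only
    stop codon reachable through NNK is TAG, flagged ``nonsense``.
    """
    out: list[Variant] = []
    for pos in spec.mutagenized_positions:
        wt = spec.codon_at(pos)
        for codon in NNK_CODONS:
            out.append(Variant(pos, wt, codon))
    return out


def expected_wt_fraction(spec: OperonSpec, template_carryover: float = 0.0) -> float:
    """Expected WT fraction of the pooled library.

    NNK pools regenerate the WT codon only at positions whose reference codon
    ends in G/T (one of the 32 codons in that pool); template carryover adds a
    flat extra fraction. Positions are assumed equimolar.
    """
    if not 0 <= template_carryover < 1:
        raise ValueError("template_carryover must lie in [0, 1)")
    n_pos = len(spec.mutagenized_positions)
    if n_pos == 0:
        return template_carryover
    n_k_ending = sum(
        spec.codon_at(p)[2] in "GT" for p in spec.mutagenized_positions
    )
    return template_carryover + (1 - template_carryover) * n_k_ending / (n_pos * 32)


def assign_true_effects(
    variants: list[Variant],
    model: EffectModel,
    rcu_by_variant: dict[str, float] | None = None,
    wt_fraction: float = 0.10,
    spec: OperonSpec | None = None,
) -> SimulatedLibrary:
    """Attach true survivals to variants under the generative effect model.

    ``rcu_by_variant`` maps variant_id -> RCU; required whenever
    ``rcu_coefficient`` is nonzero. WT-identical NNK variants get the
    baseline survival (they are WT sequence).
    """
    rng = np.random.default_rng(model.seed)
    n = len(variants)
    log_s = np.full(n, math.log(model.baseline_survival))
    for i, v in enumerate(variants):
        if v.kind == "wt":
            continue
        if v.kind == "nonsense":
            log_s[i] += math.log(model.nonsense_survival)
        elif model.rcu_coefficient != 0.0:
            if rcu_by_variant is None or v.variant_id not in rcu_by_variant:
                raise ValueError(f"no RCU available for variant {v.variant_id}")
            log_s[i] += model.rcu_coefficient * math.log(rcu_by_variant[v.variant_id])
        for (lo, hi), offset in model.region_effects.items():
            if lo <= v.position <= hi:
                log_s[i] += offset
    if model.noise_sd > 0:
        noise = rng.normal(0.0, model.noise_sd, size=n)
        mask = np.array([v.kind != "wt" for v in variants])
        log_s = log_s + noise * mask
    survival = np.exp(log_s)

    props = np.full(n + 1, (1.0 - wt_fraction) / n)
    props[-1] = wt_fraction
    props /= props.sum()
    lib = SimulatedLibrary(
        spec=spec,
        variants=variants,
        true_survival=survival,
        wt_fraction=wt_fraction,
        unselected_proportions=props,
    )
    lib._wt_survival = model.baseline_survival
    return lib


def library_from_survivals(
    spec: OperonSpec,
    variants: list[Variant],
    true_survival: np.ndarray,
    wt_fraction: float = 0.10,
    wt_survival: float = 1.0,
) -> SimulatedLibrary:
    """Build a library directly from externally chosen true survivals."""
    n = len(variants)
    props = np.full(n + 1, (1.0 - wt_fraction) / n)
    props[-1] = wt_fraction
    props /= props.sum()
    lib = SimulatedLibrary(
        spec=spec,
        variants=variants,
        true_survival=np.asarray(true_survival, dtype=float),
        wt_fraction=wt_fraction,
        unselected_proportions=props,
    )
    lib._wt_survival = wt_survival
    return lib


def simulate_counts(library: SimulatedLibrary, config: SimConfig) -> CountTable:
    """Multinomial sampling of unselected and selected read counts.

    Unselected counts are multinomial at the library proportions; selection
    reweights each variant's proportion by its true survival (WT by the WT
    survival) before an independent multinomial draw. Draws are independent
    across replicates and seeded. NNK variants whose codon is the reference
    codon are WT sequence and indistinguishable by sequencing; their draws
    are folded into the WT row.
    """
    rng = np.random.default_rng(config.seed)
    pre = library.unselected_proportions
    weights = np.concatenate([library.true_survival, [library.wt_survival]])
    post = pre * weights
    if post.sum() <= 0:
        raise ValueError("selection removed the entire library")
    post = post / post.sum()

    distinct = [v for v in library.variants if v.kind != "wt"]
    keep = np.array([v.kind != "wt" for v in library.variants] + [True])
    columns = [
        (cond, rep)
        for rep in range(1, config.n_replicates + 1)
        for cond in CountTable.CONDITIONS
    ]
    table = CountTable.from_variants(distinct, columns)
    depth = config.depth_per_replicate
    for rep in range(1, config.n_replicates + 1):
        for cond, props in (("unselected", pre), ("selected", post)):
            draw = rng.multinomial(depth, props)
            col = np.concatenate([draw[:-1][keep[:-1]], [draw[-1] + draw[:-1][~keep[:-1]].sum()]])
            table.counts[(cond, rep)] = col
    return table


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(3)]
    return "".join(chars)


def emit_fastq(
    library: SimulatedLibrary,
    counts: CountTable,
    config: SimConfig,
    out_prefix,
) -> list[tuple[str, str]]:
    """Write paired FASTQ (Phred+33) for every counted molecule.

    One (R1, R2) file pair per replicate, both conditions mixed in the same
    files and distinguished only by the 6-base MID tag that starts every
    read. Forward reads are tag + gene sense strand; reverse reads are tag +
    reverse complement of the gene, so the pair overlaps over the full gene.
    Returns the list of (r1_path, r2_path) per replicate.
    """
    if library.spec is None:
        raise ValueError("library has no OperonSpec; cannot emit reads")
    rng = np.random.default_rng(config.seed + 1)
    spec = library.spec
    qual_char = chr(33 + config.q_score)
    seqs = [spec.with_variant(v) for v in library.variants] + [spec.coding_sequence]
    row_ids = [v.variant_id for v in library.variants] + [WT_ROW_ID]
    rate = config.sequencing_error_rate

    paths = []
    for rep in counts.replicates:
        r1_path = f"{out_prefix}_rep{rep}_R1.fastq"
        r2_path = f"{out_prefix}_rep{rep}_R2.fastq"
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            serial = 0
            for cond in CountTable.CONDITIONS:
                tag = config.mid_tags[cond]
                col = counts.counts[(cond, rep)]
                for row_id, template in zip(row_ids, seqs):
                    c = int(col.get(row_id, 0))
                    if c == 0:
                        continue
                    fwd = tag + template
                    rev = tag + revcomp(template)
                    qline = qual_char * len(fwd)
                    for _ in range(c):
                        serial += 1
                        rid = f"sim_rep{rep}_{serial}"
                        s1 = _apply_errors(fwd, rate, rng) if rate > 0 else fwd
                        s2 = _apply_errors(rev, rate, rng) if rate > 0 else rev
                        f1.write(f"@{rid}/1\n{s1}\n+\n{qline}\n")
                        f2.write(f"@{rid}/2\n{s2}\n+\n{qline}\n")
        paths.append((r1_path, r2_path))
    return paths


def random_gene(n_codons: int, seed: int = 0) -> str:
    """Random coding sequence: ATG start, no internal stops, ``n_codons`` codons."""
    rng = np.random.default_rng(seed)
    sense = [c for c in _all_codons() if _aa(c) != "*"]
    codons = ["ATG"]
    for _ in range(n_codons - 1):
        codons.append(sense[rng.integers(len(sense))])
    return "".join(codons)


def _all_codons():
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def _aa(codon):
    from .core import GENETIC_CODE

    return GENETIC_CODE[codon]
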