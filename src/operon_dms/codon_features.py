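"""Codon-optimality and sequence features of single-codon substitutions.

Features follow the convention "mutant relative to WT": relative codon usage
(RCU) normalizes each codon's usage fraction to its amino acid's most common
codon before taking the mutant/WT ratio; relative tRNA abundance, relative
GC content, relative ribosome stalling and relative CAI are plain
mutant-over-WT ratios; the number of base changes is the codon Hamming
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import GENETIC_CODE, load_table, translate_codon


class NonsenseCodonError(ValueError):
    """Raised when a stop codon reaches an amino-acid-normalized feature."""


def _norm_codon(codon: str) -> str:
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    return c


class UsageTable:
    """Codon usage fractions with per-amino-acid maxima.

    Accepts a mapping or TSV of codon -> usage fraction. Stop codons may be
    present but are rejected by the amino-acid-normalized operations.
    """

    def __init__(self, fractions, source: str = "user"):
        self.fractions = load_table(fractions)
        self.source = source
        for c, v in self.fractions.items():
            if v <= 0:
                raise ValueError(f"usage fraction for {c} must be positive")
        self._family_max: dict[str, float] = {}
        for c, v in self.fractions.items():
            aa = GENETIC_CODE.get(c)
            if aa is None:
                raise ValueError(f"unknown codon {c}")
            self._family_max[aa] = max(self._family_max.get(aa, 0.0), v)

    def cuf(self, codon: str) -> float:
        c = _norm_codon(codon)
        if c not in self.fractions:
            raise KeyError(f"codon {c} missing from usage table")
        return self.fractions[c]

    def family_max(self, codon: str) -> float:
        aa = translate_codon(_norm_codon(codon))
        if aa == "*":
            raise NonsenseCodonError(f"stop codon {codon}")
        return self._family_max[aa]

    def relative_adaptiveness(self, codon: str) -> float:
        """Sharp-Li weight w_c = CUF_c / max CUF within the synonymous family."""
        return self.cuf(codon) / self.family_max(codon)

    @classmethod
    def default(cls) -> "UsageTable":
        return cls(_data_path("codon_usage_ecoli_k12.tsv"), source="E. coli K-12")


class SimpleCodonTable:
    """Flat codon -> positive value table (tRNA abundance, pause values, ...)."""

    def __init__(self, values, source: str = "user"):
        self.values = load_table(values)
        self.source = source
        for c, v in self.values.items():
            if v <= 0:
                raise ValueError(f"value for {c} must be positive")

    def __getitem__(self, codon: str) -> float:
        c = _norm_codon(codon)
        if c not in self.values:
            raise KeyError(f"codon {c} missing from {self.source} table")
        return self.values[c]

    @classmethod
    def default_trna(cls) -> "SimpleCodonTable":
        return cls(_data_path("trna_abundance_synthetic.tsv"), source="synthetic tRNA")

    @classmethod
    def default_stalling(cls) -> "SimpleCodonTable":
        return cls(_data_path("ribosome_stalling_synthetic.tsv"), source="synthetic stalling")


TRNATable = SimpleCodonTable
StallTable = SimpleCodonTable


def _data_path(name: str):
    return resources.files("operon_dms.data").joinpath(name)


def rcu(wt_codon: str, mut_codon: str, table: UsageTable) -> float:
    """Relative codon usage of a substitution.

    (CUF_mut / CUF of the mutant amino acid's most common codon) divided by
    (CUF_wt / CUF of the WT amino acid's most common codon). Equals 1 for
    synonymous moves between two family-maximal codons and for wt == mut.
    """
    wt, mut = _norm_codon(wt_codon), _norm_codon(mut_codon)
    if translate_codon(wt) == "*" or translate_codon(mut) == "*":
        raise NonsenseCodonError("RCU is undefined for stop codons")
    return table.relative_adaptiveness(mut) / table.relative_adaptiveness(wt)


def relative_trna(wt_codon: str, mut_codon: str, table: SimpleCodonTable) -> float:
    """tRNA abundance of the mutant codon over the WT codon."""
    return table[mut_codon] / table[wt_codon]


def relative_stalling(wt_codon: str, mut_codon: str, table: SimpleCodonTable) -> float:
    """Ribosome pause value of the mutant codon over the WT codon."""
    return table[mut_codon] / table[wt_codon]


def gc_fraction(codon: str) -> float:
    c = _norm_codon(codon)
    return sum(b in "GC" for b in c) / 3.0


def codon_basic_features(wt_codon: str, mut_codon: str) -> tuple[float | None, int]:
    """(relative GC content, number of base changes).

    Relative GC is GC_fraction(mut)/GC_fraction(wt); None (missing) when the
    WT codon has no G/C. Base changes is the Hamming distance (0-3).
    """
    wt, mut = _norm_codon(wt_codon), _norm_codon(mut_codon)
    n_changes = sum(a != b for a, b in zip(wt, mut))
    wt_gc = gc_fraction(wt)
    rel_gc = None if wt_gc == 0 else gc_fraction(mut) / wt_gc
    return rel_gc, n_changes


def cai(coding_sequence: str, weights: UsageTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Codons from single-codon families (Met, Trp) and stop codons are excluded
    (standard Sharp-Li convention).
    """
    seq = coding_sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    log_sum = 0.0
    n = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = translate_codon(codon)
        if aa in ("*", "M", "W"):
            continue
        w = weights.relative_adaptiveness(codon)
        if w <= 0:
            raise ValueError(f"zero weight for codon {codon}")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("no CAI-informative codons in sequence")
    return math.exp(log_sum / n)


def relative_cai(mut_sequence: str, wt_sequence: str, weights: UsageTable) -> float:
    """CAI(mutant gene) / CAI(WT gene)."""
    return cai(mut_sequence, weights) / cai(wt_sequence, weights)


@dataclass
class FeatureSet:
    rcu: float | None
    rel_trna: float | None
    rel_gc: float | None
    n_base_changes: int
    rel_stall: float | None
    rel_cai: float | None
    nonsense: bool = False


def feature_table(
    records: pd.DataFrame,
    reference: str,
    usage: UsageTable | None = None,
    trna: SimpleCodonTable | None = None,
    stalling: SimpleCodonTable | None = None,
) -> pd.DataFrame:
    """Compute all features for a variant records frame (indexed by variant_id).

    ``records`` needs position / wt_codon / mut_codon / kind columns (the
    CountTable metadata or an enrichment score table both qualify).
    Nonsense variants get NaN for the amino-acid-normalized features and a
    True ``nonsense`` flag; nothing is silently dropped.
    """
    usage = usage or UsageTable.default()
    trna = trna or SimpleCodonTable.default_trna()
    stalling = stalling or SimpleCodonTable.default_stalling()
    reference = reference.upper()
    wt_cai = cai(reference, usage)

    rows = []
    for vid, rec in records.iterrows():
        wt, mut = rec["wt_codon"], rec["mut_codon"]
        nonsense = rec["kind"] == "nonsense"
        rel_gc, n_changes = codon_basic_features(wt, mut)
        if nonsense:
            r = rt = rc_ = np.nan
        else:
            r = rcu(wt, mut, usage)
            rt = relative_trna(wt, mut, trna)
            i = (int(rec["position"]) - 1) * 3
            mut_seq = reference[:i] + mut + reference[i + 3 :]
            rc_ = cai(mut_seq, usage) / wt_cai
        rows.append(
            {
                "variant_id": vid,
                "rcu": r,
                "rel_trna": rt,
                "rel_gc": np.nan if rel_gc is None else rel_gc,
                "n_base_changes": n_changes,
                "rel_stall": relative_stalling(wt, mut, stalling),
                "rel_cai": rc_,
                "nonsense": nonsense,
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")
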