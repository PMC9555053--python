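"""Shared domain types for single-codon saturation (NNK) mutagenesis analysis.

Coordinates are 1-based codon indices with codon 1 = the start codon;
intervals are closed. Substitution classes follow the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

DNA_BASES = "ACGT"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

#: the 32 NNK codons (N = A/C/G/T, K = G/T), in lexicographic order
NNK_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c for a in DNA_BASES for b in DNA_BASES for c in "GT")
)

WT_ROW_ID = "WT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


def substitution_class(wt_codon: str, mut_codon: str) -> str:
    """Classify a codon substitution relative to the reference codon.

    Returns one of ``wt`` (identical codon), ``synonymous``, ``nonsynonymous``
    or ``nonsense`` (mutation to a stop codon).
    """
    if mut_codon == wt_codon:
        return "wt"
    wt_aa = translate_codon(wt_codon)
    mut_aa = translate_codon(mut_codon)
    if mut_aa == "*":
        return "nonsense"
    return "synonymous" if mut_aa == wt_aa else "nonsynonymous"


@dataclass(frozen=True)
class Variant:
    """One single-codon substitution in the mutagenized gene."""

    position: int  # 1-based codon index
    wt_codon: str
    mut_codon: str
    kind: str = field(compare=False, default="")

    def __post_init__(self):
        if not self.kind:
            object.__setattr__(
                self, "kind", substitution_class(self.wt_codon, self.mut_codon)
            )

    @property
    def variant_id(self) -> str:
        return f"p{self.position}_{self.wt_codon}>{self.mut_codon}"

    @property
    def mut_aa(self) -> str:
        return translate_codon(self.mut_codon)

    @property
    def wt_aa(self) -> str:
        return translate_codon(self.wt_codon)


@dataclass
class OperonSpec:
    """The mutagenized upstream gene of an operon and its annotated regions.

    ``rbs_region`` marks the codon interval (closed, 1-based) that carries the
    ribosome-binding site of the downstream gene, which in compact operons can
    lie inside the upstream coding sequence (e.g. the toxin RBS inside the
    antitoxin gene at codons 70-71).
    """

    gene_id: str
    coding_sequence: str
    mutagenized_positions: list[int]
    rbs_region: tuple[int, int] | None = None
    amplicon_flanks: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.coding_sequence = self.coding_sequence.upper()
        n = len(self.coding_sequence)
        if n == 0 or n % 3 != 0:
            raise ValueError(f"coding sequence length {n} is not a multiple of 3")
        if any(b not in DNA_BASES for b in self.coding_sequence):
            raise ValueError("coding sequence contains non-ACGT characters")
        if self.coding_sequence[:3] != "ATG":
            raise ValueError("coding sequence must start with the ATG start codon")
        for p in self.mutagenized_positions:
            if not 1 <= p <= self.n_codons:
                raise ValueError(f"mutagenized position {p} outside gene (1..{self.n_codons})")
        if self.rbs_region is not None:
            lo, hi = self.rbs_region
            if not (1 <= lo <= hi <= self.n_codons):
                raise ValueError(f"rbs_region {self.rbs_region} outside gene")

    @property
    def n_codons(self) -> int:
        return len(self.coding_sequence) // 3

    def codon_at(self, position: int) -> str:
        if not 1 <= position <= self.n_codons:
            raise ValueError(f"codon position {position} outside gene (1..{self.n_codons})")
        i = (position - 1) * 3
        return self.coding_sequence[i : i + 3]

    def with_variant(self, variant: Variant) -> str:
        """Coding sequence with the variant codon substituted in."""
        if self.codon_at(variant.position) != variant.wt_codon:
            raise ValueError(
                f"variant {variant.variant_id} wt codon does not match reference"
            )
        i = (variant.position - 1) * 3
        return (
            self.coding_sequence[:i] + variant.mut_codon + self.coding_sequence[i + 3 :]
        )


class CountTable:
    """Per-variant read counts by (condition, replicate), plus one WT row.

    Wraps a wide pandas DataFrame indexed by ``variant_id`` (with a ``WT``
    row) and a variant metadata frame. Column totals are the spec's
    "total # of reads": all single mutants plus WT identified in a sample.
    """

    CONDITIONS = ("unselected", "selected")

    def __init__(self, counts: pd.DataFrame, variants: pd.DataFrame):
        if WT_ROW_ID not in counts.index:
            raise ValueError("count table must contain a WT row")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = counts
        self.variants = variants  # index variant_id; columns position, wt_codon, mut_codon, kind

    @classmethod
    def from_variants(
        cls, variants: Iterable[Variant], columns: Iterable[tuple[str, int]]
    ) -> "CountTable":
        meta = variants_frame(variants)
        idx = list(meta.index) + [WT_ROW_ID]
        cols = pd.MultiIndex.from_tuples(list(columns), names=["condition", "replicate"])
        counts = pd.DataFrame(0, index=idx, columns=cols)
        return cls(counts, meta)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def replicates(self) -> list[int]:
        return sorted({r for _, r in self.counts.columns})

    def to_long(self) -> pd.DataFrame:
        """Long-format table: variant_id, position, wt_codon, mut_codon, condition, replicate, count."""
        long = (
            self.counts.stack(["condition", "replicate"], future_stack=True)
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "variant_id"})
        )
        meta = self.variants.reindex(long["variant_id"])
        long["position"] = pd.array(meta["position"].to_numpy(), dtype="Int64")
        long["wt_codon"] = meta["wt_codon"].to_numpy()
        long["mut_codon"] = meta["mut_codon"].to_numpy()
        return long[
            ["variant_id", "position", "wt_codon", "mut_codon", "condition", "replicate", "count"]
        ]

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        long = pd.read_csv(path, sep="\t", dtype={"wt_codon": str, "mut_codon": str})
        return cls.from_long(long)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CountTable":
        counts = long.pivot_table(
            index="variant_id",
            columns=["condition", "replicate"],
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        meta = (
            long[long["variant_id"] != WT_ROW_ID]
            .drop_duplicates("variant_id")
            .set_index("variant_id")[["position", "wt_codon", "mut_codon"]]
        )
        meta["position"] = meta["position"].astype(int)
        meta["kind"] = [
            substitution_class(w, m) for w, m in zip(meta["wt_codon"], meta["mut_codon"])
        ]
        # keep variant rows first, WT last, for stable output ordering
        order = [i for i in counts.index if i != WT_ROW_ID] + [WT_ROW_ID]
        return cls(counts.loc[order], meta)

    def equals(self, other: "CountTable") -> bool:
        """Count-for-count equality; rows absent from one table count as zero."""
        idx = self.counts.index.union(other.counts.index)
        cols = self.counts.columns.union(other.counts.columns)
        a = self.counts.reindex(index=idx, columns=cols, fill_value=0)
        b = other.counts.reindex(index=idx, columns=cols, fill_value=0)
        return bool((a.to_numpy() == b.to_numpy()).all())


def variants_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    rows = [
        (v.variant_id, v.position, v.wt_codon, v.mut_codon, v.kind) for v in variants
    ]
    return pd.DataFrame(
        rows, columns=["variant_id", "position", "wt_codon", "mut_codon", "kind"]
    ).set_index("variant_id")


def read_fasta_sequence(path) -> tuple[str, str]:
    """First record of a FASTA file as (id, uppercase sequence)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def load_table(path_or_mapping, value_col: str = "value") -> dict[str, float]:
    """Load a codon->value TSV (columns: codon, value[, amino_acid]) or pass a mapping through."""
    if isinstance(path_or_mapping, Mapping):
        return {str(k).upper().replace("U", "T"): float(v) for k, v in path_or_mapping.items()}
    df = pd.read_csv(path_or_mapping, sep="\t", comment="#")
    col = value_col if value_col in df.columns else df.columns[1]
    return {
        str(c).upper().replace("U", "T"): float(v) for c, v in zip(df["codon"], df[col])
    }
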