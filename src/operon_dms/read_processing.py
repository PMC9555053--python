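"""Paired-end amplicon reads -> single-codon-variant count table.

The processing contract mirrors a conservative amplicon DMS workflow:
demultiplex on exact 6-base MID tags, drop low-quality or short reads, merge
pairs only when the overlap is base-identical, align to the reference coding
sequence (Smith-Waterman, affine gaps), and keep only full-coverage, gapless
reads that differ from the reference in at most one codon. A Poisson model of
Phred sequencing error gives the minimum read count at which a single-base
variant cannot be explained by sequencing error alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.stats import norm, poisson

from .core import CountTable, Variant, revcomp, variants_frame, WT_ROW_ID

MID_LENGTH = 6
MIN_OVERLAP = 10

REJECT_INDEL = "indel"
REJECT_MULTI = "multi_codon"
REJECT_PARTIAL = "partial_coverage"
REJECT_AMBIG = "ambiguous_base"


@dataclass
class SequencingRead:
    id: str
    sequence: str
    qualities: list[int]
    mate: int = 1

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities length mismatch")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0


@dataclass
class VariantCall:
    """Outcome of calling one merged read: a variant, WT, or a rejection."""

    variant: Variant | None = None
    is_wt: bool = False
    rejection: str | None = None

    def __post_init__(self):
        n_set = sum([self.variant is not None, self.is_wt, self.rejection is not None])
        if n_set != 1:
            raise ValueError("exactly one of variant / WT / rejection must be set")


# ---------------------------------------------------------------------------
# demultiplexing and filtering


def demultiplex(
    reads: Iterable[SequencingRead], mid_map: dict[str, str]
) -> dict[str, list[SequencingRead]]:
    """Bin reads by exact MID-tag match on their first 6 bases.

    The matched tag is stripped from sequence and qualities. Reads whose
    prefix matches no tag go to the ``unassigned`` bin untouched.
    """
    tag_to_condition = _invert_mid_map(mid_map)
    bins: dict[str, list[SequencingRead]] = {c: [] for c in mid_map}
    bins["unassigned"] = []
    for read in reads:
        cond = tag_to_condition.get(read.sequence[:MID_LENGTH])
        if cond is None:
            bins["unassigned"].append(read)
        else:
            bins[cond].append(
                SequencingRead(
                    read.id,
                    read.sequence[MID_LENGTH:],
                    read.qualities[MID_LENGTH:],
                    read.mate,
                )
            )
    return bins


def _invert_mid_map(mid_map: dict[str, str]) -> dict[str, str]:
    inv: dict[str, str] = {}
    for cond, tag in mid_map.items():
        if tag in inv:
            raise ValueError(f"duplicate MID tag {tag!r}")
        inv[tag] = cond
    return inv


def quality_filter(
    read: SequencingRead, q_cutoff: float = 20, min_length: int = 75, per_base: bool = False
) -> tuple[bool, str | None]:
    """Keep/drop decision with reason.

    Default convention: drop when mean Phred < ``q_cutoff`` or length <
    ``min_length``. ``per_base=True`` instead requires every base to reach
    the cutoff.
    """
    if len(read.sequence) < min_length:
        return False, "length"
    if per_base:
        ok = min(read.qualities) >= q_cutoff
    else:
        ok = read.mean_quality >= q_cutoff
    return (True, None) if ok else (False, "quality")


def merge_pair(fwd: SequencingRead, rev: SequencingRead) -> str | None:
    """Merge a pair when the overlap is base-identical; otherwise None.

    The reverse read is reverse-complemented, then the maximal exact overlap
    (>= 10 nt) between the forward read's suffix and the reverse-complemented
    read's prefix is sought. Any mismatch in a candidate overlap disqualifies
    that overlap length; if no exact overlap exists the pair is rejected.
    """
    rc = revcomp(rev.sequence)
    f = fwd.sequence
    max_l = min(len(f), len(rc))
    for overlap in range(max_l, MIN_OVERLAP - 1, -1):
        if f[len(f) - overlap :] == rc[:overlap]:
            return f + rc[overlap:]
    return None


# ---------------------------------------------------------------------------
# alignment and variant calling

#: EDNAFULL-equivalent scores with the gap opening penalty raised to 20.
#: A gap of length L costs open + (L-1) * extend.
ALIGN_MATCH = 5
ALIGN_MISMATCH = -4
ALIGN_GAP_OPEN = 20.0
ALIGN_GAP_EXTEND = 0.5


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = ALIGN_MATCH
    aligner.mismatch_score = ALIGN_MISMATCH
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_read(
    read_sequence: str,
    reference: str,
    gap_open: float = ALIGN_GAP_OPEN,
    gap_extend: float = ALIGN_GAP_EXTEND,
) -> Align.Alignment:
    """Smith-Waterman local alignment of a read against the reference."""
    if not read_sequence or not reference:
        raise ValueError("empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    return aligner.align(reference, read_sequence)[0]


def call_variant(alignment: Align.Alignment, reference: str) -> VariantCall:
    """Interpret an alignment as a single-codon variant call.

    Rejects reads that do not span the full reference (partial_coverage),
    contain any gap (indel), differ in more than one codon (multi_codon), or
    carry an N inside a differing codon (ambiguous_base).
    """
    blocks_ref, blocks_read = alignment.aligned
    if len(blocks_ref) != 1:
        return VariantCall(rejection=REJECT_INDEL)
    (r0, r1), (q0, q1) = blocks_ref[0], blocks_read[0]
    if r0 != 0 or r1 != len(reference):
        return VariantCall(rejection=REJECT_PARTIAL)
    read_aln = alignment.query[q0:q1] if hasattr(alignment, "query") else None
    return _call_from_equal_length(str(read_aln), reference)


def _call_from_equal_length(read_seq: str, reference: str) -> VariantCall:
    """Codon-wise comparison for a read segment spanning the full reference."""
    if read_seq == reference:
        return VariantCall(is_wt=True)
    diff_codons = sorted(
        {i // 3 for i, (a, b) in enumerate(zip(read_seq, reference)) if a != b}
    )
    if len(diff_codons) > 1:
        return VariantCall(rejection=REJECT_MULTI)
    ci = diff_codons[0]
    mut = read_seq[ci * 3 : ci * 3 + 3]
    if "N" in mut:
        return VariantCall(rejection=REJECT_AMBIG)
    wt = reference[ci * 3 : ci * 3 + 3]
    return VariantCall(variant=Variant(ci + 1, wt, mut))


def tally_counts(calls: Iterable[VariantCall]) -> tuple[Counter, int, Counter]:
    """Counts per variant_id plus WT from one (condition, replicate).

    Returns (variant counts incl. WT row, total retained, rejection reasons).
    Rejected calls are excluded from counts and totals.
    """
    counts: Counter = Counter()
    rejects: Counter = Counter()
    total = 0
    for call in calls:
        if call.rejection is not None:
            rejects[call.rejection] += 1
        elif call.is_wt:
            counts[WT_ROW_ID] += 1
            total += 1
        else:
            counts[call.variant.variant_id] += 1
            total += 1
    return counts, total, rejects


# ---------------------------------------------------------------------------
# sequencing-error thresholds


def phred_error_prob(q: float, n_alternatives: int = 4) -> tuple[float, float]:
    """(per-base error probability, per-specific-substitution probability).

    Per-base error is 10^(-q/10). The per-substitution probability divides by
    ``n_alternatives`` (default 4: the convention that all four bases are
    equally likely to be assigned in error; pass 3 to count only the three
    non-reference bases).
    """
    if q < 0:
        raise ValueError("Phred score must be nonnegative")
    per_base = 10.0 ** (-q / 10.0)
    return per_base, per_base / n_alternatives


def min_reads_threshold(
    total_reads: int,
    q: float = 35,
    alpha: float = 0.05,
    convention: str = "poisson_gt",
    n_alternatives: int = 4,
) -> int:
    """Minimum reads for a specific single-base variant to exceed sequencing error.

    The count of a specific erroneous substitution among ``total_reads`` reads
    is modelled as Poisson with rate lambda = total_reads * per-substitution
    error probability. Conventions:

    - ``poisson_gt``: smallest k with P(X > k) < alpha
    - ``poisson_ge``: smallest k with P(X >= k) < alpha
    - ``normal``: smallest k with the upper normal-approximation tail < alpha
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    _, p_sub = phred_error_prob(q, n_alternatives)
    lam = total_reads * p_sub
    return _poisson_min_count(lam, alpha, convention)


def _poisson_min_count(lam: float, alpha: float, convention: str) -> int:
    if convention not in ("poisson_gt", "poisson_ge", "normal"):
        raise ValueError(f"unknown convention {convention!r}")
    k = 0
    while True:
        if convention == "poisson_gt":
            tail = poisson.sf(k, lam)
        elif convention == "poisson_ge":
            tail = poisson.sf(k - 1, lam)
        else:
            tail = norm.sf((k - lam) / np.sqrt(lam))
        if tail < alpha:
            return k
        k += 1
        if k > 100 * (lam + 10):  # pragma: no cover - safety valve
            raise RuntimeError("threshold search failed to converge")


# ---------------------------------------------------------------------------
# high-level FASTQ -> CountTable driver


def _fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str, str, str]]:
    with open(r1_path) as f1, open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (id1, s1, q1), (_id2, s2, q2) in zip(it1, it2):
            yield id1, s1, q1, s2, q2


def _mean_phred(qual_string: str) -> float:
    return sum(qual_string.encode()) / len(qual_string) - 33.0


class PairProcessor:
    """Stateful processor for one replicate's paired FASTQ files.

    Calls are memoized by merged sequence; reads whose merged length equals
    the reference length take a direct codon-comparison path (equivalent to
    align+call for gapless full-coverage reads), others go through
    Smith-Waterman alignment.
    """

    def __init__(
        self,
        reference: str,
        mid_map: dict[str, str],
        q_cutoff: float = 20,
        min_length: int = 75,
        gap_open: float = ALIGN_GAP_OPEN,
        gap_extend: float = ALIGN_GAP_EXTEND,
        per_base_quality: bool = False,
    ):
        self.reference = reference.upper()
        self.tag_to_condition = _invert_mid_map(mid_map)
        self.conditions = list(mid_map)
        self.q_cutoff = q_cutoff
        self.min_length = min_length
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.per_base_quality = per_base_quality
        self._call_cache: dict[str, VariantCall] = {}
        # per condition: Counter of variant_id -> count
        self.counts: dict[str, Counter] = {c: Counter() for c in self.conditions}
        self.fates: Counter = Counter()  # read-pair fates, conservation check
        self.rejections: Counter = Counter()

    def _call(self, merged: str) -> VariantCall:
        call = self._call_cache.get(merged)
        if call is None:
            if len(merged) == len(self.reference):
                call = _call_from_equal_length(merged, self.reference)
            else:
                aln = align_read(merged, self.reference, self.gap_open, self.gap_extend)
                call = call_variant(aln, self.reference)
            self._call_cache[merged] = call
        return call

    def process_pair(self, s1: str, q1: str, s2: str, q2: str) -> None:
        tag1 = s1[:MID_LENGTH]
        cond = self.tag_to_condition.get(tag1)
        if cond is None or s2[:MID_LENGTH] != tag1:
            self.fates["unassigned"] += 1
            return
        s1, q1 = s1[MID_LENGTH:], q1[MID_LENGTH:]
        s2, q2 = s2[MID_LENGTH:], q2[MID_LENGTH:]
        for s, q in ((s1, q1), (s2, q2)):
            if len(s) < self.min_length:
                self.fates["filtered_length"] += 1
                return
            if self.per_base_quality:
                ok = min(q.encode()) - 33 >= self.q_cutoff
            else:
                ok = _mean_phred(q) >= self.q_cutoff
            if not ok:
                self.fates["filtered_quality"] += 1
                return
        merged = self._merge_strings(s1, s2)
        if merged is None:
            self.fates["merge_rejected"] += 1
            return
        call = self._call(merged)
        if call.rejection is not None:
            self.fates["rejected"] += 1
            self.rejections[call.rejection] += 1
            return
        row = WT_ROW_ID if call.is_wt else call.variant.variant_id
        self.counts[cond][row] += 1
        self.fates["counted"] += 1

    @staticmethod
    def _merge_strings(f: str, rc_source: str) -> str | None:
        rc = revcomp(rc_source)
        if f == rc:  # full-length overlap fast path
            return f
        max_l = min(len(f), len(rc))
        for overlap in range(max_l, MIN_OVERLAP - 1, -1):
            if f[len(f) - overlap :] == rc[:overlap]:
                return f + rc[overlap:]
        return None

    def run(self, r1_path, r2_path) -> None:
        for _rid, s1, q1, s2, q2 in _fastq_pairs(r1_path, r2_path):
            self.process_pair(s1, q1, s2, q2)


def process_replicates(
    fastq_pairs: list[tuple[str, str]],
    reference: str,
    mid_map: dict[str, str],
    **kwargs,
) -> tuple[CountTable, "pd.DataFrame"]:
    """Process one (R1, R2) file pair per replicate into a CountTable.

    Returns the count table and a rejection/fate summary frame
    (replicate, reason, count).
    """
    import pandas as pd

    processors = []
    for r1, r2 in fastq_pairs:
        proc = PairProcessor(reference, mid_map, **kwargs)
        proc.run(r1, r2)
        processors.append(proc)

    variant_ids: set[str] = set()
    for proc in processors:
        for cond in proc.conditions:
            variant_ids.update(k for k in proc.counts[cond] if k != WT_ROW_ID)

    variants = []
    ref = reference.upper()
    for vid in sorted(variant_ids):
        pos_part, change = vid[1:].split("_")
        wt, mut = change.split(">")
        variants.append(Variant(int(pos_part), wt, mut))
    columns = [
        (cond, rep)
        for rep in range(1, len(processors) + 1)
        for cond in CountTable.CONDITIONS
    ]
    table = CountTable.from_variants(variants, columns)
    for rep, proc in enumerate(processors, start=1):
        for cond in proc.conditions:
            col = (cond, rep)
            for row, c in proc.counts[cond].items():
                table.counts.loc[row, col] = c

    rows = []
    for rep, proc in enumerate(processors, start=1):
        for reason, c in sorted(proc.fates.items()):
            rows.append((rep, reason, c))
        for reason, c in sorted(proc.rejections.items()):
            rows.append((rep, f"reject_{reason}", c))
    summary = pd.DataFrame(rows, columns=["replicate", "reason", "count"])
    return table, summary
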