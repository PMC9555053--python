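"""Anti-Shine-Dalgarno hybridization energies of mRNA windows.

Scores 8-nt mRNA windows against the 16S rRNA anti-SD tail
(5' CCUCCUAU 3') with a transparent nearest-neighbor RNA/RNA duplex model:
the best contiguous complementary run (Watson-Crick or G-U wobble, best
registration over all antiparallel offsets) pays one duplex-initiation
penalty plus the sum of its stack free energies. Windows with no
complementary stretch of at least two pairs score 0 (no stable duplex).

Used for two scans: internal SD-like pause-site creation around a mutated
codon (ten 8-nt windows overlapping the codon), and the strength of a
downstream gene's RBS that overlaps the mutagenized coding sequence. The
model preserves rankings of complementarity changes; it is not a
full secondary-structure ensemble. A user-supplied callable can replace the
energy backend (e.g. to plug in ViennaRNA duplex energies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .core import Variant

ASD_SEQUENCE = "CCUCCUAU"
WINDOW_SIZE = 8

_WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def transcribe(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class NNParams:
    """Nearest-neighbor stack table plus initiation penalty (kcal/mol)."""

    stacks: dict[str, float]
    wobble_stack: float
    initiation: float

    @classmethod
    def default(cls) -> "NNParams":
        path = resources.files("operon_dms.data").joinpath("rna_duplex_stacks.tsv")
        df = pd.read_csv(path, sep="\t", comment="#")
        values = dict(zip(df["key"], df["value"].astype(float)))
        wobble = values.pop("wobble_stack")
        init = values.pop("initiation")
        stacks = {k: v for k, v in values.items()}
        return cls(stacks=stacks, wobble_stack=wobble, initiation=init)

    def stack_energy(self, top: str, bottom: str) -> float:
        """Energy of one stack: top 5'->3' dinucleotide over bottom 3'->5'."""
        if any(_pair_type(t, b) == "wobble" for t, b in zip(top, bottom)):
            return self.wobble_stack
        key = f"{top}/{bottom}"
        if key in self.stacks:
            return self.stacks[key]
        sym = f"{bottom[::-1]}/{top[::-1]}"
        if sym in self.stacks:
            return self.stacks[sym]
        raise KeyError(f"no stack parameters for {key}")


def _pair_type(a: str, b: str) -> str | None:
    if (a, b) in _WC_PAIRS:
        return "wc"
    if (a, b) in _WOBBLE_PAIRS:
        return "wobble"
    return None


def duplex_dg(
    window: str, asd: str = ASD_SEQUENCE, params: NNParams | None = None
) -> float:
    """Minimum duplex free energy of an 8-nt window against the anti-SD.

    Scans all antiparallel registrations; within each, every maximal
    contiguous complementary run of >= 2 pairs is scored as initiation +
    stack sum, and the most negative run wins. Returns 0.0 when no run
    achieves a negative free energy.
    """
    w = transcribe(window)
    if len(w) != WINDOW_SIZE:
        raise ValueError(f"window must be {WINDOW_SIZE} nt, got {len(w)}")
    return _best_duplex(w, transcribe(asd), params or NNParams.default())


def _best_duplex(top: str, asd: str, params: NNParams) -> float:
    bottom = asd[::-1]  # now 3'->5' left to right under the top strand
    best = 0.0
    n, m = len(top), len(bottom)
    for shift in range(-(m - 1), n):
        # top[i] pairs bottom[i - shift]
        run: list[int] = []
        for i in range(max(0, shift), min(n, m + shift) + 1):
            paired = (
                i < min(n, m + shift)
                and _pair_type(top[i], bottom[i - shift]) is not None
            )
            if paired:
                run.append(i)
            else:
                if len(run) >= 2:
                    e = params.initiation
                    for a in run[:-1]:
                        e += params.stack_energy(
                            top[a : a + 2], bottom[a - shift : a - shift + 2]
                        )
                    best = min(best, e)
                run = []
    return best


@dataclass
class HybridResult:
    """Per-window duplex energies for WT and mutant, and their mean difference."""

    window_starts: list[int]  # 1-based nt on the transcript
    dg_wt: list[float]
    dg_mut: list[float]
    mean_ddg: float = field(init=False)

    def __post_init__(self):
        ddg = np.array(self.dg_mut) - np.array(self.dg_wt)
        self.mean_ddg = float(ddg.mean())

    @property
    def ddg(self) -> list[float]:
        return [m - w for m, w in zip(self.dg_mut, self.dg_wt)]


def asd_scan(
    transcript: str,
    codon_position: int,
    wt_codon: str,
    mut_codon: str,
    asd: str = ASD_SEQUENCE,
    params: NNParams | None = None,
    energy_fn: Callable[[str], float] | None = None,
) -> HybridResult:
    """Anti-SD energies of the ten 8-nt windows overlapping a mutated codon.

    The transcript's first nt is codon 1, base 1. Window starts run from 7 nt
    left of the codon to 2 nt into it (the ten 8-nt windows that intersect a
    3-nt codon). Requires >= 7 nt flanking context on each side.
    """
    t = transcribe(transcript)
    c0 = (codon_position - 1) * 3  # 0-based
    if t[c0 : c0 + 3] != transcribe(wt_codon):
        raise ValueError(
            f"transcript codon {codon_position} is {t[c0:c0+3]}, expected {wt_codon}"
        )
    first = c0 - (WINDOW_SIZE - 1)
    last = c0 + 2
    if first < 0 or last + WINDOW_SIZE > len(t):
        raise ValueError(
            f"codon {codon_position} lacks the 7-nt flanking context for the scan"
        )
    mut_t = t[:c0] + transcribe(mut_codon) + t[c0 + 3 :]
    fn = energy_fn or (lambda w: duplex_dg(w, asd, params))
    starts = list(range(first, last + 1))
    dg_wt = [fn(t[s : s + WINDOW_SIZE]) for s in starts]
    dg_mut = [fn(mut_t[s : s + WINDOW_SIZE]) for s in starts]
    return HybridResult([s + 1 for s in starts], dg_wt, dg_mut)


def rbs_strength(
    transcript: str,
    rbs_codons: tuple[int, int],
    variant: Variant | None = None,
    flank_nt: int = 3,
    asd: str = ASD_SEQUENCE,
    params: NNParams | None = None,
) -> float:
    """Binding free energy of a downstream gene's RBS region to the anti-SD.

    ``rbs_codons`` is the closed 1-based codon interval of the upstream gene
    that carries the RBS; the scanned span is that interval extended by
    ``flank_nt`` on each side. Returns the most negative 8-nt window energy
    (more negative = stronger predicted translation initiation). If a variant
    is given it must fall inside the RBS codon interval and is substituted
    into the transcript first.
    """
    t = transcribe(transcript)
    lo, hi = rbs_codons
    if variant is not None:
        if not lo <= variant.position <= hi:
            raise ValueError(
                f"variant at codon {variant.position} lies outside RBS codons {rbs_codons}"
            )
        c0 = (variant.position - 1) * 3
        if t[c0 : c0 + 3] != transcribe(variant.wt_codon):
            raise ValueError("variant wt codon does not match transcript")
        t = t[:c0] + transcribe(variant.mut_codon) + t[c0 + 3 :]
    span_lo = max(0, (lo - 1) * 3 - flank_nt)
    span_hi = min(len(t), hi * 3 + flank_nt)
    if span_hi - span_lo < WINDOW_SIZE:
        raise ValueError("RBS span shorter than one 8-nt window")
    fn = lambda w: duplex_dg(w, asd, params)  # noqa: E731
    return min(fn(t[s : s + WINDOW_SIZE]) for s in range(span_lo, span_hi - WINDOW_SIZE + 1))
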