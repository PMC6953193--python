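"""Molecular-clock computations.

Jukes-Cantor corrected distances, Nei-Gojobori (1986) Ka/Ks on codon
alignments, ortholog divergence times from mean Ks, and LTR retrotransposon
insertion ages from the divergence of an element's two LTRs
(T = K / (2 r), both LTRs being identical at insertion).

NG86 counts synonymous/non-synonymous sites per codon as the fraction of
one-step changes that are synonymous (changes to stop codons count as
non-synonymous), averages difference counts over all minimal mutational
pathways between differing codons with equal weight (pathways through stop
codons are excluded; if every pathway is excluded the exclusion is waived),
and applies the Jukes-Cantor-style correction to the raw proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import edlib

from .io import WildcompError

_CODON_TABLE: dict[str, str] = {}


def _build_code() -> None:
    bases = "TCAG"
    aa = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    for i, (a, b, c) in enumerate(itertools.product(bases, bases, bases)):
        _CODON_TABLE[a + b + c] = aa[i]


_build_code()
SENSE_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a != "*")


class SaturationError(WildcompError):
    """Corrected distance diverges (p beyond the JC69 domain)."""


class CodonAlignmentError(WildcompError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """Two equal-length, in-frame, gap-free coding sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise CodonAlignmentError("sequences differ in length")
        if len(a) == 0 or len(a) % 3:
            raise CodonAlignmentError("length must be a positive codon multiple")
        if not (set(a) <= set("ACGT") and set(b) <= set("ACGT")):
            raise CodonAlignmentError("alphabet must be {A,C,G,T}")
        for seq in (a, b):
            for i in range(0, len(seq) - 3, 3):  # terminal stop tolerated
                if _CODON_TABLE[seq[i : i + 3]] == "*":
                    raise CodonAlignmentError(f"in-frame stop at codon {i // 3}")

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass(frozen=True)
class ClockEstimate:
    """A substitution distance with its clock rate and derived age."""

    distance: float  # substitutions per site (K or Ks)
    rate: float  # substitutions per site per year
    time_mya: float
    p_distance: float | None = None
    saturated: bool = False


def jc69_distance(p: float) -> float:
    """JC69 correction K = -(3/4) ln(1 - 4p/3) of a raw p-distance."""
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond JC69 saturation (0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon."""
    syn = 0.0
    aa = _CODON_TABLE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mut] == aa and _CODON_TABLE[mut] != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Mean (synonymous, non-synonymous) differences over minimal pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                blocked = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur] and _CODON_TABLE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in results if not b]
    if not open_paths:  # all pathways pass a stop: waive the exclusion
        open_paths = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


class NG86Counts(NamedTuple):
    """Raw NG86 site and difference counts before any correction."""

    S: float  # synonymous sites (averaged between sequences)
    N: float  # non-synonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float  # non-synonymous differences

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0


def ng86_counts(aln: CodonAlignment) -> NG86Counts:
    """Site and difference counts of the NG86 method for one alignment."""
    S = N = Sd = Nd = 0.0
    for ca, cb in aln.codons():
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            continue  # tolerated terminal stop contributes nothing
        sa, na = _site_fractions(ca)
        sb, nb = _site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if S + N <= 0:
        raise CodonAlignmentError("no countable sites")
    return NG86Counts(S, N, Sd, Nd)


def ng86_kaks(aln: CodonAlignment) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) (Ka, Ks, Ka/Ks) for a codon alignment.

    The ratio is ``None`` (flagged) when Ks is zero; saturation of either
    proportion raises :class:`SaturationError`.
    """
    counts = ng86_counts(aln)
    ks = jc69_distance(counts.ps)
    ka = jc69_distance(counts.pn)
    return ka, ks, (ka / ks if ks > 0 else None)


def divergence_time(mean_ks: float, rate: float = 6.5e-9) -> float:
    """Divergence time in MYA from mean Ks: T = Ks / (2 r)."""
    if mean_ks < 0:
        raise ValueError("mean Ks must be non-negative")
    return mean_ks / (2.0 * rate) / 1e6


def _global_p_distance(a: str, b: str) -> tuple[float, int]:
    """p-distance over aligned non-gap columns of a global alignment.

    Equal-length sequences are compared column-wise (the optimal global
    alignment whenever gaps cost more than mismatches, and exact for
    substitution-only divergence); unequal lengths fall back to an
    edit-distance alignment, whose unit gap cost can trade mismatches for
    gap shifts in repeats and slightly deflate p.
    """
    if len(a) == len(b):
        if not a:
            raise SaturationError("no aligned columns")
        mm = sum(x != y for x, y in zip(a, b))
        return mm / len(a), len(a)
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    aligned = mismatch = 0
    for x, y in zip(qa, ta):
        if x == "-" or y == "-":
            continue
        aligned += 1
        mismatch += x != y
    if aligned == 0:
        raise SaturationError("no aligned columns")
    return mismatch / aligned, aligned


def ltr_insertion_time(ltr5: str, ltr3: str, rate: float = 1.3e-8) -> ClockEstimate:
    """Insertion age of an LTR element from its two LTRs, T = K / (2 r).

    The LTRs are globally aligned; the p-distance over aligned non-gap
    columns is JC69-corrected to K.  A saturated pair (p >= 0.75) is
    returned flagged rather than raising, since real LTR surveys contain
    ancient elements.
    """
    p, _ = _global_p_distance(ltr5.upper(), ltr3.upper())
    try:
        k = jc69_distance(p)
    except SaturationError:
        return ClockEstimate(math.inf, rate, math.inf, p_distance=p, saturated=True)
    return ClockEstimate(k, rate, k / (2.0 * rate) / 1e6, p_distance=p)
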