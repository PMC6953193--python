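"""Pairwise sequence comparison primitives.

A seed-and-extend local aligner (exact k-mer seeds, banded Smith-Waterman
extension with linear gap costs) reports identity over aligned columns and
coverage over the query, the two decision quantities used throughout the
pipeline: cDNA-to-genome placement at the 80%/50% identity/coverage gate,
all-vs-all homolog-pair detection feeding synteny, and the organelle
contamination QC.  Within its band the extension is an exact dynamic
program, so on substitution-dominated inputs the reported score matches the
full quadratic Smith-Waterman optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, WildcompError, revcomp

_NEG = -(10**9)
_NUCLEOTIDES = set("ACGTN")
_AMINO = set("ACDEFGHIKLMNPQRSTVWYXBZU*")


class AlignmentInputError(WildcompError):
    pass


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment; spans are 0-based half-open, strand of the query."""

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    score: int
    identity: float
    coverage: float

    def __post_init__(self):
        assert 0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0
        assert self.query_span[1] >= self.query_span[0]
        assert self.target_span[1] >= self.target_span[0]


def _validate(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{name}: empty sequence")
    seq = seq.upper()
    chars = set(seq)
    if not (chars <= _NUCLEOTIDES or chars <= _AMINO):
        raise AlignmentInputError(f"{name}: invalid alphabet {sorted(chars - _AMINO)}")
    return seq


def is_nucleotide(seq: str) -> bool:
    return set(seq.upper()) <= _NUCLEOTIDES


class SeedIndex:
    """Exact k-mer position index over one target sequence."""

    def __init__(self, target: str, k: int):
        self.target = target
        self.k = k
        index: dict[str, list[int]] = {}
        ambiguous = "N" if is_nucleotide(target) else "X"
        for pos in range(len(target) - k + 1):
            kmer = target[pos : pos + k]
            if ambiguous in kmer:
                continue
            index.setdefault(kmer, []).append(pos)
        self._index = index

    def seed_diagonals(self, query: str) -> np.ndarray:
        """Sorted unique diagonals (tpos - qpos) with at least one exact seed."""
        k = self.k
        ambiguous = "N" if is_nucleotide(query) else "X"
        diags = set()
        for qpos in range(len(query) - k + 1):
            kmer = query[qpos : qpos + k]
            if ambiguous in kmer:
                continue
            for tpos in self._index.get(kmer, ()):
                diags.add(tpos - qpos)
        return np.array(sorted(diags), dtype=np.int64)


def _score_row(q_char: int, t_codes: np.ndarray, scoring: Scoring, amb: int) -> np.ndarray:
    s = np.where(t_codes == q_char, scoring.match, scoring.mismatch)
    if q_char == amb:
        s[:] = scoring.mismatch
    else:
        s[t_codes == amb] = scoring.mismatch
    return s


def _banded_sw(
    q: str, t: str, d_lo: int, d_hi: int, scoring: Scoring
) -> tuple[int, np.ndarray] | None:
    """Banded Smith-Waterman over diagonals [d_lo, d_hi]; returns (best, H).

    H[i, k] is the best local score of an alignment ending at query prefix i
    and target prefix j = i + d_lo + k; the in-row (gap-in-query) dependency
    is resolved with a prefix-max scan, which is exact for linear gaps.
    """
    m, n = len(q), len(t)
    d_lo = max(d_lo, -m)
    d_hi = min(d_hi, n)
    if d_hi < d_lo:
        return None
    W = d_hi - d_lo + 1
    qc = np.frombuffer(q.encode(), dtype=np.uint8).astype(np.int16)
    tc = np.frombuffer(t.encode(), dtype=np.uint8).astype(np.int16)
    amb = ord("N") if is_nucleotide(q) and is_nucleotide(t) else ord("X")
    gap = scoring.gap
    ks = np.arange(W)
    H = np.full((m + 1, W), _NEG, dtype=np.int64)
    j0 = d_lo + ks
    H[0, (j0 >= 0) & (j0 <= n)] = 0
    for i in range(1, m + 1):
        j = i + d_lo + ks
        valid = (j >= 0) & (j <= n)
        prev = H[i - 1]
        # diagonal move: consumes q[i-1] and t[j-1]
        s = np.full(W, _NEG, dtype=np.int64)
        has_t = j >= 1
        tj = np.where(has_t, j - 1, 0)
        srow = _score_row(int(qc[i - 1]), tc[np.clip(tj, 0, n - 1)], scoring, amb)
        diag = np.where(has_t & (prev > _NEG // 2), prev + srow, _NEG)
        # up move: gap in target (consumes q[i-1]) comes from k+1 of row i-1
        up = np.full(W, _NEG, dtype=np.int64)
        up[:-1] = np.where(prev[1:] > _NEG // 2, prev[1:] + gap, _NEG)
        cand = np.maximum(np.maximum(diag, up), 0)
        cand[~valid] = _NEG
        # left moves within the row: prefix-max of cand[k'] - gap*k'
        run = np.maximum.accumulate(cand - gap * ks)
        row = np.maximum(cand, run + gap * ks)
        row[~valid] = _NEG
        H[i] = row
    best = int(H.max())
    return best, H


def _traceback(
    q: str, t: str, H: np.ndarray, d_lo: int, scoring: Scoring
) -> tuple[int, int, int, int, int, int]:
    """Walk back from the best cell; returns (qs, qe, ts, te, matches, cols)."""
    m, n = len(q), len(t)
    amb = "N" if is_nucleotide(q) and is_nucleotide(t) else "X"
    i, k = np.unravel_index(int(np.argmax(H)), H.shape)
    i, k = int(i), int(k)
    j = i + d_lo + k
    qe, te = i, j
    matches = cols = 0
    gap = scoring.gap
    while H[i, k] > 0:
        val = H[i, k]
        j = i + d_lo + k
        if i >= 1 and j >= 1:
            qch, tch = q[i - 1], t[j - 1]
            s = scoring.match if (qch == tch and qch != amb and tch != amb) else scoring.mismatch
            if H[i - 1, k] > _NEG // 2 and val == H[i - 1, k] + s:
                matches += int(s == scoring.match)
                cols += 1
                i -= 1
                continue
        if i >= 1 and k + 1 < H.shape[1] and H[i - 1, k + 1] > _NEG // 2 \
                and val == H[i - 1, k + 1] + gap:
            cols += 1
            i -= 1
            k += 1
            continue
        if k >= 1 and H[i, k - 1] > _NEG // 2 and val == H[i, k - 1] + gap:
            cols += 1
            k -= 1
            continue
        break
    qs, ts = i, i + d_lo + k
    return qs, qe, ts, te, matches, cols


def _cluster_diagonals(diags: np.ndarray, band: int) -> list[tuple[int, int]]:
    if diags.size == 0:
        return []
    splits = np.flatnonzero(np.diff(diags) > band)
    groups = np.split(diags, splits + 1)
    return [(int(g.min()) - band, int(g.max()) + band) for g in groups]


def _local_alignments(
    query: str,
    target: str,
    scoring: Scoring,
    index: SeedIndex,
    band: int,
    min_score: int,
    max_clusters: int = 100,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """All seed-cluster alignments: (score, qs, qe, ts, te, matches, cols)."""
    diags = index.seed_diagonals(query)
    out = []
    for d_lo, d_hi in _cluster_diagonals(diags, band)[:max_clusters]:
        res = _banded_sw(query, target, d_lo, d_hi, scoring)
        if res is None:
            continue
        score, H = res
        if score < min_score:
            continue
        qs, qe, ts, te, matches, cols = _traceback(query, target, H, max(d_lo, -len(query)), scoring)
        out.append((score, qs, qe, ts, te, matches, cols))
    return out


def align_local(
    query: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = 25,
    k: int | None = None,
    band: int = 32,
    query_id: str = "query",
    target_id: str = "target",
    _index: SeedIndex | None = None,
) -> AlignmentResult | None:
    """Highest-scoring local alignment found by seeding + banded extension.

    Returns ``None`` when no exact k-mer seed exists or the best extension
    scores below ``min_score``.  Plus strand only; callers search the
    reverse complement where relevant.
    """
    query = _validate(query, "query")
    target = _validate(target, "target")
    if k is None:
        k = 15 if is_nucleotide(query) and is_nucleotide(target) else 5
    index = _index if _index is not None else SeedIndex(target, k)
    hits = _local_alignments(query, target, scoring, index, band, min_score)
    if not hits:
        return None
    score, qs, qe, ts, te, matches, cols = max(hits, key=lambda h: (h[0], -h[1]))
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        query_span=(qs, qe),
        target_span=(ts, te),
        strand="+",
        score=score,
        identity=matches / cols if cols else 0.0,
        coverage=(qe - qs) / len(query),
    )


# ---------------------------------------------------------------------------
# cDNA placement


def map_cdna(
    cdna_set: dict[str, str],
    genome: GenomeAnnotation,
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = 25,
    k: int = 15,
    band: int = 32,
) -> tuple[list[AlignmentResult], set[str]]:
    """Place each cDNA on the genome, both strands.

    Returns (all placements with identity >= min_identity and coverage >=
    min_coverage, identifiers of cDNAs with zero passing placements).
    """
    if not (0 < min_identity <= 1) or not (0 < min_coverage <= 1):
        raise AlignmentInputError("thresholds must be in (0, 1]")
    if not genome.sequences:
        raise AlignmentInputError("empty genome")
    if not cdna_set:
        raise AlignmentInputError("empty cDNA set")
    placements: list[AlignmentResult] = []
    placed: set[str] = set()
    for scaffold, seq in genome.sequences.items():
        index = SeedIndex(seq, k)
        for cdna_id, cdna in cdna_set.items():
            cdna = _validate(cdna, cdna_id)
            for strand, q in (("+", cdna), ("-", revcomp(cdna))):
                for score, qs, qe, ts, te, matches, cols in _local_alignments(
                    q, seq, scoring, index, band, min_score
                ):
                    identity = matches / cols if cols else 0.0
                    coverage = (qe - qs) / len(cdna)
                    if identity >= min_identity and coverage >= min_coverage:
                        if strand == "-":
                            qs, qe = len(cdna) - qe, len(cdna) - qs
                        placements.append(
                            AlignmentResult(
                                cdna_id, scaffold, (qs, qe), (ts, te),
                                strand, score, identity, coverage,
                            )
                        )
                        placed.add(cdna_id)
    unplaced = set(cdna_set) - placed
    return placements, unplaced


# ---------------------------------------------------------------------------
# homolog pairs


def all_vs_all_homologs(
    genes_A: dict[str, str],
    genes_B: dict[str, str],
    min_score: int = 50,
    min_identity: float = 0.60,
    min_coverage: float = 0.50,
    scoring: Scoring = DEFAULT_SCORING,
    k: int = 15,
    band: int = 32,
) -> pd.DataFrame:
    """All-against-all gene homology: one best alignment per passing pair.

    A k-mer prefilter restricts the quadratic pair space to pairs sharing at
    least one exact k-mer (on either strand); each candidate pair is then
    aligned and gated on score, identity and coverage.
    """
    if not genes_A or not genes_B:
        raise AlignmentInputError("both gene sets must be non-empty")
    kmer_to_b: dict[str, set[str]] = {}
    for gid, seq in genes_B.items():
        seq = _validate(seq, gid)
        for pos in range(len(seq) - k + 1):
            kmer_to_b.setdefault(seq[pos : pos + k], set()).add(gid)
    rows = []
    for gid_a, seq_a in genes_A.items():
        seq_a = _validate(seq_a, gid_a)
        candidates: set[str] = set()
        for q in (seq_a, revcomp(seq_a)):
            for pos in range(len(q) - k + 1):
                candidates |= kmer_to_b.get(q[pos : pos + k], set())
        for gid_b in sorted(candidates):
            best = None
            for strand, q in (("+", seq_a), ("-", revcomp(seq_a))):
                aln = align_local(
                    q, genes_B[gid_b], scoring, min_score, k, band,
                    query_id=gid_a, target_id=gid_b,
                )
                if aln is not None and (best is None or aln.score > best.score):
                    best = aln
            if best is None:
                continue
            if best.identity >= min_identity and best.coverage >= min_coverage:
                rows.append(
                    {
                        "gene_A": gid_a,
                        "gene_B": gid_b,
                        "score": best.score,
                        "identity": best.identity,
                        "coverage": best.coverage,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_A", "gene_B", "score", "identity", "coverage"])


# ---------------------------------------------------------------------------
# contamination QC


def contamination_fraction(
    assembly: dict[str, str],
    contaminant_set: dict[str, str],
    min_identity: float = 0.80,
    min_score: int = 50,
    scoring: Scoring = DEFAULT_SCORING,
    k: int = 15,
    band: int = 32,
) -> tuple[int, float]:
    """Assembly bases covered by qualifying contaminant alignments.

    Qualifying alignment target spans are unioned per assembly sequence (no
    double counting); the fraction is matched bases over total assembly
    length.
    """
    if not assembly or not contaminant_set:
        raise AlignmentInputError("both inputs must be non-empty")
    total = sum(len(s) for s in assembly.values())
    matched = 0
    for name, seq in assembly.items():
        index = SeedIndex(seq, k)
        spans: list[tuple[int, int]] = []
        for cid, cont in contaminant_set.items():
            cont = _validate(cont, cid)
            for q in (cont, revcomp(cont)):
                for score, qs, qe, ts, te, m, cols in _local_alignments(
                    q, seq, scoring, index, band, min_score
                ):
                    if cols and m / cols >= min_identity:
                        spans.append((ts, te))
        # union of intervals
        spans.sort()
        cur_s, cur_e = None, None
        for s, e in spans:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                matched += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            matched += cur_e - cur_s
    return matched, matched / total if total else 0.0


def contamination_percent(matched_bp: int, assembly_bp: float, decimals: int = 2) -> float:
    """Contamination proportion as a percentage, at reporting precision."""
    return round(100.0 * matched_bp / assembly_bp, decimals)
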