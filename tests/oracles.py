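"""Independent brute-force oracles used to validate the implementations.

Each oracle is deliberately written with a different algorithmic structure
from the code it checks: per-cell dynamic programming instead of banded
row scans, recursive chain enumeration instead of chain DP, recursive
pathway walks over Biopython's codon table instead of cached permutation
counting, and explicit-loop normalization formulas.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from numba import njit


# ---------------------------------------------------------------------------
# full Smith-Waterman (per-cell, linear gaps)


@njit
def _sw_matrix(q: np.ndarray, t: np.ndarray, match: int, mismatch: int, gap: int) -> np.ndarray:
    m, n = q.size, t.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    amb = 78  # ord('N')
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if q[i - 1] == t[j - 1] and q[i - 1] != amb:
                s = match
            else:
                s = mismatch
            best = 0
            v = H[i - 1, j - 1] + s
            if v > best:
                best = v
            v = H[i - 1, j] + gap
            if v > best:
                best = v
            v = H[i, j - 1] + gap
            if v > best:
                best = v
            H[i, j] = best
    return H


def sw_full(query: str, target: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """(best score, full H matrix) of unrestricted local alignment."""
    q = np.frombuffer(query.encode(), dtype=np.uint8).astype(np.int64)
    t = np.frombuffer(target.encode(), dtype=np.uint8).astype(np.int64)
    H = _sw_matrix(q, t, match, mismatch, gap)
    return int(H.max()), H


def sw_identity(query: str, target: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Identity (matches / alignment columns) of the optimal local alignment,
    traced back preferring diagonal moves."""
    _, H = sw_full(query, target, match, mismatch, gap)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    matches = cols = 0
    while H[i, j] > 0:
        val = H[i, j]
        if i and j:
            s = match if (query[i - 1] == target[j - 1] and query[i - 1] != "N") else mismatch
            if val == H[i - 1, j - 1] + s:
                matches += int(s == match)
                cols += 1
                i, j = i - 1, j - 1
                continue
        if i and val == H[i - 1, j] + gap:
            cols += 1
            i -= 1
            continue
        if j and val == H[i, j - 1] + gap:
            cols += 1
            j -= 1
            continue
        break
    return matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# syntenic chain enumeration

def enumerate_valid_chains(nodes, max_gap):
    """All chains (any length >= 1) satisfying both gap criteria.

    A node is (ord_a, ord_b, gene_a, gene_b); chains are strictly increasing
    in ord_a and strictly monotone in ord_b, with fewer than max_gap
    intervening genes between adjacent members on both sides.
    """
    nodes = sorted(set(nodes))
    chains = []

    def ok(prev, nxt, direction):
        if nxt[0] <= prev[0] or nxt[0] - prev[0] - 1 >= max_gap:
            return False
        if direction == 0:
            return True  # second member fixes the direction
        if direction > 0:
            return nxt[1] > prev[1] and nxt[1] - prev[1] - 1 < max_gap
        return nxt[1] < prev[1] and prev[1] - nxt[1] - 1 < max_gap

    def extend(chain, direction, start_idx):
        chains.append(list(chain))
        for idx in range(start_idx, len(nodes)):
            cand = nodes[idx]
            if chain and not ok(chain[-1], cand, direction):
                if chain and cand[0] - chain[-1][0] - 1 >= max_gap:
                    break
                continue
            new_dir = direction
            if chain and direction == 0:
                if cand[1] > chain[-1][1]:
                    if cand[1] - chain[-1][1] - 1 >= max_gap:
                        continue
                    new_dir = 1
                elif cand[1] < chain[-1][1]:
                    if chain[-1][1] - cand[1] - 1 >= max_gap:
                        continue
                    new_dir = -1
                else:
                    continue
            chain.append(cand)
            extend(chain, new_dir, idx + 1)
            chain.pop()

    extend([], 0, 0)
    return [c for c in chains if c]


def chain_gapsum(chain):
    return sum(
        (q[0] - p[0] - 1) + (abs(q[1] - p[1]) - 1) for p, q in zip(chain, chain[1:])
    )


def oracle_blocks(nodes, min_block_genes, max_gap):
    """Greedy best-first selection over the exhaustive chain enumeration.

    Preference: most members, smallest summed gap, lexicographically
    smallest (ord_a, ord_b) sequence; selected chains retire their genes.
    """
    chains = enumerate_valid_chains(nodes, max_gap)
    chains = [c for c in chains if len(c) >= min_block_genes]
    selected = []
    used = set()
    while True:
        avail = [
            c for c in chains
            if not any(n[2] in used or n[3] in used for n in c)
        ]
        if not avail:
            break
        best = min(
            avail,
            key=lambda c: (
                -len(c),
                chain_gapsum(c),
                tuple(n[0] for n in c),
                tuple(n[1] for n in c),
            ),
        )
        selected.append(best)
        for n in best:
            used.add(n[2])
            used.add(n[3])
    return selected


# ---------------------------------------------------------------------------
# NG86 pathway enumeration over Biopython's codon table

_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


def ng86_site_oracle(codon: str) -> float:
    """Synonymous site count: fraction of one-step changes that preserve
    the amino acid (changes to stop count as non-synonymous)."""
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in _TABLE.stop_codons and _translate(mut) == _translate(codon):
                syn += 1 / 3
    return syn


def ng86_path_oracle(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences averaged over minimal
    pathways, found by recursive walks; stop-crossing paths are excluded
    unless every path crosses a stop."""
    paths = []

    def walk(cur, sd, nd, through_stop):
        if cur == cb:
            paths.append((sd, nd, through_stop))
            return
        for pos in range(3):
            if cur[pos] != cb[pos]:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                syn = nxt not in _TABLE.stop_codons and cur not in _TABLE.stop_codons \
                    and _translate(nxt) == _translate(cur)
                walk(
                    nxt,
                    sd + (1 if syn else 0),
                    nd + (0 if syn else 1),
                    through_stop or nxt in _TABLE.stop_codons,
                )

    walk(ca, 0, 0, False)
    if not paths:
        return 0.0, 0.0
    clean = [(s, n) for s, n, stop in paths if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in paths]
    return (
        sum(s for s, _ in clean) / len(clean),
        sum(n for _, n in clean) / len(clean),
    )


# ---------------------------------------------------------------------------
# size factors, direct formula


def size_factors_oracle(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios factors rescaled to median 1, with explicit loops."""
    n_genes, n_samples = counts.shape
    geomeans = []
    for g in range(n_genes):
        row = counts[g]
        if (row > 0).all():
            geomeans.append((g, float(np.prod(row ** (1.0 / n_samples)))))
    factors = []
    for j in range(n_samples):
        ratios = [counts[g, j] / gm for g, gm in geomeans]
        factors.append(float(np.median(ratios)))
    factors = np.array(factors)
    return factors / np.median(factors)
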