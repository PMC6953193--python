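"""Read mapping, homozygous SNV calling and windowed SNV density.

The mapper is an exact substitution-only aligner: reads are seeded with
``max_substitutions + 1`` disjoint exact k-mers (pigeonhole: any placement
within the mismatch cap must leave one seed intact), candidate loci are
verified by direct comparison, and each read keeps its minimum-mismatch
placement — reads whose best count is tied at distinct loci are discarded
as ambiguous.  Suited to comparing two inbred genotypes, where true
variants are homozygous and a high alternate-allele fraction is expected
at every real site.

Internal coordinates are 0-based half-open; VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import GenomeAnnotation, Read, WildcompError

_PAD = 4  # sentinel code distinct from A/C/G/T


class VariantError(WildcompError):
    pass


class ReadPlacement(NamedTuple):
    read_id: str
    scaffold: str
    start: int  # 0-based
    strand: str
    n_mismatches: int


class SNVRecord(NamedTuple):
    scaffold: str
    position: int  # 1-based, as printed in VCF
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float


class WindowDensity(NamedTuple):
    scaffold: str
    window_start: int  # 0-based half-open
    window_end: int
    snv_count: int
    partial: bool


@dataclass
class PlacementSet:
    """Vectorized read placements against one reference."""

    scaffolds: list[str]
    scaffold_lengths: dict[str, int]
    read_length: int
    read_ids: list[str]
    read_index: np.ndarray
    scaffold_index: np.ndarray
    start: np.ndarray  # local, 0-based
    strand: np.ndarray  # '+'/'-' as bool (True = reverse)
    n_mismatches: np.ndarray
    # one row per mismatching base of a kept placement
    mm_scaffold_index: np.ndarray
    mm_position: np.ndarray
    mm_base: np.ndarray  # read base code 0..3

    def __len__(self) -> int:
        return len(self.start)

    def to_records(self) -> list[ReadPlacement]:
        return [
            ReadPlacement(
                self.read_ids[self.read_index[i]],
                self.scaffolds[self.scaffold_index[i]],
                int(self.start[i]),
                "-" if self.strand[i] else "+",
                int(self.n_mismatches[i]),
            )
            for i in range(len(self))
        ]


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(raw.size, _PAD, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of all k-mers free of non-ACGT bases."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    clean = codes != _PAD
    for j in range(k):
        vals = vals * 4 + np.where(clean[j : j + n], codes[j : j + n], 0)
    bad = np.cumsum(~clean)
    bad_in_win = bad[k - 1 :] - np.concatenate(([0], bad[: n - 1]))
    pos = np.flatnonzero(bad_in_win == 0)
    return vals[pos], pos


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten [lo_i, hi_i) ranges; returns (owner row index, flat values)."""
    counts = hi - lo
    total = int(counts.sum())
    owners = np.repeat(np.arange(lo.size), counts)
    flat = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts) + np.repeat(lo, counts)
    return owners, flat


def map_reads(
    reads: list[Read],
    reference: GenomeAnnotation,
    max_substitutions: int = 2,
) -> PlacementSet:
    """Place each read at its minimum-mismatch locus within the cap.

    Both orientations are searched; reads with tied best placements at
    distinct loci are discarded as ambiguous.
    """
    if not reads:
        raise VariantError("no reads")
    L = len(reads[0].seq)
    if any(len(r.seq) != L for r in reads):
        raise VariantError("reads must have uniform length")
    k = min(31, L // (max_substitutions + 1))
    if k < 8:
        raise VariantError(f"reads of {L} bp too short for {max_substitutions} substitutions")

    scaffolds = list(reference.sequences)
    pad = np.full(L, _PAD, dtype=np.uint8)
    chunks, offsets = [], {}
    cursor = 0
    for name in scaffolds:
        codes = _encode(reference.sequences[name])
        offsets[name] = cursor
        chunks.append(codes)
        chunks.append(pad)
        cursor += codes.size + L
    ref = np.concatenate(chunks)
    off_arr = np.array([offsets[s] for s in scaffolds], dtype=np.int64)
    len_arr = np.array([len(reference.sequences[s]) for s in scaffolds], dtype=np.int64)

    ref_codes, ref_pos = _kmer_codes(ref, k)
    order = np.argsort(ref_codes, kind="stable")
    sorted_codes, sorted_pos = ref_codes[order], ref_pos[order]

    read_mat = np.stack([_encode(r.seq) for r in reads])
    n_reads = read_mat.shape[0]
    offsets_seed = [i * k for i in range(max_substitutions + 1)]

    per_orient: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for rc in (False, True):
        mat = np.where(read_mat == _PAD, _PAD, 3 - read_mat[:, ::-1]) if rc else read_mat
        cand_reads, cand_starts = [], []
        for o in offsets_seed:
            seed = np.zeros(n_reads, dtype=np.int64)
            ok = np.ones(n_reads, dtype=bool)
            for j in range(k):
                col = mat[:, o + j]
                ok &= col != _PAD
                seed = seed * 4 + np.where(col == _PAD, 0, col)
            lo = np.searchsorted(sorted_codes, seed, side="left")
            hi = np.searchsorted(sorted_codes, seed, side="right")
            lo, hi = np.where(ok, lo, 0), np.where(ok, hi, 0)
            owners, flat = _expand_ranges(lo, hi)
            cand_reads.append(owners)
            cand_starts.append(sorted_pos[flat] - o)
        c_read = np.concatenate(cand_reads)
        c_start = np.concatenate(cand_starts)
        keep = (c_start >= 0) & (c_start + L <= ref.size)
        c_read, c_start = c_read[keep], c_start[keep]
        # candidate start must sit fully inside one scaffold
        scaf = np.searchsorted(off_arr, c_start, side="right") - 1
        inside = (c_start >= off_arr[scaf]) & (c_start + L <= off_arr[scaf] + len_arr[scaf])
        c_read, c_start = c_read[inside], c_start[inside]
        key = c_read.astype(np.int64) * (ref.size + 1) + c_start
        _, uniq = np.unique(key, return_index=True)
        c_read, c_start = c_read[uniq], c_start[uniq]
        # verify by direct comparison, chunked
        mism = np.empty(c_read.size, dtype=np.int32)
        step = 100_000
        for s0 in range(0, c_read.size, step):
            sl = slice(s0, s0 + step)
            windows = ref[c_start[sl, None] + np.arange(L)]
            mism[sl] = (windows != mat[c_read[sl]]).sum(axis=1)
        good = mism <= max_substitutions
        per_orient.append((c_read[good], c_start[good], mism[good]))

    a_read = np.concatenate([per_orient[0][0], per_orient[1][0]])
    a_start = np.concatenate([per_orient[0][1], per_orient[1][1]])
    a_mism = np.concatenate([per_orient[0][2], per_orient[1][2]])
    a_rc = np.concatenate(
        [np.zeros(per_orient[0][0].size, bool), np.ones(per_orient[1][0].size, bool)]
    )
    if a_read.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return PlacementSet(
            scaffolds, reference.scaffold_lengths(), L, [r.read_id for r in reads],
            empty, empty, empty, np.empty(0, bool), empty, empty, empty, empty,
        )

    order = np.lexsort((a_start, a_rc, a_mism, a_read))
    a_read, a_start, a_mism, a_rc = a_read[order], a_start[order], a_mism[order], a_rc[order]
    first = np.concatenate(([True], a_read[1:] != a_read[:-1]))
    best_idx = np.flatnonzero(first)
    # ambiguous: the next placement of the same read ties the best count
    nxt = best_idx + 1
    has_next = nxt < a_read.size
    tied = np.zeros(best_idx.size, dtype=bool)
    hn = np.flatnonzero(has_next)
    tied[hn] = (a_read[nxt[hn]] == a_read[best_idx[hn]]) & (
        a_mism[nxt[hn]] == a_mism[best_idx[hn]]
    )
    keep = best_idx[~tied]
    p_read, p_start, p_mism, p_rc = a_read[keep], a_start[keep], a_mism[keep], a_rc[keep]
    p_scaf = np.searchsorted(off_arr, p_start, side="right") - 1
    p_local = p_start - off_arr[p_scaf]

    # mismatch records for the kept placements
    mm_s, mm_p, mm_b = [], [], []
    step = 100_000
    for s0 in range(0, p_read.size, step):
        sl = slice(s0, min(s0 + step, p_read.size))
        windows = ref[p_start[sl, None] + np.arange(L)]
        mats = np.where(
            p_rc[sl, None],
            np.where(read_mat[p_read[sl]] == _PAD, _PAD, 3 - read_mat[p_read[sl], ::-1]),
            read_mat[p_read[sl]],
        )
        row, col = np.nonzero(windows != mats)
        base = mats[row, col]
        valid = base != _PAD
        row, col, base = row[valid], col[valid], base[valid]
        gpos = p_start[sl][row] + col
        mm_s.append(p_scaf[sl][row])
        mm_p.append(gpos - off_arr[p_scaf[sl][row]])
        mm_b.append(base)

    return PlacementSet(
        scaffolds=scaffolds,
        scaffold_lengths=reference.scaffold_lengths(),
        read_length=L,
        read_ids=[r.read_id for r in reads],
        read_index=p_read,
        scaffold_index=p_scaf,
        start=p_local,
        strand=p_rc,
        n_mismatches=p_mism,
        mm_scaffold_index=np.concatenate(mm_s) if mm_s else np.empty(0, dtype=np.int64),
        mm_position=np.concatenate(mm_p) if mm_p else np.empty(0, dtype=np.int64),
        mm_base=np.concatenate(mm_b) if mm_b else np.empty(0, dtype=np.int64),
    )


def depth_profile(placements: PlacementSet) -> dict[str, np.ndarray]:
    """Per-base read depth for every reference scaffold."""
    out = {}
    for s_idx, name in enumerate(placements.scaffolds):
        L = placements.scaffold_lengths[name]
        diff = np.zeros(L + 1, dtype=np.int64)
        sel = placements.scaffold_index == s_idx
        starts = placements.start[sel]
        np.add.at(diff, starts, 1)
        np.add.at(diff, np.minimum(starts + placements.read_length, L), -1)
        out[name] = np.cumsum(diff[:-1])
    return out


def call_snvs(
    placements: PlacementSet,
    reference: GenomeAnnotation,
    min_depth: int = 4,
    min_alt_fraction: float = 0.9,
) -> list[SNVRecord]:
    """Pileup SNV calling under the depth / allele-fraction rule.

    A site is an SNV iff read depth >= ``min_depth`` and the most frequent
    non-reference allele reaches ``min_alt_fraction`` of the depth — the
    homozygous-variant regime expected between inbred genotypes.
    """
    depth = depth_profile(placements)
    snvs: list[SNVRecord] = []
    bases = "ACGT"
    for s_idx, name in enumerate(placements.scaffolds):
        sel = placements.mm_scaffold_index == s_idx
        pos = placements.mm_position[sel]
        base = placements.mm_base[sel]
        if pos.size == 0:
            continue
        key = pos * 4 + base
        uniq, counts = np.unique(key, return_counts=True)
        upos, ubase = uniq // 4, uniq % 4
        ref_seq = reference.sequences[name]
        d = depth[name]
        # best alt per position (counts desc, then base asc for determinism)
        order = np.lexsort((ubase, -counts, upos))
        upos, ubase, counts = upos[order], ubase[order], counts[order]
        first = np.concatenate(([True], upos[1:] != upos[:-1]))
        for p, b, c in zip(upos[first], ubase[first], counts[first]):
            dep = int(d[p])
            ref_base = ref_seq[p]
            if ref_base not in bases:
                continue
            alt = bases[int(b)]
            if alt == ref_base:
                continue
            if dep >= min_depth and c / dep >= min_alt_fraction:
                snvs.append(SNVRecord(name, int(p) + 1, ref_base, alt, dep, float(c / dep)))
    snvs.sort(key=lambda s: (s.scaffold, s.position))
    return snvs


def window_density(
    snvs: list[SNVRecord],
    scaffold_lengths: dict[str, int],
    window: int = 10_000_000,
) -> list[WindowDensity]:
    """Non-overlapping windowed SNV counts tiling each scaffold.

    The final partial window is retained and flagged; counts across all
    windows sum to the number of SNVs.
    """
    if window <= 0:
        raise VariantError("window must be positive")
    per_scaf: dict[str, list[int]] = {s: [] for s in scaffold_lengths}
    for s in snvs:
        if s.scaffold not in scaffold_lengths:
            raise VariantError(f"SNV on unknown scaffold {s.scaffold}")
        pos0 = s.position - 1
        if not (0 <= pos0 < scaffold_lengths[s.scaffold]):
            raise VariantError(f"SNV position {s.position} outside {s.scaffold}")
        per_scaf[s.scaffold].append(pos0)
    out: list[WindowDensity] = []
    for name, L in scaffold_lengths.items():
        n_win = max(1, -(-L // window))
        counts = np.zeros(n_win, dtype=np.int64)
        pos = np.array(per_scaf[name], dtype=np.int64)
        if pos.size:
            np.add.at(counts, pos // window, 1)
        for w in range(n_win):
            end = min((w + 1) * window, L)
            out.append(WindowDensity(name, w * window, end, int(counts[w]), end - w * window < window))
    return out


def write_vcf(
    snvs: list[SNVRecord], scaffold_lengths: dict[str, int], path: str
) -> None:
    """Minimal 8-column VCF with DP and AF in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n')
        for name, L in scaffold_lengths.items():
            fh.write(f"##contig=<ID={name},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snvs:
            fh.write(
                f"{s.scaffold}\t{s.position}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t"
                f"DP={s.depth};AF={s.alt_fraction:.4f}\n"
            )


def write_bedgraph(densities: list[WindowDensity], path: str) -> None:
    with open(path, "w") as fh:
        for w in densities:
            fh.write(f"{w.scaffold}\t{w.window_start}\t{w.window_end}\t{w.snv_count}\n")
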