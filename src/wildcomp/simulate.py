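"""Synthetic two-genotype genome simulator with recorded ground truth.

Emulates the comparison of a wild and a cultivated inbred genotype: an
ancestral gene-bearing genome is split into genotypes A and B, where B
accumulates planted single-nucleotide substitutions (optionally at elevated
pericentromeric density) and each genotype loses a disjoint set of planted
genotype-specific genes (whole-gene deletions, the PAV concept).  Short
reads, LTR retrotransposon pairs diverged to known ages, and a
negative-binomial tissue count matrix complete the inputs every downstream
stage needs, so the whole pipeline is testable without any download.

All randomness flows from a single seed; each stage draws from its own
spawned substream, so adding a stage never perturbs the output of earlier
stages and identical specs give byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Gene, GenomeAnnotation, Read, WildcompError

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in _STOPS
]

# stage keys for spawned random substreams
_STAGE_GENOME = 0
_STAGE_READS = 1
_STAGE_LTR = 2
_STAGE_COUNTS = 3


class SimulationError(WildcompError):
    pass


def _rng(seed: int, stage: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage, sub)))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated study.

    Defaults are the desk-scale study conditions: a handful of sub-Mb
    scaffolds carrying forward-strand genes, inter-genotype divergence of a
    few substitutions per kilobase with a 3x pericentromeric elevation,
    ~10x substitution-error short reads, LTR pairs aged 0.5-2 MYA under the
    grass LTR clock (1.3e-8 subs/site/year), and a six-tissue two-replicate
    count matrix with 4-fold tissue-specific genes.
    """

    seed: int = 0
    # genome layout
    n_scaffolds: int = 2
    scaffold_length: int = 300_000
    n_genes: int = 60
    gene_length: int = 900
    intergenic_length: int = 3_000
    random_strand: bool = False
    name_A: str = "WB"
    name_B: str = "MX"
    # inter-genotype variation
    snv_rate: float = 0.003
    pericentromere_interval: tuple[int, int] = (100_000, 200_000)
    pericentromere_multiplier: float = 3.0
    n_specific_A: int = 5
    n_specific_B: int = 5
    specific_mode: str = "deletion"  # or "divergence"
    specific_divergence: float = 0.35
    # LTR elements
    n_ltr_pairs: int = 20
    ltr_ages: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    ltr_rate: float = 1.3e-8
    ltr_length: int = 2_000
    # reads
    read_length: int = 100
    read_depth: float = 10.0
    read_error_rate: float = 0.001
    # expression
    tissues: tuple[str, ...] = ("root", "seedling", "leaf", "stem", "kernel", "spikelet")
    reps_per_tissue: int = 2
    nb_dispersion: float = 0.05
    specific_fraction_expr: float = 0.1
    fold_change: float = 4.0

    def __post_init__(self):
        if min(self.scaffold_length, self.gene_length, self.intergenic_length,
               self.read_length, self.ltr_length) <= 0:
            raise SimulationError("all lengths must be positive")
        if not (0.0 <= self.snv_rate <= 0.2):
            raise SimulationError("snv_rate must be in [0, 0.2]")
        if self.pericentromere_multiplier < 1.0:
            raise SimulationError("pericentromere multiplier must be >= 1")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.read_depth <= 0:
            raise SimulationError("read_depth must be > 0")
        if self.fold_change < 1.0:
            raise SimulationError("fold_change must be >= 1")
        if self.specific_mode not in ("deletion", "divergence"):
            raise SimulationError(f"unknown specific_mode {self.specific_mode!r}")
        if self.gene_length % 3:
            raise SimulationError("gene_length must be a codon multiple")


@dataclass
class TruthTable:
    """Ground truth recorded while simulating; keys exist in emitted data."""

    specific_genes_A: set[str] = field(default_factory=set)
    specific_genes_B: set[str] = field(default_factory=set)
    # per scaffold of genotype B (the SNV-calling reference): 0-based sorted
    # positions with ref (B) and alt (A) alleles
    snv_positions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    ltr_true_ages: dict[str, float] = field(default_factory=dict)
    # (gene_A, gene_B, planted substitution count, planted p-distance)
    ortholog_map: list[tuple[str, str, int, float]] = field(default_factory=list)
    tissue_specific_genes: dict[str, str] = field(default_factory=dict)
    # pericentromere interval per B scaffold, in B coordinates
    pericentromere: dict[str, tuple[int, int]] = field(default_factory=dict)

    def n_snvs(self) -> int:
        return sum(len(p) for p, _, _ in self.snv_positions.values())


# ---------------------------------------------------------------------------
# genome pair


def _random_coding(rng: np.random.Generator, length: int) -> str:
    """Stop-free coding sequence of `length` (codon multiple)."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=length // 3)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _layout(spec: SimulationSpec) -> list[list[tuple[int, int]]]:
    """Gene intervals per scaffold for the ancestral genome."""
    n_anc = spec.n_genes + spec.n_specific_B
    per = [n_anc // spec.n_scaffolds] * spec.n_scaffolds
    for i in range(n_anc % spec.n_scaffolds):
        per[i] += 1
    pitch = spec.gene_length + spec.intergenic_length
    out = []
    for n_i in per:
        need = n_i * pitch + spec.intergenic_length
        if need > spec.scaffold_length:
            raise SimulationError(
                f"{n_i} genes of {spec.gene_length} bp with {spec.intergenic_length} bp "
                f"spacing need {need} bp > scaffold_length {spec.scaffold_length}"
            )
        out.append(
            [(spec.intergenic_length + j * pitch,
              spec.intergenic_length + j * pitch + spec.gene_length) for j in range(n_i)]
        )
    return out


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, rate: np.ndarray | float
) -> np.ndarray:
    """Substitute bases i.i.d. at per-site `rate`; returns 0-based positions hit."""
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        codes[hit] = (codes[hit] + shift) % 4
    return hit


def _to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def _to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(raw.size, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def simulate_genome_pair(
    spec: SimulationSpec,
) -> tuple[GenomeAnnotation, GenomeAnnotation, TruthTable]:
    """Build genotypes A and B from a shared ancestor, recording truth.

    B carries planted SNVs (density multiplied inside the pericentromere
    interval) and lacks the planted A-specific genes; A lacks the planted
    B-specific genes.  Gene order is preserved, so true syntenic blocks are
    the maximal runs of shared genes.
    """
    rng = _rng(spec.seed, _STAGE_GENOME)
    layout = _layout(spec)
    n_anc = spec.n_genes + spec.n_specific_B

    # choose disjoint planted specific sets among ancestral gene indices
    chosen = rng.choice(n_anc, size=spec.n_specific_A + spec.n_specific_B, replace=False)
    spec_a_idx = set(chosen[: spec.n_specific_A].tolist())
    spec_b_idx = set(chosen[spec.n_specific_A :].tolist())

    truth = TruthTable()
    a_seqs: dict[str, str] = {}
    b_seqs: dict[str, str] = {}
    a_genes: list[Gene] = []
    b_genes: list[Gene] = []

    peri_lo, peri_hi = spec.pericentromere_interval
    gene_no = 0
    for s_idx, intervals in enumerate(layout):
        scaf_a = f"{spec.name_A}_scaf{s_idx + 1}"
        scaf_b = f"{spec.name_B}_chr{s_idx + 1}"
        anc = rng.integers(0, 4, size=spec.scaffold_length, dtype=np.uint8)
        strands = []
        for (g0, g1) in intervals:
            anc[g0:g1] = _to_codes(_random_coding(rng, spec.gene_length))
            strands.append("-" if spec.random_strand and rng.random() < 0.5 else "+")

        # genotype B: mutate the ancestor ...
        b_codes = anc.copy()
        rate = np.full(spec.scaffold_length, spec.snv_rate)
        lo, hi = max(0, peri_lo), min(spec.scaffold_length, peri_hi)
        rate[lo:hi] = spec.snv_rate * spec.pericentromere_multiplier
        if spec.specific_mode == "divergence":
            # A-specific genes stay in B but diverge past recognition
            for j, (g0, g1) in enumerate(intervals):
                if gene_no + j in spec_a_idx:
                    rate[g0:g1] = spec.specific_divergence
        hit = _mutate(rng, b_codes, rate)

        # ... then excise per-genotype deleted genes and shift coordinates
        a_keep = np.ones(spec.scaffold_length, dtype=bool)
        b_keep = np.ones(spec.scaffold_length, dtype=bool)
        for j, (g0, g1) in enumerate(intervals):
            gi = gene_no + j
            if gi in spec_b_idx:
                a_keep[g0:g1] = False
            if gi in spec_a_idx and spec.specific_mode == "deletion":
                b_keep[g0:g1] = False

        a_off = np.cumsum(~a_keep)  # bases removed at-or-before each position
        b_off = np.cumsum(~b_keep)
        a_final = anc[a_keep]
        b_final = b_codes[b_keep]
        a_seqs[scaf_a] = _to_str(a_final)
        b_seqs[scaf_b] = _to_str(b_final)

        # record SNVs on B coordinates (exclude excised bases)
        keep_hit = hit[b_keep[hit]]
        pos_b = keep_hit - b_off[keep_hit]
        ref = BASES[b_codes[keep_hit]].tobytes().decode()
        alt = BASES[anc[keep_hit]].tobytes().decode()
        truth.snv_positions[scaf_b] = (
            pos_b.astype(np.int64),
            np.array(list(ref)),
            np.array(list(alt)),
        )
        truth.pericentromere[scaf_b] = (
            int(lo - (b_off[lo - 1] if lo else 0)),
            int(hi - (b_off[hi - 1] if hi else 0)),
        )

        for j, (g0, g1) in enumerate(intervals):
            gi = gene_no + j
            id_a = f"{spec.name_A}_g{gi + 1:04d}"
            id_b = f"{spec.name_B}_g{gi + 1:04d}"
            strand = strands[j]
            in_a = gi not in spec_b_idx
            in_b = gi not in spec_a_idx or spec.specific_mode == "divergence"
            if in_a:
                a0 = g0 - (a_off[g0 - 1] if g0 else 0)
                a_genes.append(Gene(id_a, scaf_a, int(a0), int(a0 + spec.gene_length), strand))
            if in_b:
                b0 = g0 - (b_off[g0 - 1] if g0 else 0)
                b_genes.append(Gene(id_b, scaf_b, int(b0), int(b0 + spec.gene_length), strand))
            if gi in spec_a_idx:
                truth.specific_genes_A.add(id_a)
            elif gi in spec_b_idx:
                truth.specific_genes_B.add(id_b)
            else:
                n_sub = int(np.count_nonzero(anc[g0:g1] != b_codes[g0:g1]))
                truth.ortholog_map.append((id_a, id_b, n_sub, n_sub / spec.gene_length))
        gene_no += len(intervals)

    genome_a = GenomeAnnotation(spec.name_A, a_seqs, a_genes)
    genome_b = GenomeAnnotation(spec.name_B, b_seqs, b_genes)
    _check_truth(genome_a, genome_b, truth)
    return genome_a, genome_b, truth


def _check_truth(a: GenomeAnnotation, b: GenomeAnnotation, truth: TruthTable) -> None:
    for gid in truth.specific_genes_A:
        assert gid in a
    for gid in truth.specific_genes_B:
        assert gid in b
    for ga, gb, _, _ in truth.ortholog_map:
        assert ga in a and gb in b
    for pos, _, _ in truth.snv_positions.values():
        assert np.all(np.diff(pos) > 0), "SNV positions must be strictly increasing"


# ---------------------------------------------------------------------------
# reads


def simulate_reads(genome: GenomeAnnotation, spec: SimulationSpec) -> list[Read]:
    """Uniform-coverage single-end reads with i.i.d. substitution errors.

    Expected per-base depth equals ``spec.read_depth``; read count per
    scaffold is the deterministic round of depth * length / read_length.
    """
    sub = zlib.crc32(genome.name.encode()) & 0x7FFFFFFF
    rng = _rng(spec.seed, _STAGE_READS, sub)
    reads: list[Read] = []
    for scaf, seq in genome.sequences.items():
        L = len(seq)
        if spec.read_length > L:
            raise SimulationError(f"read_length {spec.read_length} > scaffold {scaf} ({L} bp)")
        n_reads = int(round(spec.read_depth * L / spec.read_length))
        codes = _to_codes(seq)
        starts = rng.integers(0, L - spec.read_length + 1, size=n_reads)
        rc = rng.random(n_reads) < 0.5
        windows = codes[starts[:, None] + np.arange(spec.read_length)]
        if spec.read_error_rate > 0:
            err = rng.random(windows.shape) < spec.read_error_rate
            shift = rng.integers(1, 4, size=windows.shape)
            windows = np.where(err, (windows + shift) % 4, windows)
        # reverse-complement half the reads (complement = 3 - code for ACGT)
        windows[rc] = 3 - windows[rc, ::-1]
        raw = BASES[windows]
        for i in range(n_reads):
            strand = "r" if rc[i] else "f"
            reads.append(Read(f"{scaf}:{starts[i]}:{strand}:{i}", raw[i].tobytes().decode()))
    return reads


# ---------------------------------------------------------------------------
# LTR pairs


def simulate_ltr_pairs(spec: SimulationSpec) -> tuple[dict[str, str], TruthTable]:
    """LTR element pairs whose two LTRs diverged for a known age.

    Each copy evolves independently under a JC69 substitution process with
    branch length r*T substitutions/site, so the expected JC-corrected
    pairwise distance is 2*r*T — exactly what the dating formula inverts.
    """
    rng = _rng(spec.seed, _STAGE_LTR)
    truth = TruthTable()
    seqs: dict[str, str] = {}
    for i in range(spec.n_ltr_pairs):
        age = float(spec.ltr_ages[i % len(spec.ltr_ages)])
        if age < 0:
            raise SimulationError("LTR ages must be non-negative")
        d = spec.ltr_rate * age * 1e6  # expected substitutions/site per copy
        if 2 * d >= 0.75:
            raise SimulationError(
                f"age {age} MYA at rate {spec.ltr_rate} exceeds the JC69 saturation bound"
            )
        anc = rng.integers(0, 4, size=spec.ltr_length, dtype=np.uint8)
        # JC69: P(change to each specific other base after branch d)
        a = (1.0 - math.exp(-4.0 * d / 3.0)) / 4.0
        copies = []
        for _ in range(2):
            c = anc.copy()
            _mutate(rng, c, 3.0 * a)
            copies.append(_to_str(c))
        name = f"ltr{i + 1:04d}"
        seqs[f"{name}_5p"] = copies[0]
        seqs[f"{name}_3p"] = copies[1]
        truth.ltr_true_ages[name] = age
    return seqs, truth


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    spec: SimulationSpec, gene_ids: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Negative-binomial tissue x replicate counts with planted specifics.

    Returns (counts, sample->tissue map, gene->tissue truth).  Planted
    tissue-specific genes have their mean multiplied by ``fold_change`` in
    exactly one tissue; with ``fold_change == 1`` nothing is planted.
    """
    if len(spec.tissues) < 2 or spec.reps_per_tissue < 2:
        raise SimulationError("need >=2 tissues and >=2 replicates per tissue")
    rng = _rng(spec.seed, _STAGE_COUNTS)
    if gene_ids is None:
        gene_ids = [f"{spec.name_A}_g{i + 1:04d}" for i in range(spec.n_genes)]
    n_genes = len(gene_ids)
    base = rng.lognormal(mean=math.log(1000.0), sigma=0.5, size=n_genes)
    base = np.clip(base, 50.0, 5e4)

    truth: dict[str, str] = {}
    mu = np.tile(base[:, None], (1, len(spec.tissues)))
    if spec.fold_change > 1.0:
        n_spec = int(round(spec.specific_fraction_expr * n_genes))
        planted = rng.choice(n_genes, size=n_spec, replace=False)
        for k, g_idx in enumerate(planted):
            t_idx = int(rng.integers(0, len(spec.tissues)))
            mu[g_idx, t_idx] *= spec.fold_change
            truth[gene_ids[g_idx]] = spec.tissues[t_idx]

    samples, tissue_of = [], {}
    cols = []
    for t_idx, tissue in enumerate(spec.tissues):
        for rep in range(spec.reps_per_tissue):
            name = f"{tissue}_r{rep + 1}"
            samples.append(name)
            tissue_of[name] = tissue
            m = mu[:, t_idx]
            n_param = 1.0 / spec.nb_dispersion
            p_param = n_param / (n_param + m)
            cols.append(rng.negative_binomial(n_param, p_param))
    counts = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=samples)
    return counts, tissue_of, truth
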