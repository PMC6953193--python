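"""Local aligner vs the full quadratic DP oracle; placement and QC gates."""

import numpy as np
import pytest

from wildcomp import alignment
from wildcomp.alignment import (
    AlignmentInputError,
    align_local,
    all_vs_all_homologs,
    contamination_fraction,
    contamination_percent,
    map_cdna,
)
from wildcomp.io import GenomeAnnotation, revcomp

from .conftest import mutate_sequence, random_dna


def test_self_alignment_perfect():
    seq = "ACGTTGCAGGCTAAGCTTACGATCGTAGCTAGC" * 4
    res = align_local(seq, seq)
    assert res.identity == 1.0 and res.coverage == 1.0 and res.strand == "+"
    assert res.query_span == (0, len(seq)) and res.target_span == (0, len(seq))


def test_unrelated_homopolymers_give_none():
    assert align_local("A" * 120, "C" * 120) is None


def test_invalid_alphabet_rejected():
    with pytest.raises(AlignmentInputError):
        align_local("ACGT1234", "ACGT")
    with pytest.raises(AlignmentInputError):
        align_local("", "ACGT")


def test_n_never_matches():
    res = align_local("ACGT" * 10 + "N" * 4 + "ACGT" * 10, "ACGT" * 10 + "N" * 4 + "ACGT" * 10)
    assert res.identity < 1.0


def test_planted_mismatches_agree_with_dp_oracle(rng):
    """300-bp query with 30 planted mismatches: score and identity match
    the unrestricted Smith-Waterman oracle."""
    from .oracles import sw_full, sw_identity

    for _ in range(10):
        target = random_dna(rng, 1000)
        query = mutate_sequence(rng, target[350:650], 30)
        res = align_local(query, target)
        oracle_score, _ = sw_full(query, target)
        assert res is not None
        assert res.score == oracle_score
        assert res.identity == pytest.approx(sw_identity(query, target), abs=0.01)


def test_score_equals_full_dp_on_many_instances(rng):
    """Seeded banded extension reproduces the full-DP optimum on >=100
    substitution-dominated instances up to 2 kb."""
    from .oracles import sw_full

    checked = 0
    sizes = [60, 80, 120, 200, 300, 500, 800, 1200, 2000]
    for trial in range(110):
        n = sizes[trial % len(sizes)]
        target = random_dna(rng, n)
        qlen = max(40, int(n * rng.uniform(0.3, 0.9)))
        start = int(rng.integers(0, n - qlen + 1))
        query = mutate_sequence(
            rng, target[start : start + qlen], max(1, qlen // 12), keep_tail=20
        )
        res = align_local(query, target)
        oracle_score, _ = sw_full(query, target)
        assert res is not None and res.score == oracle_score
        checked += 1
    assert checked >= 100


def test_identity_symmetric_under_swap(rng):
    target = random_dna(rng, 400)
    query = mutate_sequence(rng, target, 25)
    a = align_local(query, target)
    b = align_local(target, query)
    assert a.identity == pytest.approx(b.identity, abs=1e-12)
    assert a.score == b.score


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(77)
    seq = random_dna(rng, 30_000)
    return GenomeAnnotation("G", {"chr1": seq}, []), seq, rng


class TestMapCdna:
    def test_verbatim_cdna_placed_both_strands(self, genome):
        g, seq, _ = genome
        cdnas = {"fwd": seq[5000:5900], "rev": revcomp(seq[12000:12900])}
        placements, unplaced = map_cdna(cdnas, g)
        assert not unplaced
        by_id = {p.query_id: p for p in placements}
        assert by_id["fwd"].identity == 1.0 and by_id["fwd"].strand == "+"
        assert by_id["rev"].identity == 1.0 and by_id["rev"].strand == "-"
        assert by_id["rev"].target_span == (12000, 12900)

    def test_low_identity_unplaced_at_default_gate(self, genome):
        """~75% identity at the only locus fails the 80% identity gate."""
        g, seq, rng = genome
        cdna = mutate_sequence(rng, seq[8000:8600], 150)
        placements, unplaced = map_cdna({"div": cdna}, g)
        assert unplaced == {"div"}

    def test_partial_coverage_unplaced_at_default_gate(self, genome):
        """A high-identity hit covering only 40% of the query fails the
        50% coverage gate."""
        g, seq, rng = genome
        cdna = seq[20_000:20_400] + random_dna(rng, 600)
        placements, unplaced = map_cdna({"part": cdna}, g)
        assert unplaced == {"part"}

    def test_threshold_monotonicity(self, genome):
        g, seq, rng = genome
        cdnas = {
            f"c{i}": mutate_sequence(rng, seq[i * 1000 : i * 1000 + 800], 80)
            for i in range(5, 10)
        }
        base, _ = map_cdna(cdnas, g, min_identity=0.80, min_coverage=0.50)
        for ident, cov in [(0.9, 0.5), (0.8, 0.8), (0.95, 0.95)]:
            stricter, _ = map_cdna(cdnas, g, min_identity=ident, min_coverage=cov)
            assert {(p.query_id, p.target_span) for p in stricter} <= {
                (p.query_id, p.target_span) for p in base
            }

    def test_empty_inputs_rejected(self, genome):
        g, _, _ = genome
        with pytest.raises(AlignmentInputError):
            map_cdna({}, g)


class TestHomologs:
    def test_identical_sets_pair_each_gene_with_itself(self, rng):
        genes = {f"g{i}": random_dna(rng, 400) for i in range(8)}
        table = all_vs_all_homologs(genes, genes)
        self_pairs = table[table.gene_A == table.gene_B]
        assert set(self_pairs.gene_A) == set(genes)
        assert (self_pairs.identity == 1.0).all()

    def test_disjoint_random_sets_give_empty_table(self, rng):
        a = {f"a{i}": random_dna(rng, 350) for i in range(6)}
        b = {f"b{i}": random_dna(rng, 350) for i in range(6)}
        assert len(all_vs_all_homologs(a, b)) == 0

    def test_simulated_orthologs_fully_recovered(self, simulated_pair):
        a, b, truth = simulated_pair
        table = all_vs_all_homologs(a.cdna_set(), b.cdna_set())
        found = set(zip(table.gene_A, table.gene_B))
        for gene_a, gene_b, _, _ in truth.ortholog_map:
            assert (gene_a, gene_b) in found

    def test_symmetric_content_under_swap(self, rng):
        a = {f"a{i}": random_dna(rng, 400) for i in range(4)}
        b = {f"b{i}": mutate_sequence(rng, seq, 10) for i, seq in enumerate(a.values())}
        ab = all_vs_all_homologs(a, b)
        ba = all_vs_all_homologs(b, a)
        assert set(zip(ab.gene_A, ab.gene_B)) == set(zip(ba.gene_B, ba.gene_A))


class TestContamination:
    def test_no_shared_sequence(self, rng):
        matched, frac = contamination_fraction(
            {"s": "ACGT" * 2000}, {"c": "TTGGCC" * 100}
        )
        assert matched == 0 and frac == 0.0

    def test_single_planted_copy_counted_once(self, rng):
        contaminant = random_dna(rng, 5000)
        assembly = random_dna(rng, 500_000) + contaminant + random_dna(rng, 494_999)
        matched, frac = contamination_fraction({"s": assembly}, {"c": contaminant})
        assert matched == 5000
        assert frac == pytest.approx(5000 / 999_999)

    def test_percent_reporting_precision(self):
        """783,287 matched bases over a 4.28-Gb assembly prints as 0.02%."""
        assert contamination_percent(783_287, 4.28e9) == 0.02
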