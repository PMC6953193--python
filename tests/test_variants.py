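"""Read mapping rules, pileup SNV calling and window densities."""

import numpy as np
import pytest

from wildcomp.io import GenomeAnnotation, Read, revcomp
from wildcomp.simulate import SimulationSpec, simulate_genome_pair, simulate_reads
from wildcomp.variants import (
    SNVRecord,
    VariantError,
    call_snvs,
    depth_profile,
    map_reads,
    window_density,
)

from .conftest import mutate_sequence, random_dna


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(99)
    seq = random_dna(rng, 8_000)
    return GenomeAnnotation("ref", {"chr1": seq}, []), seq, rng


class TestMapReads:
    def test_exact_read_placed_forward(self, reference):
        ref, seq, _ = reference
        ps = map_reads([Read("r1", seq[1000:1100])], ref)
        rec, = ps.to_records()
        assert rec == ("r1", "chr1", 1000, "+", 0)

    def test_reverse_complement_read_placed(self, reference):
        ref, seq, _ = reference
        ps = map_reads([Read("r1", revcomp(seq[2000:2100]))], ref)
        rec, = ps.to_records()
        assert (rec.start, rec.strand, rec.n_mismatches) == (2000, "-", 0)

    def test_mismatch_cap_is_hard(self, reference):
        """Two substitutions place; three substitutions never place."""
        ref, seq, rng = reference
        two = mutate_sequence(rng, seq[3000:3100], 2, keep_tail=34)
        three = mutate_sequence(rng, seq[3000:3100], 3, keep_tail=34)
        # force the three changes into the first two thirds so a seed survives
        ps = map_reads([Read("two", two), Read("three", three)], ref)
        recs = {r.read_id: r for r in ps.to_records()}
        assert recs["two"].n_mismatches == 2
        assert "three" not in recs

    def test_duplicate_locus_read_discarded_as_ambiguous(self):
        rng = np.random.default_rng(5)
        unit = random_dna(rng, 150)
        seq = random_dna(rng, 1000) + unit + random_dna(rng, 1000) + unit + random_dna(rng, 1000)
        ref = GenomeAnnotation("ref", {"c": seq}, [])
        ps = map_reads([Read("dup", unit[10:110]), Read("uniq", seq[100:200])], ref)
        recs = {r.read_id for r in ps.to_records()}
        assert recs == {"uniq"}

    def test_minimum_mismatch_placement_wins(self, reference):
        """A read one substitution away from locus X and four away from a
        copy of X elsewhere maps to X."""
        ref, seq, rng = reference
        read = mutate_sequence(rng, seq[4000:4100], 1, keep_tail=34)
        ps = map_reads([Read("r", read)], ref)
        rec, = ps.to_records()
        assert rec.start == 4000 and rec.n_mismatches == 1


class TestCallSnvs:
    def _ref_and_reads(self, depth: int, alt_at: int = 500):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 2_000)
        ref = GenomeAnnotation("ref", {"c": seq}, [])
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[alt_at]]
        reads = []
        for i in range(depth):
            start = alt_at - 50 + i  # staggered, all covering alt_at
            window = list(seq[start : start + 100])
            window[alt_at - start] = alt_base
            reads.append(Read(f"v{i}", "".join(window)))
        return ref, reads, alt_at, alt_base

    def test_variant_with_five_reads_called(self):
        ref, reads, pos, alt = self._ref_and_reads(5)
        snvs = call_snvs(map_reads(reads, ref), ref)
        assert [(s.position, s.alt_allele, s.depth) for s in snvs] == [(pos + 1, alt, 5)]

    def test_variant_with_three_reads_below_min_depth(self):
        ref, reads, _, _ = self._ref_and_reads(3)
        assert call_snvs(map_reads(reads, ref), ref) == []

    def test_no_variant_no_error_never_called(self, reference):
        ref, seq, _ = reference
        reads = [Read(f"c{i}", seq[i * 37 : i * 37 + 100]) for i in range(150)]
        assert call_snvs(map_reads(reads, ref), ref) == []

    def test_raising_min_depth_never_adds_calls(self):
        ref, reads, _, _ = self._ref_and_reads(8)
        ps = map_reads(reads, ref)
        prev = None
        for min_depth in (4, 6, 8, 10):
            snvs = call_snvs(ps, ref, min_depth=min_depth)
            if prev is not None:
                assert {(s.scaffold, s.position) for s in snvs} <= prev
            prev = {(s.scaffold, s.position) for s in snvs}


class TestWindowDensity:
    LENGTHS = {"chr1": 25_000_000}

    def test_zero_snvs_all_zero_windows(self):
        dens = window_density([], self.LENGTHS)
        assert [w.snv_count for w in dens] == [0, 0, 0]
        assert dens[-1].partial and not dens[0].partial

    def test_boundary_position_convention(self):
        """1-based position 10,000,000 is 0-based 9,999,999: first window."""
        snv = SNVRecord("chr1", 10_000_000, "A", "G", 10, 1.0)
        dens = window_density([snv], self.LENGTHS)
        assert [w.snv_count for w in dens] == [1, 0, 0]
        nxt = SNVRecord("chr1", 10_000_001, "A", "G", 10, 1.0)
        assert [w.snv_count for w in window_density([nxt], self.LENGTHS)] == [0, 1, 0]

    def test_counts_conserved(self, rng):
        snvs = [
            SNVRecord("chr1", int(p) + 1, "A", "G", 5, 1.0)
            for p in rng.integers(0, 25_000_000, size=500)
        ]
        dens = window_density(snvs, self.LENGTHS)
        assert sum(w.snv_count for w in dens) == len(snvs)

    def test_out_of_bounds_position_rejected(self):
        snv = SNVRecord("chr1", 25_000_001, "A", "G", 5, 1.0)
        with pytest.raises(VariantError):
            window_density([snv], self.LENGTHS)


@pytest.fixture(scope="module")
def deep_sim():
    spec = SimulationSpec(
        seed=123, n_scaffolds=1, scaffold_length=150_000, n_genes=10,
        snv_rate=0.003, pericentromere_interval=(50_000, 100_000),
        pericentromere_multiplier=3.0, n_specific_A=0, n_specific_B=0,
        read_depth=30.0, read_error_rate=0.0,
    )
    a, b, truth = simulate_genome_pair(spec)
    ps = map_reads(simulate_reads(a, spec), b)
    return b, truth, call_snvs(ps, b), depth_profile(ps)


class TestTruthRecovery:
    def test_error_free_high_depth_perfect_recovery(self, deep_sim):
        """Error-free ~30x reads: precision 1.0, and recall 1.0 at every
        planted site satisfying the depth floor.

        Tight clusters of planted SNVs (three or more within a read length)
        exceed the 2-substitution mapping cap for every spanning read, so
        those sites have no coverage at all — the depth >= 4 precondition
        of the perfect-recovery property excludes them by construction.
        """
        b, truth, snvs, depth = deep_sim
        called = {(s.scaffold, s.position) for s in snvs}
        planted = {
            (scaf, int(p) + 1)
            for scaf, (pos, _, _) in truth.snv_positions.items()
            for p in pos
        }
        assert called <= planted  # precision 1.0
        recoverable = {(sc, p) for sc, p in planted if depth[sc][p - 1] >= 4}
        assert recoverable <= called  # recall 1.0 on covered sites
        assert len(recoverable) > 0.9 * len(planted)

    def test_alleles_match_truth(self, deep_sim):
        b, truth, snvs, _ = deep_sim
        by_site = {}
        for scaf, (pos, ref, alt) in truth.snv_positions.items():
            for p, r, a in zip(pos, ref, alt):
                by_site[(scaf, int(p) + 1)] = (r, a)
        for s in snvs:
            assert by_site[(s.scaffold, s.position)] == (s.ref_allele, s.alt_allele)

    def test_pericentromeric_density_ratio_recovered(self, deep_sim):
        """Windowed density inside/outside the planted pericentromere
        recovers the multiplier within 3 SDs (Poisson on window totals)."""
        b, truth, snvs, _ = deep_sim
        (lo, hi), = truth.pericentromere.values()
        dens = window_density(snvs, b.scaffold_lengths(), window=10_000)
        c_in = sum(w.snv_count for w in dens if lo <= w.window_start and w.window_end <= hi)
        c_out = sum(w.snv_count for w in dens if w.window_end <= lo or w.window_start >= hi)
        l_in = sum(w.window_end - w.window_start for w in dens
                   if lo <= w.window_start and w.window_end <= hi)
        l_out = sum(w.window_end - w.window_start for w in dens
                    if w.window_end <= lo or w.window_start >= hi)
        ratio = (c_in / l_in) / (c_out / l_out)
        sd = ratio * np.sqrt(1 / c_in + 1 / c_out)
        assert abs(ratio - 3.0) <= 3 * sd
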