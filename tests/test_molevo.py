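"""Clock math: JC69, NG86 vs pathway-enumeration oracle, LTR dating."""

import itertools
import math

import numpy as np
import pytest

from wildcomp.molevo import (
    SENSE_CODONS,
    CodonAlignment,
    CodonAlignmentError,
    SaturationError,
    divergence_time,
    jc69_distance,
    ltr_insertion_time,
    ng86_counts,
    ng86_kaks,
)
from wildcomp.simulate import SimulationSpec, simulate_ltr_pairs

from .conftest import mutate_sequence, random_dna


class TestJC69:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (0.10, 0.10732), (0.74, 3.23812)],
    )
    def test_closed_form(self, p, expected):
        assert jc69_distance(p) == pytest.approx(expected, abs=5e-5)

    def test_saturation_flagged_not_clamped(self):
        with pytest.raises(SaturationError):
            jc69_distance(0.75)
        with pytest.raises(ValueError):
            jc69_distance(-0.1)

    def test_inverts_planted_substitution_probability(self, rng):
        """K estimated from a mutated pair recovers the expected
        substitutions per site within 3 binomial SDs."""
        L, d = 20_000, 0.08  # substitutions/site on one branch
        a = random_dna(rng, L)
        prob = 3 * (1 - math.exp(-4 * d / 3)) / 4
        n_mut = rng.binomial(L, prob)
        b = mutate_sequence(rng, a, n_mut)
        p_obs = sum(x != y for x, y in zip(a, b)) / L
        k = jc69_distance(p_obs)
        p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
        sd_p = math.sqrt(p_exp * (1 - p_exp) / L)
        # delta method: dK/dp = 1 / (1 - 4p/3)
        sd_k = sd_p / (1 - 4 * p_exp / 3)
        assert abs(k - d) <= 3 * sd_k


class TestNG86:
    def test_identical_sequences(self):
        ka, ks, ratio = ng86_kaks(CodonAlignment("ATGGCT", "ATGGCT"))
        assert ka == 0.0 and ks == 0.0 and ratio is None

    def test_single_synonymous_codon_difference(self):
        """GGA vs GGG (both Gly): one synonymous, zero non-synonymous."""
        counts = ng86_counts(CodonAlignment("GGA", "GGG"))
        assert counts.Sd == 1.0 and counts.Nd == 0.0
        ka, ks, _ = ng86_kaks(CodonAlignment("AAA" * 50 + "GGA", "AAA" * 50 + "GGG"))
        assert ka == 0.0 and ks > 0.0

    def test_in_frame_stop_rejected(self):
        with pytest.raises(CodonAlignmentError):
            CodonAlignment("ATGTAAGCT", "ATGTAAGCT")

    def test_swap_invariance(self):
        r = np.random.default_rng(1)
        codons = r.choice(SENSE_CODONS, 80)
        a = "".join(codons)
        b = list(codons)
        for i in r.choice(80, size=15, replace=False):
            alt = b[i]
            while alt == b[i] or alt not in SENSE_CODONS:
                pos = int(r.integers(3))
                alt = b[i][:pos] + r.choice(list("ACGT")) + b[i][pos + 1 :]
            b[i] = alt
        b = "".join(b)
        assert ng86_kaks(CodonAlignment(a, b)) == ng86_kaks(CodonAlignment(b, a))

    def test_adding_synonymous_differences_never_decreases_ks(self):
        """Converting GGA codons to GGG one at a time grows Ks monotonically."""
        base = ["GGA"] * 20 + ["ATG"] * 80
        prev = -1.0
        for n_changed in range(0, 8):
            other = ["GGG"] * n_changed + base[n_changed:]
            _, ks, _ = ng86_kaks(CodonAlignment("".join(base), "".join(other)))
            assert ks >= prev
            prev = ks

    def test_counts_match_pathway_oracle_exhaustively(self):
        """All 61 x 61 sense-codon pairs agree with the independent
        recursive pathway-enumeration oracle on sites and differences."""
        from .oracles import ng86_path_oracle, ng86_site_oracle

        for codon in SENSE_CODONS:
            s, n = ng86_counts(CodonAlignment(codon * 2, codon * 2)).S / 2, None
            assert s == pytest.approx(ng86_site_oracle(codon), abs=1e-12)
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            counts = ng86_counts(CodonAlignment(ca, cb))
            sd, nd = ng86_path_oracle(ca, cb)
            assert counts.Sd == pytest.approx(sd, abs=1e-12), (ca, cb)
            assert counts.Nd == pytest.approx(nd, abs=1e-12), (ca, cb)

    def test_agrees_with_biopython_on_long_alignment(self, rng):
        """Cross-check Ka/Ks against Biopython's NG86 on a diverged pair."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        codons = np.random.default_rng(5).choice(SENSE_CODONS, 300)
        a = "".join(codons)
        b = []
        r = np.random.default_rng(6)
        for c in codons:
            if r.random() < 0.15:
                alt = c
                while alt == c or alt not in SENSE_CODONS:
                    pos = int(r.integers(3))
                    alt = c[:pos] + r.choice(list("ACGT")) + c[pos + 1 :]
                b.append(alt)
            else:
                b.append(c)
        b = "".join(b)
        ka, ks, _ = ng86_kaks(CodonAlignment(a, b))
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert ka == pytest.approx(dn, abs=2e-3)
        assert ks == pytest.approx(ds, abs=2e-3)


class TestClockTimes:
    @pytest.mark.parametrize(
        "ks,rate,expected",
        [
            (0.0, 6.5e-9, 0.0),
            (0.13, 6.5e-9, 10.0),
            (0.1625, 6.5e-9, 12.5),
            (0.026, 1.3e-8, 1.0),
        ],
    )
    def test_closed_form(self, ks, rate, expected):
        assert divergence_time(ks, rate) == pytest.approx(expected, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)


class TestLTRDating:
    def test_identical_ltrs_age_zero(self):
        est = ltr_insertion_time("ACGT" * 300, "ACGT" * 300)
        assert est.time_mya == 0.0 and est.distance == 0.0 and not est.saturated

    def test_saturated_pair_flagged(self):
        est = ltr_insertion_time("A" * 400, "G" * 400)
        assert est.saturated and est.time_mya == math.inf

    def test_known_divergence_dates_correctly(self, rng):
        """~2.6% divergence at r = 1.3e-8 dates to ~1 MYA."""
        L = 20_000
        a = random_dna(rng, L)
        p = 0.75 * (1 - math.exp(-4 * 0.026 / 3))  # raw p for K = 0.026
        b = mutate_sequence(rng, a, round(p * L))
        est = ltr_insertion_time(a, b, rate=1.3e-8)
        assert est.time_mya == pytest.approx(1.0, rel=0.02)

    def test_age_recovery_on_simulated_elements(self):
        """Mean estimated age of fifty 1.5-MYA elements within 5%."""
        spec = SimulationSpec(seed=77, n_ltr_pairs=50, ltr_ages=(1.5,), ltr_length=5_000)
        seqs, truth = simulate_ltr_pairs(spec)
        ages = [
            ltr_insertion_time(seqs[f"{n}_5p"], seqs[f"{n}_3p"]).time_mya
            for n in truth.ltr_true_ages
        ]
        assert np.mean(ages) == pytest.approx(1.5, rel=0.05)
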