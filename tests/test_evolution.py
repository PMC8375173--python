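"""NG86 site/difference counting against a brute-force pathway oracle,
Jukes-Cantor correction, selection calls and the molecular clock."""

import math

import numpy as np
import pytest

from helpers_oracles import oracle_codon_diffs, oracle_sites
from zfsurvey.errors import CodonError
from zfsurvey.evolution import (
    SENSE_CODONS,
    CodonPair,
    count_differences,
    count_sites,
    divergence_time,
    kaks,
)
from zfsurvey.synthetic_data import make_codon_pair


class TestSites:
    @pytest.mark.parametrize(
        "codon,S,N",
        [("TTT", 1 / 3, 8 / 3), ("ATG", 0.0, 3.0)],
    )
    def test_single_codon_site_counts(self, codon, S, N):
        s, n = count_sites(codon)
        assert s == pytest.approx(S) and n == pytest.approx(N)

    def test_concatenation_additivity(self):
        s1, n1 = count_sites("TTT")
        s2, n2 = count_sites("ATG")
        s, n = count_sites("TTTATG")
        assert s == pytest.approx(s1 + s2) and n == pytest.approx(n1 + n2)

    def test_site_conservation_on_random_cds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            codons = rng.choice(SENSE_CODONS, size=int(rng.integers(5, 60)))
            cds = "".join(codons)
            S, N = count_sites(cds)
            assert S + N == pytest.approx(len(cds), abs=1e-9)

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_internal_stop_is_error(self):
        with pytest.raises(CodonError):
            count_sites("ATGTAAATG")


class TestDifferences:
    def test_single_synonymous_difference(self):
        assert count_differences(CodonPair("a", "b", "GAA", "GAG")) == (1.0, 0.0)

    def test_identical_codons(self):
        assert count_differences(CodonPair("a", "b", "AAA", "AAA")) == (0.0, 0.0)

    def test_two_difference_pathway_average(self):
        got = count_differences(CodonPair("a", "b", "AAA", "AGC"))
        assert got == pytest.approx(oracle_codon_diffs("AAA", "AGC"))

    def test_full_sense_codon_grid_matches_oracle(self):
        from zfsurvey.evolution import _codon_differences

        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                assert _codon_differences(a, b) == pytest.approx(
                    oracle_codon_diffs(a, b)
                ), (a, b)


class TestKaKs:
    def test_identical_pair_rates_zero_selection_undefined(self):
        cds = "GAATTTATGCAA" * 10
        r = kaks(CodonPair("a", "b", cds, cds))
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert r.omega is None and r.selection is None

    def test_synonymous_only_pair_is_purifying(self):
        a = "GAAGAAGAAGGA" * 5
        b = "GAGGAAGAAGGA" * 5   # one synonymous change per repeat
        r = kaks(CodonPair("a", "b", a, b))
        assert r.Ks > 0 and r.Ka == 0.0 and r.omega == 0.0
        assert r.selection == "purifying"

    def test_saturation_flag_instead_of_exception(self):
        # serine repeats: TCT vs AGC differ everywhere -> pn at the JC bound
        r = kaks(CodonPair("a", "b", "TCT" * 20, "AGC" * 20))
        assert r.saturated
        assert r.Ka is None or r.Ks is None

    def test_neutrality_band_is_configurable(self):
        r = kaks(CodonPair("a", "b", "GAA" * 30, "GAA" * 30), neutral_band=0.05)
        assert r.selection is None
        # one synonymous + one nonsynonymous change on a 60-codon backbone
        a = "AAATTT" * 30
        b = "AAGCTT" + "AAATTT" * 29
        narrow = kaks(CodonPair("a", "b", a, b), neutral_band=0.05)
        wide = kaks(CodonPair("a", "b", a, b), neutral_band=0.95)
        assert narrow.omega == wide.omega and 0 < narrow.omega < 1
        assert narrow.selection == "purifying"
        assert wide.selection == "neutral"

    def test_gap_columns_dropped_and_terminal_stop_stripped(self):
        pair = CodonPair.from_aligned("a", "b", "GAA---GCTTAA", "GAAGTA---TAA")
        assert pair.cds_a == "GAA" and pair.cds_b == "GAA"

    def test_internal_stop_in_pair_is_error(self):
        with pytest.raises(CodonError):
            CodonPair.from_aligned("a", "b", "GAATAAGAA", "GAAGAAGAA")

    def test_parameter_recovery_on_simulated_pair(self):
        pair, _ = make_codon_pair(0.2, 0.02, n_codons=300, seed=42)
        r = kaks(pair)
        assert abs(r.Ks - 0.2) <= 0.05
        assert r.omega < 1 and r.selection == "purifying"


class TestClock:
    def test_closed_form_values(self):
        assert divergence_time(0.0) == 0.0
        assert divergence_time(0.013) == pytest.approx(1.0)
        assert divergence_time(0.26) == pytest.approx(20.0)

    def test_linearity(self):
        for ks in (0.01, 0.1, 0.33):
            assert divergence_time(2 * ks) == pytest.approx(2 * divergence_time(ks))

    def test_negative_ks_rejected(self):
        with pytest.raises(CodonError):
            divergence_time(-0.1)

    def test_lambda_configurable(self):
        assert divergence_time(0.013, lam=1.3e-8) == pytest.approx(0.5)


class TestSimulator:
    def test_zero_target_gives_identical_pair(self):
        pair, truth = make_codon_pair(0.0, 0.0, 50, seed=1)
        assert pair.cds_a == pair.cds_b
        assert truth["n_syn_applied"] == truth["n_nonsyn_applied"] == 0

    def test_truth_counts_recorded(self):
        _, truth = make_codon_pair(0.3, 0.1, 200, seed=2)
        assert truth["n_syn_applied"] > 0 and truth["n_nonsyn_applied"] > 0

    def test_invalid_targets_rejected(self):
        from zfsurvey.errors import SpecError

        with pytest.raises(SpecError):
            make_codon_pair(-0.1, 0.0, 100, seed=0)
        with pytest.raises(SpecError):
            make_codon_pair(math.inf, 0.0, 100, seed=0)
        with pytest.raises(SpecError):
            make_codon_pair(0.1, 0.0, 5, seed=0)

    def test_omega_below_one_when_ka_is_zero(self):
        hits = 0
        for seed in range(40):
            pair, _ = make_codon_pair(0.1, 0.0, 300, seed=seed)
            r = kaks(pair)
            if r.omega is not None and r.omega < 1:
                hits += 1
        assert hits >= 38
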