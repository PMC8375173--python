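"""Finger detection against an exhaustive-enumeration oracle, typing cascade,
and planted-domain recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import oracle_scan
from zfsurvey.sequence_io import ProteinRecord
from zfsurvey.synthetic_data import ProteinSpec, make_protein
from zfsurvey.zf_scan import ScanParams, scan_domains

PARAMS = ScanParams()
ALPHABET = "ACHQLGFS"


def scan(seq: str, params=PARAMS):
    return scan_domains(ProteinRecord.from_parts("t", seq), params)


class TestScanExamples:
    def test_canonical_q_type(self):
        (d,) = scan("MKCAECGKAFSQKQALGGHLRSHIRT")
        assert (d.c1, d.c2, d.h1, d.h2) == (2, 5, 18, 22)
        assert d.spacing == 12 and d.window == "QALGGH" and d.mismatches == 0
        assert d.dtype == "Q"

    def test_no_cysteines_no_domains(self):
        assert scan("MKAAAAAAAA") == []

    def test_sequence_shorter_than_a_finger(self):
        assert scan("MKC") == []

    def test_single_substitution_is_m1(self):
        (d,) = scan("MKCAECGKAFSQKRALGGHLRSHIRT")
        assert d.dtype == "M1" and d.mismatches == 1

    def test_degenerate_window_short_spacing_is_z2(self):
        # spacing 9 between Cys2 and His1, window shares nothing with QALGGH
        (d,) = scan("MKCAECGKAFSWKSNHSIKHAA")
        assert d.spacing == 9 and d.dtype == "Z2"

    def test_missing_second_histidine_is_d_type(self):
        (d,) = scan("MKCAECGKAFSQKQALGGHLRS")
        assert d.dtype == "D" and d.h2 is None and d.h1 == 18

    def test_x_never_matches_a_ligand(self):
        # replace the first cysteine with X: no full unit remains
        domains = scan("MKXAECGKAFSQKQALGGHLRSHIRT")
        assert all(d.c1 != 2 for d in domains)


class TestOracleEquivalence:
    def _assert_equal(self, seq: str, params=PARAMS):
        got = [(d.c1, d.c2, d.h1, d.h2) for d in scan(seq, params)]
        assert got == oracle_scan(seq, params), seq

    def test_seeded_random_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(400):
            n = int(rng.integers(5, 41))
            seq = "".join(rng.choice(list(ALPHABET), size=n))
            self._assert_equal(seq)

    def test_longer_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            seq = "".join(rng.choice(list(ALPHABET), size=200))
            self._assert_equal(seq)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=40))
    def test_property_restricted_alphabet(self, seq):
        self._assert_equal(seq)

    def test_strict_consensus_mode_agrees_with_oracle(self):
        params = ScanParams(require_FL=True)
        rng = np.random.default_rng(5)
        for _ in range(200):
            seq = "".join(rng.choice(list(ALPHABET), size=int(rng.integers(10, 41))))
            self._assert_equal(seq, params)


TYPE_POOL = ("Q", "M1", "M2", "M3", "M4", "Z1", "Z2", "D")


def random_spec(rng, index):
    n = int(rng.integers(1, 5))
    types = [str(rng.choice(TYPE_POOL)) for _ in range(n)]
    min_gap_after_d = {"Q": 2, "M1": 2, "M2": 2, "M3": 2, "M4": 2,
                       "Z1": 0, "Z2": 5, "D": 1}
    gaps = []
    for i in range(n - 1):
        lo = min_gap_after_d[types[i + 1]] if types[i] == "D" else 0
        gaps.append(int(rng.integers(lo, 41)))
    return ProteinSpec(
        protein_id=f"s{index}", domain_types=tuple(types), gaps=tuple(gaps),
        n_flank=int(rng.integers(0, 21)), c_flank=int(rng.integers(0, 21)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


class TestPlantedRecovery:
    def test_planted_domains_recovered_exactly(self):
        rng = np.random.default_rng(11)
        for i in range(300):
            spec = random_spec(rng, i)
            record, truth, _ = make_protein(spec)
            scanned = scan_domains(record)
            assert [(d.start, d.end, d.dtype) for d in scanned] == [
                (d.start, d.end, d.dtype) for d in truth
            ], spec

    def test_same_seed_reproducible_different_seed_same_structure(self):
        spec = ProteinSpec("p.1", ("Q", "Z1"), (13,), seed=3)
        rec_a, truth_a, _ = make_protein(spec)
        rec_b, truth_b, _ = make_protein(spec)
        assert rec_a.sequence == rec_b.sequence
        from dataclasses import replace
        rec_c, truth_c, _ = make_protein(replace(spec, seed=4))
        assert rec_c.sequence != rec_a.sequence
        assert [(d.start, d.dtype) for d in truth_c] == [
            (d.start, d.dtype) for d in truth_a
        ]


class TestTypingInvariants:
    def test_every_domain_gets_exactly_one_type(self):
        rng = np.random.default_rng(23)
        labels = {"Q", "M1", "M2", "M3", "M4", "Z1", "Z2", "D"}
        for _ in range(100):
            seq = "".join(rng.choice(list(ALPHABET), size=120))
            for d in scan(seq):
                assert d.dtype in labels

    def test_m_ceiling_monotone_and_q_d_stable(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            seq = "".join(rng.choice(list(ALPHABET), size=150))
            by_ceiling = {
                k: scan(seq, ScanParams(m_max_mismatch=k)) for k in (1, 2, 3, 4)
            }
            counts = {
                k: sum(d.dtype.startswith("M") for d in doms)
                for k, doms in by_ceiling.items()
            }
            assert counts[1] <= counts[2] <= counts[3] <= counts[4]
            for k in (2, 3, 4):
                q_d = lambda doms: [(d.start, d.dtype) for d in doms
                                    if d.dtype in ("Q", "D")]
                assert q_d(by_ceiling[k]) == q_d(by_ceiling[1])

    def test_q_requires_intact_window_and_spacing_12(self):
        for d in scan("MKCAECGKAFSQKQALGGHLRSHIRT"):
            assert (d.dtype == "Q") == (d.mismatches == 0 and d.spacing == 12)

    def test_bad_spacing_bounds_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(spacing_min=13)
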