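"""Expression grouping, filtering, level calls and 2^-ddCT quantification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from zfsurvey.errors import ExpressionError
from zfsurvey.expression import (
    STAGE_CODES,
    categorize_levels,
    cluster_groups,
    ddct_table,
    expressed_filter,
    fold_change_ddct,
    log_transform,
)
from zfsurvey.synthetic_data import make_expression


def tpm_matrix(rows, columns=None):
    columns = columns or list(STAGE_CODES)
    return pd.DataFrame(rows, columns=columns,
                        index=[f"g{i}" for i in range(len(rows))])


class TestLogTransform:
    def test_values(self):
        m = tpm_matrix([[0.0] * 15, [1.0] * 15, [3.0] * 15])
        logm = log_transform(m)
        assert logm.iloc[0, 0] == 0.0
        assert logm.iloc[1, 0] == 1.0
        assert logm.iloc[2, 0] == 2.0

    def test_monotone_and_invertible(self):
        values = np.linspace(0, 50, 25)
        m = tpm_matrix([values], columns=[f"S{i}" for i in range(25)])
        logm = log_transform(m)
        assert (np.diff(logm.values[0]) > 0).all()
        back = 2.0 ** logm.values - 1.0
        assert back == pytest.approx(m.values)

    def test_negative_input_rejected(self):
        with pytest.raises(ExpressionError):
            log_transform(tpm_matrix([[-1.0] * 15]))


class TestExpressedFilter:
    def test_all_zero_gene_removed_and_boundary_kept(self):
        m = tpm_matrix([[0.0] * 15, [0.5] + [0.0] * 14, [0.49] + [0.0] * 14])
        kept = expressed_filter(m)
        assert list(kept.index) == ["g1"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        m = tpm_matrix(rng.uniform(0, 2, size=(30, 15)))
        previous = None
        for min_tpm in (0.1, 0.5, 1.0, 1.5):
            kept = set(expressed_filter(m, min_tpm=min_tpm).index)
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestClustering:
    def test_separated_constant_levels_give_ordered_singletons(self):
        m = tpm_matrix([[100.0] * 15, [0.0] * 15, [10.0] * 15, [1000.0] * 15,
                        [1.0] * 15])
        ga = cluster_groups(m, k=5)
        assert ga.groups.tolist() == [4, 1, 3, 5, 2]
        means = [ga.group_means[g] for g in sorted(ga.group_means)]
        assert means == sorted(means)

    def test_duplicate_rows_share_a_group(self):
        m = tpm_matrix([[5.0] * 15, [5.0] * 15, [100.0] * 15, [0.1] * 15,
                        [40.0] * 15, [0.6] * 15])
        ga = cluster_groups(m, k=5)
        assert ga.groups["g0"] == ga.groups["g1"]

    def test_zero_noise_planted_groups_recovered_exactly(self):
        profiles = [[level] * 15 for level in (0.5, 2.5, 4.5, 6.5, 8.5)]
        m, labels = make_expression([6, 7, 8, 9, 10], profiles, sigma=0.0, seed=0)
        ga = cluster_groups(m, k=5)
        assert (ga.groups == labels).all()

    def test_default_noise_high_agreement(self):
        profiles = [[level] * 15 for level in (0.5, 2.5, 4.5, 6.5, 8.5)]
        m, labels = make_expression([20, 20, 20, 20, 20], profiles,
                                    sigma=0.3, seed=1)
        ga = cluster_groups(m, k=5)
        assert adjusted_rand_score(labels, ga.groups) >= 0.9

    def test_permutation_stable_up_to_relabel(self):
        profiles = [[level] * 15 for level in (0.5, 3.0, 6.0)]
        m, _ = make_expression([8, 8, 8], profiles, sigma=0.2, seed=3)
        ga = cluster_groups(m, k=3)
        rng = np.random.default_rng(5)
        shuffled = m.iloc[rng.permutation(len(m))]
        gb = cluster_groups(shuffled, k=3)
        assert (gb.groups.reindex(ga.groups.index) == ga.groups).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ExpressionError):
            cluster_groups(tpm_matrix([[1.0] * 15] * 3), k=5)


class TestLevels:
    def test_level_boundaries(self):
        m = tpm_matrix([[0.2] * 15, [3.0] * 15, [7.0] * 15])
        calls = categorize_levels(m)   # already on log2 scale by construction
        assert set(calls.loc["g0"]) == {"low"}
        assert set(calls.loc["g1"]) == {"moderate"}
        assert set(calls.loc["g2"]) == {"high"}

    def test_organ_means_drive_the_call(self):
        row = [0.2] * 3 + [3.0] * 12   # low in root, moderate elsewhere
        calls = categorize_levels(tpm_matrix([row]))
        assert calls.loc["g0", "root"] == "low"
        assert calls.loc["g0", "leaf"] == "moderate"

    def test_unknown_stage_code_is_error(self):
        m = tpm_matrix([[1.0] * 15],
                       columns=[f"BAD{i}" for i in range(15)])
        with pytest.raises(ExpressionError):
            categorize_levels(m)


class TestDdct:
    def test_worked_example(self):
        r = fold_change_ddct(24, 20, 26, 20)
        assert r.ddct == -2 and r.fold_change == 4.0

    def test_identity_when_deltas_equal(self):
        for a, b in [(20, 18), (30, 25), (22.5, 22.5)]:
            r = fold_change_ddct(a, b, a, b)
            assert r.ddct == 0 and r.fold_change == 1.0

    def test_positive_ddct_halves_expression(self):
        assert fold_change_ddct(25, 20, 24, 20).fold_change == 0.5

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ExpressionError):
            fold_change_ddct(0, 20, 24, 20)

    def test_long_table(self):
        table = pd.DataFrame([
            {"sample": "leaf", "gene": "g1", "ct_target": 26.0,
             "ct_reference": 20.0, "condition": "control"},
            {"sample": "leaf", "gene": "g1", "ct_target": 24.0,
             "ct_reference": 20.0, "condition": "heat"},
        ])
        out = ddct_table(table)
        assert len(out) == 1
        assert out.loc[0, "fold_change"] == 4.0
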