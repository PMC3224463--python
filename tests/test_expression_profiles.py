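"""Expression calling, resampling, τ, ratios, and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrscape.expression_profiles import (
    CallPolicy,
    ExpressionMatrix,
    ResamplingConfig,
    assign_probes,
    call_expressed,
    compare_distributions,
    constitutive_ratio,
    read_expression_tsv,
    replicate_summaries,
    sample_tissues,
    tau,
    tau_matrix,
    write_expression_tsv,
)


class TestTau:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((5, 5, 5, 5), 0.0),  # uniform expression
            ((0, 0, 0, 7), 1.0),  # single-tissue expression
            ((8, 4, 2, 2), 2 / 3),  # (0 + .5 + .75 + .75)/3
        ],
    )
    def test_examples(self, values, expected):
        assert tau(values) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6), min_size=2, max_size=12).filter(
            lambda v: max(v) > 0
        ),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_bounds(self, values, c):
        t = tau(values)
        assert 0.0 <= t <= 1.0
        assert tau([c * v for v in values]) == pytest.approx(t, rel=1e-9)

    def test_moving_mass_to_max_never_decreases_tau(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 100, size=8)
            i_max = int(np.argmax(x))
            i_low = int(np.argmin(x))
            if i_max == i_low:
                continue
            y = x.copy()
            shift = y[i_low] * rng.uniform(0, 1)
            y[i_low] -= shift
            y[i_max] += shift
            assert tau(y) >= tau(x) - 1e-12

    def test_negative_values_clipped(self):
        assert tau([-5, 0, 0, 7]) == 1.0

    def test_all_zero_undefined(self):
        assert math.isnan(tau([0, 0, 0]))

    def test_too_few_tissues(self):
        with pytest.raises(ValueError):
            tau([1.0])

    def test_matrix_agrees_with_scalar(self, rng):
        x = rng.uniform(0, 50, size=(30, 6))
        x[3] = 0.0
        got = tau_matrix(x)
        for i, row in enumerate(x):
            if row.max() <= 0:
                assert math.isnan(got[i])
            else:
                assert got[i] == pytest.approx(tau(row))


def make_intensity(values, genes=None, tissues=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        gene_ids=genes, tissue_labels=tissues, mode="intensity", values=values
    )


class TestCallExpressed:
    def test_strictly_greater_than_cutoff(self):
        m = make_intensity([[200.0, 200.0001, 199.9]])
        out = call_expressed(m, CallPolicy(mode="intensity", cutoff=200))
        assert out.tolist() == [[False, True, False]]

    def test_present_call_threshold(self):
        calls = np.array([[[1, 1, 1, 0], [1, 1, 0, 0]]], dtype=bool)
        m = ExpressionMatrix(
            gene_ids=["g"], tissue_labels=["a", "b"], mode="calls", calls=calls
        )
        out = call_expressed(m, CallPolicy(mode="calls", min_calls=3))
        assert out.tolist() == [[True, False]]

    def test_mode_mismatch(self):
        m = make_intensity([[1.0, 2.0]])
        with pytest.raises(ValueError):
            call_expressed(m, CallPolicy(mode="calls"))

    def test_all_zero_matrix(self):
        m = make_intensity(np.zeros((3, 4)))
        assert not call_expressed(m, CallPolicy(mode="intensity")).any()


class TestSampleTissues:
    def test_k_equals_all(self):
        subsets = sample_tissues(list("abcd"), ResamplingConfig(4, 10, seed=0))
        assert all(set(s) == set("abcd") for s in subsets)

    def test_seeded_determinism(self):
        cfg = ResamplingConfig(3, 20, seed=42)
        assert sample_tissues(list("abcdefg"), cfg) == sample_tissues(list("abcdefg"), cfg)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            sample_tissues(list("ab"), ResamplingConfig(3, 1, seed=0))

    def test_inclusion_frequency_binomial(self):
        labels = [f"t{i}" for i in range(17)]
        subsets = sample_tissues(labels, ResamplingConfig(10, 1000, seed=3))
        p = 10 / 17
        se = math.sqrt(p * (1 - p) / 1000)
        for lbl in labels:
            freq = sum(lbl in s for s in subsets) / 1000
            assert abs(freq - p) < 3 * se + 1e-12


class TestConstitutiveRatio:
    def test_balanced(self):
        grid = np.array([[1, 1], [1, 1], [1, 0], [0, 1]], dtype=bool)
        n_con, n_noncon, ratio = constitutive_ratio(grid)
        assert (n_con, n_noncon) == (2, 2)
        assert ratio == 0.0

    def test_all_constitutive_undefined_direction(self):
        grid = np.ones((3, 4), dtype=bool)
        n_con, n_noncon, ratio = constitutive_ratio(grid)
        assert (n_con, n_noncon) == (3, 0)
        assert ratio == -math.inf  # log2 of an empty numerator

    def test_no_constitutive_flagged_undefined(self):
        grid = np.array([[1, 0], [0, 1]], dtype=bool)
        _, _, ratio = constitutive_ratio(grid)
        assert math.isnan(ratio)

    def test_matches_bruteforce_on_random_grid(self, rng):
        grid = rng.random((20, 10)) < 0.9
        n_con = n_noncon = 0
        for row in grid:  # naive per-gene recount
            k = row.sum()
            if k == 10:
                n_con += 1
            elif k > 0:
                n_noncon += 1
        got = constitutive_ratio(grid)
        assert got[:2] == (n_con, n_noncon)
        assert got[2] == pytest.approx(math.log2(n_noncon / n_con))

    def test_gene_order_invariance(self, rng):
        grid = rng.random((25, 6)) < 0.6
        perm = rng.permutation(25)
        assert constitutive_ratio(grid) == constitutive_ratio(grid[perm])


class TestAssignProbes:
    CDNAS = [("geneA", "AAACCCGGGTTT"), ("geneB", "TTTGGGCCCAAA")]

    def test_multi_gene_probe_excluded(self):
        probes = [("p1", "CCC")]  # occurs in both cDNAs
        expr = pd.DataFrame({"t1": [5.0]}, index=["p1"])
        assert assign_probes(probes, self.CDNAS, expr) == {}

    def test_highest_row_sum_wins(self):
        probes = [("p1", "AAACCC"), ("p2", "CCCGGG")]
        expr = pd.DataFrame({"t1": [10.0, 50.0], "t2": [0.0, 0.0]}, index=["p1", "p2"])
        assert assign_probes(probes, self.CDNAS, expr) == {"geneA": "p2"}

    def test_mismatch_excluded(self):
        probes = [("p1", "AAACCA")]  # one mismatch: not a substring
        expr = pd.DataFrame({"t1": [5.0]}, index=["p1"])
        assert assign_probes(probes, self.CDNAS, expr) == {}

    def test_tie_broken_lexicographically(self):
        probes = [("p2", "AAACCC"), ("p1", "CCCGGG")]
        expr = pd.DataFrame({"t1": [7.0, 7.0]}, index=["p2", "p1"])
        assert assign_probes(probes, self.CDNAS, expr) == {"geneA": "p1"}


class TestCompareDistributions:
    def test_identical_multisets(self):
        u, p = compare_distributions([1, 2, 2, 3], [1, 2, 2, 3])
        assert p > 0.99

    def test_complete_separation(self):
        u, p = compare_distributions([1, 2, 3], [10, 20, 30])
        assert u == 0.0

    def test_exact_matches_permutation_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(loc=0.8, size=5)
        u_obs, p_got = compare_distributions(a, b)
        # exhaustive oracle over all C(10,5) group assignments
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1.0
        mn = 25
        count = total = 0
        dev_obs = abs((ranks[:5].sum() - 15) - mn / 2)
        for combo in itertools.combinations(range(10), 5):
            u = ranks[list(combo)].sum() - 15
            total += 1
            if abs(u - mn / 2) >= dev_obs - 1e-12:
                count += 1
        assert p_got == pytest.approx(count / total, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestReplicateSummaries:
    def test_single_rep_full_tissues_equals_direct_computation(self):
        values = np.array(
            [[300.0, 300.0, 300.0], [500.0, 100.0, 100.0], [10.0, 10.0, 10.0]]
        )
        m = make_intensity(values, genes=["g0", "g1", "g2"])
        policy = CallPolicy(mode="intensity", cutoff=200)
        lengths = {"g0": 50.0, "g1": 150.0, "g2": 999.0}
        (s,) = replicate_summaries(
            m, policy, ResamplingConfig(k_tissues=3, n_reps=1, seed=0), lengths
        )
        # g2 never expressed -> excluded; g0 constitutive, g1 non-constitutive
        assert (s.n_constitutive, s.n_nonconstitutive) == (1, 1)
        assert s.log2_ratio == 0.0
        expected_tau = np.mean([tau(values[0]), tau(values[1])])
        assert s.mean_tau == pytest.approx(expected_tau)
        assert s.median_utr_bp == 100.0

    def test_seeded_determinism(self, small_panel):
        sp = small_panel.species[0]
        m = small_panel.expression[sp]
        policy = CallPolicy(mode="intensity")
        lengths = {g: 100.0 for g in m.gene_ids}
        cfg = ResamplingConfig(k_tissues=5, n_reps=20, seed=77)
        assert replicate_summaries(m, policy, cfg, lengths) == replicate_summaries(
            m, policy, cfg, lengths
        )

    def test_no_gene_overlap_is_error(self):
        m = make_intensity([[300.0, 1.0]])
        with pytest.raises(ValueError):
            replicate_summaries(
                m,
                CallPolicy(mode="intensity"),
                ResamplingConfig(2, 1, 0),
                {"other": 5.0},
            )


def test_expression_tsv_round_trip(tmp_path, rng):
    m = make_intensity(rng.uniform(0, 1000, size=(6, 4)))
    write_expression_tsv(m, tmp_path / "i.tsv")
    back = read_expression_tsv(tmp_path / "i.tsv")
    assert back.mode == "intensity"
    np.testing.assert_allclose(back.values, m.values)
    calls = rng.random((5, 3, 4)) < 0.5
    mc = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        tissue_labels=["x", "y", "z"],
        mode="calls",
        calls=calls,
    )
    write_expression_tsv(mc, tmp_path / "c.tsv")
    back = read_expression_tsv(tmp_path / "c.tsv")
    assert back.mode == "calls" and back.n_replicates == 4
    np.testing.assert_array_equal(back.calls, calls)
    assert back.tissue_labels == ["x", "y", "z"]
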