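"""Catalogue counting, NMF recovery, cosine matching, QP refit and pruning.

The refit is cross-checked against a dense simplex grid search, and the
pruning rule against hand-iterated applications of the <10% rule.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from somascape.signatures import (
    build_snv_catalogue,
    extract_signatures_nmf,
    match_signatures_cosine,
    prune_and_reassign,
    refit_exposure_matrix,
    refit_exposures,
)
from somascape.simulate import reference_signatures, simulate_snvs
from somascape.types import SignatureSet, SnvRecord


def grid_refit(m, S, step=0.01):
    """Simplex grid-search oracle for the 3-signature refit problem."""
    m = np.asarray(m, dtype=float)
    m = m / m.sum()
    best, best_obj = None, np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for a, b in itertools.product(ticks, ticks):
        if a + b > 1 + 1e-12:
            continue
        e = np.array([a, b, 1 - a - b])
        obj = float(np.sum((m - e @ S) ** 2))
        if obj < best_obj:
            best, best_obj = e, obj
    return best, best_obj


class TestCatalogue:
    def test_single_record_lands_in_its_channel(self):
        r = SnvRecord("S1", "chr1", 100, "C", "T", "ACA", "C>T")
        cat = build_snv_catalogue([r], ["S1"])
        assert cat.loc["S1", "A[C>T]A"] == 1
        assert cat.loc["S1"].sum() == 1

    def test_duplicate_records_accumulate(self):
        r = SnvRecord("S1", "chr1", 100, "C", "T", "ACA", "C>T")
        cat = build_snv_catalogue([r, r], ["S1"])
        assert cat.loc["S1", "A[C>T]A"] == 2

    def test_zero_rows_for_empty_samples_and_conservation(self, toy_genome, ref_sigs):
        recs = simulate_snvs(toy_genome, ref_sigs, [0.25] * 4, 1_000, seed=1)
        cat = build_snv_catalogue(recs, ["S1", "S2"])
        assert cat.loc["S1"].sum() == 1_000
        assert cat.loc["S2"].sum() == 0

    def test_unknown_sample_rejected(self):
        r = SnvRecord("SX", "chr1", 100, "C", "T", "ACA", "C>T")
        with pytest.raises(KeyError):
            build_snv_catalogue([r], ["S1"])


class TestNmf:
    def test_planted_factorization_recovered(self, ref_sigs):
        rng = np.random.default_rng(0)
        E = rng.dirichlet(np.ones(4), size=25)
        X = 5_000 * E @ ref_sigs.profiles.to_numpy()
        cat = pd.DataFrame(X, index=[f"s{i}" for i in range(25)],
                           columns=ref_sigs.channels)
        sigs, expo, err = extract_signatures_nmf(cat, 4, n_restarts=10, seed=1)
        assert err <= 1e-3
        A = sigs.profiles.to_numpy()
        B = ref_sigs.profiles.to_numpy()
        C = (A / np.linalg.norm(A, axis=1, keepdims=True)) @ (
            B / np.linalg.norm(B, axis=1, keepdims=True)
        ).T
        r, c = linear_sum_assignment(-C)
        assert C[r, c].min() >= 0.99

    def test_rank_one_catalogue(self, ref_sigs):
        row = ref_sigs.profiles.iloc[0].to_numpy()
        cat = pd.DataFrame(np.outer([100, 200, 400], row),
                           index=list("abc"), columns=ref_sigs.channels)
        sigs, _, err = extract_signatures_nmf(cat, 1, n_restarts=5, seed=2)
        cos = sigs.profiles.iloc[0] @ row / (
            np.linalg.norm(sigs.profiles.iloc[0]) * np.linalg.norm(row)
        )
        assert cos >= 0.9999

    def test_deterministic_for_fixed_seed(self, ref_sigs):
        rng = np.random.default_rng(3)
        cat = pd.DataFrame(rng.poisson(20, size=(10, 96)).astype(float),
                           index=[f"s{i}" for i in range(10)],
                           columns=ref_sigs.channels)
        a = extract_signatures_nmf(cat, 3, n_restarts=3, seed=9)
        b = extract_signatures_nmf(cat, 3, n_restarts=3, seed=9)
        pd.testing.assert_frame_equal(a[0].profiles, b[0].profiles)

    def test_zero_catalogue_rejected(self, ref_sigs):
        cat = pd.DataFrame(np.zeros((3, 96)), columns=ref_sigs.channels)
        with pytest.raises(ValueError):
            extract_signatures_nmf(cat, 2, n_restarts=1, seed=0)


class TestCosineMatch:
    def test_self_match_is_one(self, ref_sigs):
        table = match_signatures_cosine(ref_sigs, ref_sigs)
        assert np.allclose(table["cosine"], 1.0)
        assert list(table["reference"]) == ref_sigs.names

    def test_orthogonal_one_hots(self):
        channels = [f"c{i}" for i in range(96)]
        a = np.zeros((1, 96)); a[0, 0] = 1
        b = np.zeros((1, 96)); b[0, 1] = 1
        sa = SignatureSet(pd.DataFrame(a, index=["x"], columns=channels))
        sb = SignatureSet(pd.DataFrame(b, index=["y"], columns=channels))
        assert match_signatures_cosine(sa, sb)["cosine"].iloc[0] == 0.0

    def test_mixture_cosine_matches_hand_formula(self, ref_sigs):
        p = ref_sigs.profiles.to_numpy()
        mix = 0.9 * p[0] + 0.1 * p[1]
        mixed = SignatureSet(pd.DataFrame([mix / mix.sum()], index=["m"],
                                          columns=ref_sigs.channels))
        table = match_signatures_cosine(mixed, ref_sigs)
        expected = mix @ p[0] / (np.linalg.norm(mix) * np.linalg.norm(p[0]))
        assert table["cosine"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, ref_sigs):
        other = reference_signatures(2, seed=1, channels=[f"c{i}" for i in range(32)])
        with pytest.raises(ValueError):
            match_signatures_cosine(ref_sigs, other)


class TestRefit:
    def test_pure_signature_row(self, ref_sigs):
        e, obj = refit_exposures(100 * ref_sigs.profiles.iloc[2].to_numpy(), ref_sigs)
        assert e[2] == pytest.approx(1.0, abs=1e-6)
        assert obj == pytest.approx(0.0, abs=1e-10)

    def test_exact_two_signature_mixture(self, ref_sigs):
        p = ref_sigs.profiles.to_numpy()
        e, _ = refit_exposures(0.7 * p[0] + 0.3 * p[1], ref_sigs)
        assert e == pytest.approx([0.7, 0.3, 0.0, 0.0], abs=1e-6)

    def test_zero_row_flagged(self, ref_sigs):
        e, obj = refit_exposures(np.zeros(96), ref_sigs)
        assert (e == 0).all() and np.isnan(obj)

    def test_agrees_with_grid_oracle(self):
        sigs3 = reference_signatures(3, seed=8)
        S = sigs3.profiles.to_numpy()
        rng = np.random.default_rng(4)
        for _ in range(5):
            m = rng.poisson(rng.dirichlet(np.ones(96)) * 500) + 0.0
            if m.sum() == 0:
                continue
            e, obj = refit_exposures(m, sigs3)
            e_grid, obj_grid = grid_refit(m, S)
            assert np.abs(e - e_grid).max() <= 0.02  # within grid resolution
            assert obj <= obj_grid + 1e-9


class TestPruneAndReassign:
    def _two_sig(self):
        return reference_signatures(2, seed=12)

    def test_sub_threshold_signature_dropped(self):
        sigs = self._two_sig()
        p = sigs.profiles.to_numpy()
        counts = 1000 * (0.95 * p[0] + 0.05 * p[1])
        cat = pd.DataFrame([counts], index=["S1"], columns=sigs.channels)
        expo = refit_exposure_matrix(cat, sigs)
        pruned = prune_and_reassign(expo, cat, sigs, threshold=0.10)
        assert pruned.loc["S1"].tolist() == pytest.approx([1.0, 0.0], abs=1e-9)

    def test_fixed_point_when_all_above_threshold(self):
        sigs = self._two_sig()
        p = sigs.profiles.to_numpy()
        cat = pd.DataFrame([1000 * (0.6 * p[0] + 0.4 * p[1])], index=["S1"],
                           columns=sigs.channels)
        expo = refit_exposure_matrix(cat, sigs)
        pruned = prune_and_reassign(expo, cat, sigs)
        pd.testing.assert_frame_equal(pruned, expo, atol=1e-9, check_exact=False)

    def test_iterates_to_threshold_or_single_signature(self):
        sigs3 = reference_signatures(3, seed=13)
        p = sigs3.profiles.to_numpy()
        cat = pd.DataFrame([2000 * (0.08 * p[0] + 0.09 * p[1] + 0.83 * p[2])],
                           index=["S1"], columns=sigs3.channels)
        expo = refit_exposure_matrix(cat, sigs3)
        pruned = prune_and_reassign(expo, cat, sigs3)
        row = pruned.loc["S1"].to_numpy()
        retained = row[row > 0]
        assert (retained >= 0.10).all() or retained.size == 1
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_stay_on_simplex(self, draw_seed):
        sigs3 = reference_signatures(3, seed=14)
        rng = np.random.default_rng(draw_seed)
        e_true = rng.dirichlet(np.ones(3))
        counts = np.round(3000 * e_true @ sigs3.profiles.to_numpy())
        cat = pd.DataFrame([counts], index=["S1"], columns=sigs3.channels)
        expo = refit_exposure_matrix(cat, sigs3)
        pruned = prune_and_reassign(expo, cat, sigs3)
        row = pruned.loc["S1"].to_numpy()
        assert (row >= -1e-12).all()
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
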