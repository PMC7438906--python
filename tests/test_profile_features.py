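import numpy as np
import pytest

from enacp.composition_features import dr_encode, kmer_encode
from enacp.core import AA_INDEX
from enacp.profile_features import (
    Pssm,
    dt_encode,
    one_hot_pssm,
    pdt_profile_encode,
    pssm_covariance_encode,
    pssm_dt_encode,
    pssm_rt_encode,
    read_pssm,
    top_n_gram_encode,
    top_n_grams,
    write_pssm,
)
from enacp.seqio import PeptideRecord

import oracles
from conftest import random_records


def random_pssm(peptide_id, length, seed):
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.ones(20), size=length)
    return Pssm.from_frequencies(peptide_id, freqs)


class TestPssmIo:
    def test_write_read_roundtrip(self, tmp_path, rng):
        scores = rng.normal(scale=3, size=(5, 20)).round(3)
        pssm = Pssm.from_scores("p1", scores)
        path = tmp_path / "p1.pssm"
        write_pssm(pssm, path, sequence="ACDKF")
        back = read_pssm(path)
        np.testing.assert_allclose(back.scores, scores, atol=1e-9)
        np.testing.assert_allclose(back.frequencies, pssm.frequencies, atol=1e-9)

    def test_short_row_names_line_number(self, tmp_path):
        path = tmp_path / "bad.pssm"
        header = "    " + "  ".join("ACDEFGHIKLMNPQRSTVWY")
        row19 = "1 A " + " ".join(["0"] * 19)
        path.write_text("\n\n" + header + "\n" + row19 + "\n")
        with pytest.raises(ValueError, match="4"):
            read_pssm(path)

    def test_non_numeric_cell_is_error(self, tmp_path):
        path = tmp_path / "bad.pssm"
        header = "    " + "  ".join("ACDEFGHIKLMNPQRSTVWY")
        row = "1 A " + " ".join(["0"] * 19 + ["oops"])
        path.write_text("\n\n" + header + "\n" + row + "\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_pssm(path)

    def test_parsed_frequencies_row_stochastic(self, tmp_path, rng):
        pssm = Pssm.from_scores("q", rng.integers(-8, 9, size=(12, 20)))
        path = tmp_path / "q.pssm"
        write_pssm(pssm, path)
        back = read_pssm(path)
        np.testing.assert_allclose(back.frequencies.sum(axis=1), 1.0, atol=1e-9)


class TestTopNGram:
    def test_one_hot_recovers_sequence_and_composition(self):
        rec = PeptideRecord("p", "ACDKFWYACD")
        pssm = one_hot_pssm(rec)
        assert [g[0] for g in top_n_grams(pssm, 1)] == list(rec.sequence)
        got = top_n_gram_encode(pssm, n=1, normalize=False).values
        np.testing.assert_array_equal(
            got, kmer_encode(rec, k=1, normalize=False).values)

    def test_tied_argmax_counts_twice(self):
        freqs = np.zeros((2, 20))
        freqs[:, AA_INDEX["C"]] = 0.5
        freqs[:, AA_INDEX["W"]] = 0.5
        pssm = Pssm.from_frequencies("t", freqs)
        # tie broken alphabetically -> C at both positions
        v = top_n_gram_encode(pssm, n=1, normalize=False)
        assert v.values[AA_INDEX["C"]] == 2

    @pytest.mark.parametrize("n", [1, 2])
    def test_matches_sort_and_tally_oracle(self, n):
        for seed in range(5):
            pssm = random_pssm(f"r{seed}", 15, seed)
            got = top_n_gram_encode(pssm, n=n, normalize=True).values
            expected = oracles.naive_top_n_gram_counts(
                pssm.frequencies.tolist(), n, True)
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestDt:
    def test_one_hot_reduces_to_dr_pair_blocks(self):
        rec = PeptideRecord("p", "ACDKFWYACDKF")
        got = dt_encode(one_hot_pssm(rec), n=1, dmax=3, normalize=False).values
        dr = dr_encode(rec, dmax=3, normalize=False).values[20:]
        np.testing.assert_array_equal(got, dr)

    def test_dmax_at_least_length_raises(self):
        pssm = one_hot_pssm(PeptideRecord("p", "ACD"))
        with pytest.raises(ValueError, match="dmax"):
            dt_encode(pssm, n=1, dmax=3)

    def test_matches_pair_loop_oracle(self):
        pssm = random_pssm("r", 12, 3)
        got = dt_encode(pssm, n=1, dmax=2, normalize=True).values
        expected = oracles.naive_dt(pssm.frequencies.tolist(), 1, 2, True)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPdtProfile:
    def test_identical_rows_zero(self):
        freqs = np.full((8, 20), 1 / 20)
        v = pdt_profile_encode(Pssm.from_frequencies("u", freqs), dmax=2)
        assert np.allclose(v.values, 0)

    def test_two_one_hot_rows_closed_form(self):
        freqs = np.zeros((2, 20))
        freqs[0, 0] = 1.0
        freqs[1, 5] = 1.0
        v = pdt_profile_encode(Pssm.from_frequencies("c", freqs), dmax=1)
        assert v.values[0] == pytest.approx(0.1)  # 2/20

    def test_matches_double_loop_oracle(self):
        pssm = random_pssm("r", 14, 4)
        got = pdt_profile_encode(pssm, dmax=3).values
        expected = oracles.naive_pdt_profile(pssm.frequencies.tolist(), 3)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPssmCovariance:
    def test_uniform_profile_all_zero(self):
        freqs = np.full((10, 20), 1 / 20)
        pssm = Pssm.from_frequencies("u", freqs)
        assert np.allclose(pssm_covariance_encode(pssm, 2, "ACC").values, 0)

    def test_acc_concatenates_ac_then_cc(self):
        pssm = random_pssm("r", 12, 5)
        acc = pssm_covariance_encode(pssm, 2, "ACC").values
        ac_block = pssm_covariance_encode(pssm, 2, "AC").values
        cc_block = pssm_covariance_encode(pssm, 2, "CC").values
        np.testing.assert_array_equal(acc[:40], ac_block)
        np.testing.assert_array_equal(acc[40:], cc_block)
        assert acc.size == 800

    def test_matches_literal_formula_oracle(self):
        pssm = random_pssm("r", 10, 6)
        np.testing.assert_allclose(
            pssm_covariance_encode(pssm, 2, "AC").values,
            oracles.naive_pssm_ac(pssm.frequencies.tolist(), 2), atol=1e-12)
        np.testing.assert_allclose(
            pssm_covariance_encode(pssm, 2, "CC").values,
            oracles.naive_pssm_cc(pssm.frequencies.tolist(), 2), atol=1e-12)


class TestPssmDt:
    def test_one_hot_reduces_to_normalized_dr(self):
        rec = PeptideRecord("p", "ACDKFWYACDKF")
        got = pssm_dt_encode(one_hot_pssm(rec), dmax=2).values
        dr = dr_encode(rec, dmax=2, normalize=True).values[20:]
        np.testing.assert_allclose(got, dr, atol=1e-12)

    def test_uniform_rows_closed_form(self):
        freqs = np.full((9, 20), 1 / 20)
        v = pssm_dt_encode(Pssm.from_frequencies("u", freqs), dmax=2)
        np.testing.assert_allclose(v.values, 1 / 400, atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        pssm = random_pssm("r", 9, 7)
        got = pssm_dt_encode(pssm, dmax=2).values
        expected = oracles.naive_pssm_dt(pssm.frequencies.tolist(), 2)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPssmRt:
    def test_all_below_threshold_zero(self):
        pssm = Pssm.from_scores("z", np.full((8, 20), -5.0))
        assert np.allclose(pssm_rt_encode(pssm, 2, threshold=0.0).values, 0)

    def test_one_hot_binarization_reduces_to_dr(self):
        rec = PeptideRecord("p", "ACDKFWYACD")
        got = pssm_rt_encode(one_hot_pssm(rec), dmax=2, threshold=-1.0).values
        dr = dr_encode(rec, dmax=2, normalize=True).values[20:]
        np.testing.assert_allclose(got, dr, atol=1e-12)

    def test_matches_bruteforce_count(self, rng):
        scores = rng.normal(size=(11, 20))
        pssm = Pssm.from_scores("r", scores)
        got = pssm_rt_encode(pssm, dmax=2, threshold=0.3).values
        expected = oracles.naive_pssm_rt(scores.tolist(), 2, 0.3)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestBoundedness:
    def test_profile_features_bounded_for_row_stochastic_input(self):
        # all encoders on row-stochastic profiles stay within [-1, 1]
        for seed in range(10):
            pssm = random_pssm(f"b{seed}", 20, 100 + seed)
            for fv in (
                top_n_gram_encode(pssm, 1),
                pdt_profile_encode(pssm, 2),
                pssm_covariance_encode(pssm, 2, "ACC"),
                pssm_dt_encode(pssm, 2),
                pssm_rt_encode(pssm, 2),
            ):
                assert np.all(np.abs(fv.values) <= 1.0 + 1e-12)
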