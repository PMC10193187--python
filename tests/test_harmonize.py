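import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrkit.errors import ConfigurationError
from mrkit.estimators import wald_ratio
from mrkit.harmonize import harmonize, merge_multivariable

from conftest import make_table


def _pair(exp_rows, out_rows):
    return (make_table(exp_rows, trait_name="exp"),
            make_table(out_rows, trait_name="out", trait_type="binary",
                       unit="log odds"))


def test_allele_swap_flips_outcome_sign_and_frequency():
    exp, out = _pair([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}],
                     [{"effect_allele": "G", "other_allele": "A", "beta": -0.05,
                       "eaf": 0.7}])
    hset = harmonize(exp, out)
    inst = hset.instruments[0]
    assert inst.beta_out == pytest.approx(0.05)
    assert inst.eaf_out == pytest.approx(0.3)


def test_strand_complement_then_direct_match():
    exp, out = _pair([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}],
                     [{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
    hset = harmonize(exp, out)
    assert hset.instruments[0].beta_out == pytest.approx(0.05)


def test_strand_complement_then_swap():
    exp, out = _pair([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}],
                     [{"effect_allele": "C", "other_allele": "T", "beta": 0.05,
                       "eaf": 0.8}])
    inst = harmonize(exp, out).instruments[0]
    assert inst.beta_out == pytest.approx(-0.05)
    assert inst.eaf_out == pytest.approx(0.2)


def test_palindromic_excluded_unconditionally_by_default():
    exp, out = _pair([{"effect_allele": "A", "other_allele": "T", "beta": 0.10}],
                     [{"effect_allele": "A", "other_allele": "T", "beta": 0.05}])
    hset = harmonize(exp, out)
    assert len(hset) == 0
    assert hset.exclusions == [("rs1", "palindromic")]


def test_palindromic_maf_window_rescues_unambiguous_frequencies():
    exp, out = _pair([{"effect_allele": "A", "other_allele": "T", "beta": 0.10,
                       "eaf": 0.1}],
                     [{"effect_allele": "A", "other_allele": "T", "beta": 0.05,
                       "eaf": 0.88}])
    hset = harmonize(exp, out, palindromic_maf_window=0.3)
    # opposite frequency sides: coding flipped on the outcome side
    assert hset.instruments[0].beta_out == pytest.approx(-0.05)
    # near-0.5 frequencies stay ambiguous even with the window
    exp2, out2 = _pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.45}],
                       [{"effect_allele": "A", "other_allele": "T", "eaf": 0.52}])
    assert harmonize(exp2, out2, palindromic_maf_window=0.3).exclusions \
        == [("rs1", "palindromic")]


def test_twelve_variant_partition_covers_every_harmonization_case():
    exp_rows = [
        {"variant_id": "rs01", "effect_allele": "A", "other_allele": "G", "beta": 0.10},
        {"variant_id": "rs02", "effect_allele": "A", "other_allele": "G", "beta": 0.20},
        {"variant_id": "rs03", "effect_allele": "A", "other_allele": "G", "beta": 0.30},
        {"variant_id": "rs04", "effect_allele": "A", "other_allele": "G", "beta": 0.40},
        {"variant_id": "rs05", "effect_allele": "A", "other_allele": "T", "beta": 0.50},
        {"variant_id": "rs06", "effect_allele": "C", "other_allele": "G", "beta": 0.60},
        {"variant_id": "rs07", "effect_allele": "A", "other_allele": "G", "beta": 0.70},
        {"variant_id": "rs08", "effect_allele": "A", "other_allele": "G", "beta": 0.80},
        {"variant_id": "rs09", "effect_allele": "C", "other_allele": "T", "beta": 0.90},
        {"variant_id": "rs10", "effect_allele": "T", "other_allele": "C", "beta": 1.00},
        {"variant_id": "rs11", "effect_allele": "A", "other_allele": "G", "beta": 1.10},
    ]
    out_rows = [
        {"variant_id": "rs01", "effect_allele": "A", "other_allele": "G", "beta": 0.01},
        {"variant_id": "rs02", "effect_allele": "G", "other_allele": "A", "beta": 0.02},
        {"variant_id": "rs03", "effect_allele": "T", "other_allele": "C", "beta": 0.03},
        {"variant_id": "rs04", "effect_allele": "C", "other_allele": "T", "beta": 0.04},
        {"variant_id": "rs05", "effect_allele": "A", "other_allele": "T", "beta": 0.05},
        {"variant_id": "rs06", "effect_allele": "G", "other_allele": "C", "beta": 0.06},
        {"variant_id": "rs07", "effect_allele": "A", "other_allele": "C", "beta": 0.07},
        {"variant_id": "rs09", "effect_allele": "C", "other_allele": "T", "beta": 0.09},
        {"variant_id": "rs10", "effect_allele": "C", "other_allele": "T", "beta": 0.10},
        {"variant_id": "rs11", "effect_allele": "G", "other_allele": "T", "beta": 0.11},
        {"variant_id": "rs12", "effect_allele": "A", "other_allele": "G", "beta": 0.12},
    ]
    exp, out = _pair(exp_rows, out_rows)
    hset = harmonize(exp, out)
    assert hset.variant_ids == ["rs01", "rs02", "rs03", "rs04", "rs09", "rs10"]
    by_id = {i.variant_id: i for i in hset.instruments}
    assert by_id["rs01"].beta_out == pytest.approx(0.01)   # direct
    assert by_id["rs02"].beta_out == pytest.approx(-0.02)  # swap
    assert by_id["rs03"].beta_out == pytest.approx(0.03)   # strand flip
    assert by_id["rs04"].beta_out == pytest.approx(-0.04)  # strand flip + swap
    assert by_id["rs10"].beta_out == pytest.approx(-0.10)  # swap, pyrimidine coding
    assert dict(hset.exclusions) == {"rs05": "palindromic", "rs06": "palindromic",
                                     "rs07": "allele_mismatch", "rs08": "not_in_outcome",
                                     "rs11": "allele_mismatch"}
    # outcome-only rs12 is not a candidate instrument
    assert len(hset) + len(hset.exclusions) == len(exp)


def test_harmonization_is_involution_safe():
    exp, out = _pair(
        [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.1},
         {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T", "beta": -0.2}],
        [{"variant_id": "rs1", "effect_allele": "A", "other_allele": "G", "beta": 0.3},
         {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T", "beta": 0.4}])
    once = harmonize(exp, out)
    assert [(i.beta_exp, i.beta_out) for i in once.instruments] == [(0.1, 0.3), (-0.2, 0.4)]


@given(st.floats(min_value=0.01, max_value=1.0),
       st.floats(min_value=-1.0, max_value=1.0),
       st.floats(min_value=0.05, max_value=0.95))
def test_flipping_exposure_coding_leaves_wald_ratio_unchanged(beta_exp, beta_out, eaf):
    base_exp = [{"effect_allele": "A", "other_allele": "G", "beta": beta_exp,
                 "eaf": eaf}]
    flip_exp = [{"effect_allele": "G", "other_allele": "A", "beta": -beta_exp,
                 "eaf": 1 - eaf}]
    out_rows = [{"effect_allele": "A", "other_allele": "G", "beta": beta_out}]
    r1 = wald_ratio(harmonize(*_pair(base_exp, out_rows)).instruments[0])
    r2 = wald_ratio(harmonize(*_pair(flip_exp, out_rows)).instruments[0])
    assert r1.beta == pytest.approx(r2.beta, rel=1e-12, abs=1e-12)
    assert r1.se == pytest.approx(r2.se, rel=1e-12)


class TestMergeMultivariable:
    def _tables(self):
        rows = [{"variant_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.1 * (i + 1), "pval": 1e-10} for i in range(10)]
        return make_table(rows, trait_name="e1"), make_table(rows, trait_name="e2")

    def test_identical_instrument_lists_give_length_two_vectors(self):
        e1, e2 = self._tables()
        out = make_table([{"variant_id": f"rs{i}", "effect_allele": "A",
                           "other_allele": "G", "beta": 0.01} for i in range(10)],
                         trait_name="out")
        mset = merge_multivariable([e1, e2], out)
        assert len(mset) == 10
        assert mset.beta_exp.shape == (10, 2)

    def test_disjoint_lists_union_when_records_exist_everywhere(self):
        all_rows = [{"variant_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                     "beta": 0.1, "pval": 1e-10 if i < 5 else 0.5} for i in range(10)]
        flip = [{**r, "pval": 0.5 if i < 5 else 1e-10} for i, r in enumerate(all_rows)]
        e1, e2 = make_table(all_rows, trait_name="e1"), make_table(flip, trait_name="e2")
        out = make_table([{**r, "pval": 0.5} for r in all_rows], trait_name="out")
        mset = merge_multivariable([e1, e2], out)
        assert len(mset) == 10  # 5 significant in e1, the other 5 in e2

    def test_variant_missing_from_one_exposure_is_excluded_with_reason(self):
        e1, e2 = self._tables()
        e2 = e2.with_records(e2.records[1:])  # drop rs0 from exposure 2
        out = make_table([{"variant_id": f"rs{i}", "effect_allele": "A",
                           "other_allele": "G"} for i in range(10)], trait_name="out")
        mset = merge_multivariable([e1, e2], out)
        assert len(mset) == 9
        assert ("rs0", "not_in_exposure") in mset.exclusions

    def test_fewer_than_two_exposures_is_usage_error(self):
        e1, _ = self._tables()
        with pytest.raises(ConfigurationError):
            merge_multivariable([e1], e1)
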