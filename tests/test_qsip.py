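"""The qSIP inference chain: densities, GC, molecular weights, MWE, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualsip import (
    AbundanceTable,
    QsipResult,
    call_active,
    carbon_max_increment,
    gc_from_light_density,
    labelled_molecular_weight,
    light_molecular_weight,
    max_heavy_mw,
    max_heavy_mw_dual,
    molecular_weight_excess,
    nitrogen_max_increment,
    run_qsip,
    weighted_average_density,
)
from dualsip.errors import InvalidStateError, ParameterError, UndefinedResultError
from dualsip.qsip import NATURAL_13C

from conftest import make_profile
from dualsip import TreatmentPair


class TestWeightedAverageDensity:
    def test_single_fraction(self):
        assert weighted_average_density([100], [1.700]) == pytest.approx(1.700)

    def test_hand_computed_two_fractions(self):
        # (10*1.70 + 30*1.74) / 40 = 1.730
        assert weighted_average_density([10, 30], [1.70, 1.74]) == pytest.approx(1.730)

    def test_all_zero_copies_undefined(self):
        with pytest.raises(UndefinedResultError):
            weighted_average_density([0, 0], [1.70, 1.74])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6), min_size=1, max_size=13),
        st.floats(1e-6, 1e6),
    )
    def test_scale_invariant_and_bounded(self, copies, scale):
        copies = np.asarray(copies)
        if copies.sum() <= 0:
            return
        dens = np.linspace(1.66, 1.78, len(copies))
        wad = weighted_average_density(copies, dens)
        assert dens.min() - 1e-9 <= wad <= dens.max() + 1e-9
        assert weighted_average_density(copies * scale, dens) == pytest.approx(
            wad, abs=1e-9
        )


class TestDensityToMolecularWeights:
    @pytest.mark.parametrize(
        "w_light,gc",
        [(1.646057, 0.0), (1.729563, 1.0), (1.687810, 0.5)],
    )
    def test_gc_inverts_linear_density_relation(self, w_light, gc):
        assert gc_from_light_density(w_light) == pytest.approx(gc, abs=1e-9)

    def test_gc_clamped_outside_unit_interval(self):
        assert gc_from_light_density(1.60) == 0.0
        assert gc_from_light_density(1.80) == 1.0

    @pytest.mark.parametrize("gc,mw", [(0.0, 307.691), (1.0, 308.187), (0.5, 307.939)])
    def test_light_molecular_weight(self, gc, mw):
        assert light_molecular_weight(gc) == pytest.approx(mw, abs=1e-9)

    def test_labelled_mw_no_shift_is_identity(self):
        assert labelled_molecular_weight(1.70, 1.70, 307.939) == pytest.approx(307.939)

    def test_labelled_mw_one_percent_shift(self):
        # dW/W = 0.017/1.700 = 0.01 exactly -> 307.939 * 1.01
        assert labelled_molecular_weight(1.700, 1.717, 307.939) == pytest.approx(
            311.01839, abs=1e-5
        )

    def test_labelled_mw_linear_in_shift(self):
        m = 307.939
        gain1 = labelled_molecular_weight(1.70, 1.71, m) - m
        gain2 = labelled_molecular_weight(1.70, 1.72, m) - m
        assert gain2 == pytest.approx(2 * gain1)

    @pytest.mark.parametrize("fn", [light_molecular_weight, carbon_max_increment,
                                    nitrogen_max_increment])
    def test_gc_domain_enforced(self, fn):
        with pytest.raises(ParameterError):
            fn(1.2)


class TestMaximumHeavyWeights:
    def test_dual_increment_at_gc_zero(self):
        m0 = light_molecular_weight(0.0)
        assert max_heavy_mw_dual(0.0, m0) == pytest.approx(321.107, abs=1e-9)

    def test_dual_increment_at_gc_half(self):
        m = light_molecular_weight(0.5)
        assert max_heavy_mw_dual(0.5, m) - m == pytest.approx(13.41725, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(100, 500))
    def test_dual_increment_independent_of_light_mw(self, gc, m):
        inc = max_heavy_mw_dual(gc, m) - m
        assert inc == pytest.approx(max_heavy_mw_dual(gc, 307.691) - 307.691)

    @pytest.mark.parametrize("gc,inc", [(0.0, 3.4895), (1.0, 3.988)])
    def test_nitrogen_increment_pair_averages(self, gc, inc):
        assert nitrogen_max_increment(gc) == pytest.approx(inc, abs=1e-9)

    @pytest.mark.parametrize("gc,inc", [(0.0, 9.974564), (1.0, 9.4758358)])
    def test_carbon_increment_endpoints(self, gc, inc):
        assert carbon_max_increment(gc) == pytest.approx(inc, abs=1e-9)

    def test_per_element_mode_differs_slightly_from_printed(self):
        m = light_molecular_weight(0.5)
        printed = max_heavy_mw_dual(0.5, m, mode="printed") - m
        per_el = max_heavy_mw_dual(0.5, m, mode="per_element") - m
        assert per_el == pytest.approx(
            carbon_max_increment(0.5) + nitrogen_max_increment(0.5)
        )
        assert abs(printed - per_el) < 0.06 and printed != per_el

    def test_carbon_only_mode_reproduces_single_isotope_maximum(self):
        m = light_molecular_weight(0.3)
        assert max_heavy_mw(0.3, m, isotopes="C") == pytest.approx(
            m + carbon_max_increment(0.3)
        )

    def test_unknown_modes_rejected(self):
        with pytest.raises(ParameterError):
            max_heavy_mw_dual(0.5, 307.9, mode="nonsense")
        with pytest.raises(ParameterError):
            max_heavy_mw(0.5, 307.9, isotopes="N")


class TestMWE:
    def test_endpoints_and_midpoint(self):
        assert molecular_weight_excess(307.9, 307.9, 321.3) == 0.0
        assert molecular_weight_excess(321.3, 307.9, 321.3) == pytest.approx(1.0)
        mid = (307.9 + 321.3) / 2
        assert molecular_weight_excess(mid, 307.9, 321.3) == pytest.approx(0.5)

    def test_negative_shift_reported_as_is(self):
        assert molecular_weight_excess(307.0, 307.9, 321.3) < 0

    def test_degenerate_maximum_rejected(self):
        with pytest.raises(InvalidStateError):
            molecular_weight_excess(310.0, 307.9, 307.9)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(1.66, 1.75), st.floats(0, 0.02), st.floats(0.001, 0.02))
    def test_mwe_strictly_increasing_in_w_lab(self, w_light, d1, extra):
        gc = gc_from_light_density(w_light)
        m_light = light_molecular_weight(gc)
        m_max = max_heavy_mw_dual(gc, m_light)

        def mwe_at(w_lab):
            m_lab = labelled_molecular_weight(w_light, w_lab, m_light)
            return molecular_weight_excess(m_lab, m_light, m_max)

        assert mwe_at(w_light + d1 + extra) > mwe_at(w_light + d1)


class TestActiveCalls:
    def res(self, mwe):
        return QsipResult(
            otu_id="o", substrate="DOM", w_light=1.7, w_lab=1.71, delta_w=0.01,
            gc=0.5, m_light=307.9, m_lab=309.0, m_heavymax=321.3, mwe=mwe,
            active=False, copies_unlabelled=1.0, copies_labelled=1.0,
        )

    @pytest.mark.parametrize(
        "mwe,active", [(0.15, True), (0.139, False), (0.14, True), (-0.05, False)]
    )
    def test_inclusive_threshold(self, mwe, active):
        (out,) = call_active([self.res(mwe)])
        assert out.active is active

    def test_custom_threshold(self):
        (out,) = call_active([self.res(0.5)], threshold=0.6)
        assert not out.active


def copies_table(values: dict, sample_ids) -> AbundanceTable:
    df = pd.DataFrame.from_dict(values, orient="index")
    df.columns = sample_ids
    return AbundanceTable(values=df.astype(float), kind="copies")


class TestRunQsip:
    densities = (1.74, 1.72, 1.70, 1.68, 1.66)

    def pair(self):
        return TreatmentPair(
            unlabelled=make_profile("U", isotope="unlabelled", densities=self.densities),
            labelled=make_profile("L", isotope="labelled", densities=self.densities),
        )

    def test_identical_profiles_give_zero_mwe_inactive(self):
        pair = self.pair()
        band = {"o1": [0, 10, 80, 10, 0]}
        cu = copies_table(band, pair.unlabelled.sample_ids)
        cl = copies_table(band, pair.labelled.sample_ids)
        results, exclusions = run_qsip(pair, cu, cl)
        assert not exclusions
        (r,) = results
        assert r.mwe == pytest.approx(0.0, abs=1e-12)
        assert not r.active
        assert r.delta_w == pytest.approx(0.0, abs=1e-12)

    def test_absent_otus_excluded_with_reason(self):
        pair = self.pair()
        cu = copies_table({"o1": [0, 10, 80, 10, 0], "only_u": [1, 1, 1, 1, 1]},
                          pair.unlabelled.sample_ids)
        cl = copies_table({"o1": [0, 10, 80, 10, 0], "only_l": [1, 1, 1, 1, 1]},
                          pair.labelled.sample_ids)
        results, exclusions = run_qsip(pair, cu, cl)
        assert [r.otu_id for r in results] == ["o1"]
        assert exclusions == {
            "only_u": "absent_in_labelled",
            "only_l": "absent_in_unlabelled",
        }

    def test_zero_copy_row_excluded_not_fatal(self):
        pair = self.pair()
        cu = copies_table({"o1": [0, 10, 80, 10, 0], "z": [0, 0, 0, 0, 0]},
                          pair.unlabelled.sample_ids)
        cl = copies_table({"o1": [0, 10, 80, 10, 0], "z": [1, 1, 1, 1, 1]},
                          pair.labelled.sample_ids)
        results, exclusions = run_qsip(pair, cu, cl)
        assert len(results) == 1 and exclusions["z"] == "absent_in_unlabelled"

    def test_mwe_invariant_under_copy_rescaling(self):
        pair = self.pair()
        band_u = {"o1": [0.0, 10.0, 80.0, 10.0, 0.0]}
        band_l = {"o1": [5.0, 40.0, 50.0, 5.0, 0.0]}
        cu = copies_table(band_u, pair.unlabelled.sample_ids)
        cl = copies_table(band_l, pair.labelled.sample_ids)
        (r1,), _ = run_qsip(pair, cu, cl)
        cu7 = copies_table({"o1": [7 * x for x in band_u["o1"]]},
                           pair.unlabelled.sample_ids)
        (r2,), _ = run_qsip(pair, cu7, cl)
        assert r2.mwe == pytest.approx(r1.mwe, abs=1e-9)

    def test_natural_abundance_correction_rescales_mwe_upward(self):
        pair = self.pair()
        cu = copies_table({"o1": [0, 10, 80, 10, 0]}, pair.unlabelled.sample_ids)
        cl = copies_table({"o1": [5, 40, 50, 5, 0]}, pair.labelled.sample_ids)
        (plain,), _ = run_qsip(pair, cu, cl)
        (corrected,), _ = run_qsip(pair, cu, cl, natural_abundance_correction=True)
        assert corrected.mwe > plain.mwe > 0
        # the correction is small: about 1% of the maximum gain
        assert corrected.mwe == pytest.approx(plain.mwe, rel=0.03)
        assert NATURAL_13C < 0.02
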