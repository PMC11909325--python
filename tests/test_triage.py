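"""Tier classification, kinetic-shape flags and hit accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndscreen import (
    Flag,
    Sensorgram,
    Tier,
    TriageResult,
    TriageThresholds,
    call_hits,
    classify,
    flag_kinetics,
)
from ndscreen.exceptions import ValidationError
from ndscreen.preprocess import extract_report_point

TIER_ORDER = [Tier.REFERENCE_BINDER, Tier.NO_BINDER, Tier.BINDER,
              Tier.SUPER_STOICHIOMETRIC]


class TestClassify:
    @pytest.mark.parametrize("occ,tier", [
        (-5.0, Tier.REFERENCE_BINDER),
        (-1e-9, Tier.REFERENCE_BINDER),
        (0.0, Tier.NO_BINDER),
        (49.999, Tier.NO_BINDER),
        (50.0, Tier.BINDER),           # inclusive lower bound
        (150.0, Tier.BINDER),
        (300.0, Tier.BINDER),          # inclusive upper bound
        (320.0, Tier.SUPER_STOICHIOMETRIC),
        (440.0, Tier.SUPER_STOICHIOMETRIC),
    ])
    def test_boundaries(self, occ, tier):
        assert classify(occ) is tier

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"),
                                     float("-inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            classify(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_monotone_in_occupancy(self, a, b):
        lo, hi = sorted((a, b))
        assert TIER_ORDER.index(classify(lo)) <= TIER_ORDER.index(classify(hi))


def shaped_trace(assoc, diss, channel="ch6", baseline=10.0, contact=20.0,
                 diss_len=40.0, dt=0.5):
    """Trace built from response functions of time-into-phase."""
    t = np.arange(0.0, baseline + contact + diss_len + 5.0 + dt / 2, dt)
    r = np.zeros_like(t)
    inj = (t >= baseline) & (t < baseline + contact)
    dis = t >= baseline + contact
    r[inj] = assoc(t[inj] - baseline)
    r[dis] = diss(t[dis] - baseline - contact)
    return Sensorgram(1, channel, t, r, baseline, baseline + contact,
                      baseline + contact + diss_len)


def flat_ref(level):
    return shaped_trace(lambda ta: np.full_like(ta, level),
                        lambda td: np.zeros_like(td), channel="ch7")


class TestFlagKinetics:
    def _flags(self, sg, ref=None, ref100=6.0, active_raw=None):
        rp = extract_report_point(sg, (15.0, 19.0))
        return flag_kinetics(sg, rp, ref, TriageThresholds(),
                             ref_occ100_ru=ref100, active_raw_ru=active_raw)

    def test_fast_ideal_fragment_unflagged(self):
        # koff ~ 1/s: the 40 s dissociation fully clears the surface
        sg = shaped_trace(lambda ta: 8.0 * (1 - np.exp(-5.0 * ta)),
                          lambda td: 8.0 * np.exp(-1.0 * td))
        assert self._flags(sg) == frozenset()

    def test_slow_dissociation_flagged(self):
        # koff/100: most of the response survives the dissociation window
        sg = shaped_trace(lambda ta: 8.0 * (1 - np.exp(-5.0 * ta)),
                          lambda td: 8.0 * np.exp(-0.01 * td))
        assert Flag.SLOW_DISSOCIATION in self._flags(sg)

    def test_rising_association_flagged(self):
        sg = shaped_trace(lambda ta: 0.3 * ta, lambda td: np.zeros_like(td))
        assert Flag.RISING_ASSOCIATION in self._flags(sg)

    def test_reference_sticker_flagged(self):
        sg = shaped_trace(lambda ta: np.full_like(ta, 2.0),
                          lambda td: np.zeros_like(td))
        flags = self._flags(sg, ref=flat_ref(5.0), ref100=6.0, active_raw=0.5)
        assert Flag.REFERENCE_CHANNEL_BINDING in flags

    def test_shared_partitioning_not_flagged_as_reference_binding(self):
        # membrane partitioning seen equally by active and reference
        # channels cancels in subtraction and is not reference binding
        sg = shaped_trace(lambda ta: np.full_like(ta, 5.0),
                          lambda td: np.zeros_like(td))
        flags = self._flags(sg, ref=flat_ref(8.0), ref100=6.0,
                            active_raw=13.0)
        assert Flag.REFERENCE_CHANNEL_BINDING not in flags

    def test_small_responses_never_flagged(self):
        # r_min gate: sub-RU report points carry no shape information
        sg = shaped_trace(lambda ta: 0.02 * ta,
                          lambda td: 0.4 * np.exp(-0.001 * td))
        assert self._flags(sg) == frozenset()

    def test_missing_dissociation_rejected(self):
        t = np.arange(0.0, 30.0, 0.5)
        sg = Sensorgram(1, "ch6", t, np.zeros_like(t), 10.0, 29.5, 29.5)
        rp_like = extract_report_point(sg, (15.0, 19.0))
        with pytest.raises(ValidationError):
            flag_kinetics(sg, rp_like, None)


def _result(i, occ, flags=(), surface="ch6"):
    return TriageResult(f"F{i:03d}", surface, occ, classify(occ),
                        frozenset(flags))


class TestCallHits:
    def test_screen_summary_arithmetic(self):
        # a 140-fragment column: 7 / 84 / 47 / 2 across the tiers with 14
        # flagged binders -> 33 hits and 30% of binders rejected
        results, i = [], 0
        for _ in range(7):
            results.append(_result(i := i + 1, -10.0))
        for _ in range(84):
            results.append(_result(i := i + 1, 20.0))
        for k in range(47):
            flags = (Flag.SLOW_DISSOCIATION,) if k < 14 else ()
            results.append(_result(i := i + 1, 150.0, flags))
        for _ in range(2):
            results.append(_result(i := i + 1, 500.0))
        hits, table = call_hits(results)
        assert table["count"].to_dict() == {
            "reference_binder": 7, "no_binder": 84, "binder": 47,
            "super_stoichiometric": 2, "rejected_binder": 14, "hits": 33,
        }
        assert table.loc["rejected_binder", "pct_of_binders"] == "30"
        assert len(hits) == 33

    def test_no_flags_means_all_binders_hit(self):
        results = [_result(i, 100.0) for i in range(10)]
        hits, table = call_hits(results)
        assert len(hits) == 10
        assert table.loc["rejected_binder", "count"] == 0

    def test_all_flagged_means_no_hits(self):
        results = [_result(i, 100.0, (Flag.RISING_ASSOCIATION,))
                   for i in range(5)]
        hits, table = call_hits(results)
        assert hits == set()
        assert table.loc["rejected_binder", "pct_of_binders"] == "100"

    def test_tier_counts_sum_to_input_length(self):
        rng = np.random.default_rng(1)
        results = [_result(i, float(occ))
                   for i, occ in enumerate(rng.uniform(-100, 500, 57))]
        _, table = call_hits(results)
        tiers = ["reference_binder", "no_binder", "binder",
                 "super_stoichiometric"]
        assert int(table.loc[tiers, "count"].sum()) == 57

    def test_duplicate_fragment_surface_rejected(self):
        with pytest.raises(ValidationError):
            call_hits([_result(1, 100.0), _result(1, 90.0)])

    def test_flags_outside_binder_tier_do_not_change_hits(self):
        results = [
            _result(1, 20.0, (Flag.SLOW_DISSOCIATION,)),
            _result(2, 400.0, (Flag.RISING_ASSOCIATION,)),
            _result(3, 100.0),
        ]
        hits, table = call_hits(results)
        assert hits == {"F003"}
        assert table.loc["rejected_binder", "count"] == 0
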