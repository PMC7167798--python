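"""Global Malmquist index: distances, decomposition, circularity, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maridea import (
    ReferenceSet,
    geometric_mean_indices,
    malmquist_panel,
    malmquist_record,
    output_distance,
    panel_from_frame,
)
from maridea.malmquist import GlobalTechnology
from maridea.published import provincial_change_rates
from tests.conftest import random_panel


class TestOutputDistance:
    def test_interior_point_closed_form(self):
        ref = ReferenceSet(X=np.array([[1.0, 1.0]]), Y=np.array([[1.0, 2.0]]),
                           rts="crs")
        assert output_distance((np.array([1.0]), np.array([1.0])), ref) == \
            pytest.approx(0.5, abs=1e-8)

    def test_frontier_point_is_one(self):
        ref = ReferenceSet(X=np.array([[1.0, 1.0]]), Y=np.array([[1.0, 2.0]]),
                           rts="crs")
        assert output_distance((np.array([1.0]), np.array([2.0])), ref) == \
            pytest.approx(1.0, abs=1e-8)

    def test_crs_scale_invariance(self):
        ref = ReferenceSet(X=np.array([[1.0, 1.0]]), Y=np.array([[1.0, 2.0]]),
                           rts="crs")
        assert output_distance((np.array([2.0]), np.array([2.0])), ref) == \
            pytest.approx(0.5, abs=1e-8)

    def test_vrs_reference_rejected(self):
        ref = ReferenceSet(X=np.array([[1.0]]), Y=np.array([[1.0]]), rts="vrs")
        with pytest.raises(ValueError, match="constant-returns"):
            output_distance((np.array([1.0]), np.array([1.0])), ref)


class TestRecords:
    def test_single_dmu_growth_splits_into_pure_frontier_shift(self):
        # one DMU doubling productivity: TE = 1 each period (self-frontier),
        # so all change is best-practice change
        panel = panel_from_frame(pd.DataFrame({
            "dmu": ["A", "A"], "period": ["t1", "t2"],
            "input:x": [1.0, 1.0], "output:y": [1.0, 2.0],
        }))
        rec = malmquist_record(panel, "A", "t1", "t2")
        assert rec.gmi == pytest.approx(2.0, abs=1e-8)
        assert rec.ec == pytest.approx(1.0, abs=1e-8)
        assert rec.bpc == pytest.approx(2.0, abs=1e-8)

    def test_static_panel_is_all_ones(self, small_panel):
        frame = small_panel.to_frame()
        frame.loc[frame.period == "t2", ["input:x", "output:y"]] = \
            frame.loc[frame.period == "t1", ["input:x", "output:y"]].to_numpy()
        panel = panel_from_frame(frame)
        records = malmquist_panel(panel)
        np.testing.assert_allclose(records[["gmi", "ec", "bpc"]], 1.0, atol=1e-8)

    def test_non_adjacent_pair_is_flagged(self):
        panel = random_panel(np.random.default_rng(0), 4, 3, 2, 1)
        rec = malmquist_record(panel, "D00", "P00", "P02")
        assert rec.adjacent is False

    def test_single_period_panel_rejected(self):
        panel = random_panel(np.random.default_rng(0), 4, 1, 2, 1)
        with pytest.raises(ValueError, match="two periods"):
            malmquist_panel(panel)


class TestProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_decomposition_identity_and_envelopment(self, seed):
        panel = random_panel(np.random.default_rng(seed), 6, 3, 2, 2)
        records = malmquist_panel(panel)
        np.testing.assert_allclose(records.gmi, records.ec * records.bpc,
                                   rtol=1e-9)
        assert ((records[["bpg_from", "bpg_to"]] > 0).all().all()
                and (records[["bpg_from", "bpg_to"]] <= 1 + 1e-9).all().all())
        assert (records[["te_from", "te_to"]] <= 1 + 1e-9).all().all()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_circularity(self, seed):
        panel = random_panel(np.random.default_rng(seed), 5, 3, 2, 1)
        tech = GlobalTechnology.from_panel(panel)
        p0, p1, p2 = panel.period_ids
        for dmu in panel.dmu_ids:
            r02 = malmquist_record(panel, dmu, p0, p2, tech)
            r01 = malmquist_record(panel, dmu, p0, p1, tech)
            r12 = malmquist_record(panel, dmu, p1, p2, tech)
            assert r02.gmi == pytest.approx(r01.gmi * r12.gmi, rel=1e-9)
            assert r02.ec == pytest.approx(r01.ec * r12.ec, rel=1e-9)
            assert r02.bpc == pytest.approx(r01.bpc * r12.bpc, rel=1e-9)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_one_by_one_gmi_equals_productivity_ratio(self, seed):
        # the global frontier cancels from the ratio of distances
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 4, 3, 1, 1)
        records = malmquist_panel(panel)
        for _, r in records.iterrows():
            x0, y0 = panel.observation(r.dmu, r.period_from)
            x1, y1 = panel.observation(r.dmu, r.period_to)
            assert r.gmi == pytest.approx((y1[0] / x1[0]) / (y0[0] / x0[0]),
                                          rel=1e-7)

    def test_no_infeasibility_on_stress_panels(self):
        # heterogeneous magnitudes; every distance LP must come back optimal
        rng = np.random.default_rng(99)
        frame_rows = []
        for i in range(8):
            for t in range(4):
                frame_rows.append({
                    "dmu": f"D{i}", "period": f"P{t}",
                    "input:a": 10.0 ** rng.uniform(-2, 4),
                    "input:b": 10.0 ** rng.uniform(-2, 4),
                    "output:y": 10.0 ** rng.uniform(-2, 4),
                })
        panel = panel_from_frame(pd.DataFrame(frame_rows))
        records = malmquist_panel(panel)  # raises on any non-optimal LP
        assert np.isfinite(records[["gmi", "ec", "bpc"]]).all().all()


class TestSummaries:
    def test_geometric_mean_basics(self):
        records = pd.DataFrame({
            "dmu": ["A", "A"], "period_from": ["t1", "t2"],
            "period_to": ["t2", "t3"],
            "gmi": [2.0, 0.5], "ec": [1.0, 1.0], "bpc": [2.0, 0.5],
        })
        out = geometric_mean_indices(records)
        a = out[out.dmu == "A"].iloc[0]
        assert a.gmi == pytest.approx(1.0)
        assert a.bpc == pytest.approx(1.0)

    def test_identity_preserved_by_geometric_means(self):
        panel = random_panel(np.random.default_rng(5), 6, 4, 2, 2)
        out = geometric_mean_indices(malmquist_panel(panel))
        np.testing.assert_allclose(out.gmi, out.ec * out.bpc, rtol=1e-9)

    def test_overall_row_is_cross_dmu_geomean(self):
        panel = random_panel(np.random.default_rng(6), 5, 3, 2, 1)
        out = geometric_mean_indices(malmquist_panel(panel))
        body = out[out.dmu != "Overall"]
        overall = out[out.dmu == "Overall"].iloc[0]
        assert overall.gmi == pytest.approx(
            float(np.exp(np.mean(np.log(body.gmi)))), rel=1e-12)

    def test_reported_provincial_rows_reproduce_reported_overall(self):
        # cross-province geometric mean of the published per-province change
        # rates matches the published Overall row at its printed precision
        table = provincial_change_rates(include_overall=True)
        body = table[table.dmu != "Overall"]
        overall = table[table.dmu == "Overall"].iloc[0]
        for col in ("gmi", "ec", "bpc"):
            mean = float(np.exp(np.mean(np.log(body[col]))))
            assert round(mean, 4) == pytest.approx(overall[col], abs=1.01e-4)

    def test_reported_rows_satisfy_decomposition_at_print_precision(self):
        table = provincial_change_rates(include_overall=True)
        for _, row in table.iterrows():
            assert row.gmi == pytest.approx(row.ec * row.bpc, abs=1.5e-4)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_indices(pd.DataFrame(columns=["dmu", "gmi", "ec", "bpc"]))
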