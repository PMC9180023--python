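"""Panel data model: validation, I/O round trips, slicing, zone aggregation."""

import numpy as np
import pandas as pd
import pytest

import equipanel as ep
from equipanel.errors import (
    PanelValidationError,
    SchemaError,
    UnsupportedCombinationError,
    YearRangeError,
)


class TestValidation:
    def test_well_formed_frame_loads(self, small_panel_frame):
        panel = ep.ResourcePanel(small_panel_frame())
        assert len(panel) == 6
        assert panel.year_range == (2003, 2004)
        assert panel.regions == ["A", "B", "C"]

    def test_missing_column_named_in_error(self, small_panel_frame):
        df = small_panel_frame().drop(columns=["th_bed"])
        with pytest.raises(SchemaError, match="th_bed"):
            ep.ResourcePanel(df)

    def test_nonpositive_population_names_row(self, small_panel_frame):
        df = small_panel_frame({("B", 2004): {"population": 0.0}})
        with pytest.raises(PanelValidationError, match=r"\(B, 2004\)"):
            ep.ResourcePanel(df)

    def test_negative_resource_rejected(self, small_panel_frame):
        df = small_panel_frame({("A", 2003): {"vc_personnel": -1.0}})
        with pytest.raises(PanelValidationError, match=r"\(A, 2003\)"):
            ep.ResourcePanel(df)

    def test_nonempty_vc_bed_column_rejected(self, small_panel_frame):
        df = small_panel_frame()
        df["vc_bed"] = 3.0
        with pytest.raises(PanelValidationError, match="vc_bed"):
            ep.ResourcePanel(df)
        # an all-zero vc_bed column is tolerated and dropped
        df["vc_bed"] = 0.0
        assert "vc_bed" not in ep.ResourcePanel(df).frame.columns

    def test_unbalanced_panel_rejected(self, small_panel_frame):
        df = small_panel_frame().drop(index=[1])  # A missing in 2004
        with pytest.raises(PanelValidationError, match="unbalanced"):
            ep.ResourcePanel(df)

    def test_duplicate_region_year_rejected(self, small_panel_frame):
        df = pd.concat([small_panel_frame(), small_panel_frame().iloc[[0]]])
        with pytest.raises(PanelValidationError, match="duplicate"):
            ep.ResourcePanel(df)

    def test_record_invariants(self):
        with pytest.raises(PanelValidationError):
            ep.RegionYearRecord("r", "z", 2003, population=-1, area=1, resources={})
        with pytest.raises(PanelValidationError):
            ep.RegionYearRecord(
                "r", "z", 2003, 1, 1,
                {(ep.Tier.VC, ep.ResourceKind.BED): 2.0},
            )


class TestIO:
    def test_csv_round_trip_reproduces_records(self, small_panel_frame, tmp_path):
        panel = ep.ResourcePanel(small_panel_frame())
        path = tmp_path / "panel.csv"
        ep.write_panel(panel, path)
        assert ep.load_panel(path) == panel

    def test_row_order_is_irrelevant(self, small_panel_frame, tmp_path):
        df = small_panel_frame()
        shuffled = df.sample(frac=1, random_state=7)
        assert ep.ResourcePanel(df) == ep.ResourcePanel(shuffled)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ep.load_panel(tmp_path / "absent.csv")


class TestSlicing:
    def test_population_and_geography_projections(self, small_panel_frame):
        panel = ep.ResourcePanel(small_panel_frame())
        a = panel.slice_allocation(
            2003, ep.Tier.CMHI, ep.ResourceKind.BED, ep.Calibre.POPULATION
        )
        assert a.n == 3
        np.testing.assert_allclose(a.m, [10.0, 20.0, 30.0])
        np.testing.assert_allclose(a.e, [20.0, 40.0, 60.0])
        g = panel.slice_allocation(
            2003, ep.Tier.CMHI, ep.ResourceKind.BED, ep.Calibre.GEOGRAPHY
        )
        np.testing.assert_allclose(g.m, [100.0, 50.0, 200.0])
        np.testing.assert_allclose(g.e, a.e)

    def test_vc_bed_slice_unsupported(self, small_panel_frame):
        panel = ep.ResourcePanel(small_panel_frame())
        with pytest.raises(UnsupportedCombinationError):
            panel.slice_allocation(
                2003, ep.Tier.VC, ep.ResourceKind.BED, ep.Calibre.POPULATION
            )

    def test_year_out_of_range(self, small_panel_frame):
        panel = ep.ResourcePanel(small_panel_frame())
        with pytest.raises(YearRangeError):
            panel.slice_allocation(
                1999, ep.Tier.TH, ep.ResourceKind.BED, ep.Calibre.POPULATION
            )

    def test_slice_is_pure_projection(self, small_panel_frame):
        # perturbing a record outside (year, tier, kind) leaves the slice alone
        base = ep.ResourcePanel(small_panel_frame()).slice_allocation(
            2003, ep.Tier.TH, ep.ResourceKind.PERSONNEL, ep.Calibre.POPULATION
        )
        perturbed = ep.ResourcePanel(
            small_panel_frame({("B", 2004): {"cmhi_bed": 999.0}})
        ).slice_allocation(
            2003, ep.Tier.TH, ep.ResourceKind.PERSONNEL, ep.Calibre.POPULATION
        )
        np.testing.assert_array_equal(base.e, perturbed.e)
        np.testing.assert_array_equal(base.m, perturbed.m)


class TestZoneAggregation:
    def test_sums_by_zone(self):
        alloc = ep.AllocationVector(
            region_ids=("a", "b", "c"),
            zones=("A", "A", "B"),
            m=np.array([1.0, 2.0, 3.0]),
            e=np.array([1.0, 1.0, 1.0]),
            calibre=ep.Calibre.POPULATION,
        )
        groups = alloc.aggregate_zones()
        assert [(z, M) for z, M, _ in groups] == [("A", 3.0), ("B", 3.0)]

    def test_single_zone_equals_grand_totals(self):
        alloc = ep.AllocationVector(
            region_ids=("a", "b"),
            zones=("only", "only"),
            m=np.array([2.0, 5.0]),
            e=np.array([1.0, 4.0]),
            calibre=ep.Calibre.POPULATION,
        )
        [(zone, M, E)] = alloc.aggregate_zones()
        assert (zone, M, E) == ("only", 7.0, 5.0)

    def test_totals_conserved_exactly_on_synthetic_panel(self, default_panel):
        alloc = default_panel.slice_allocation(
            2010, ep.Tier.TH, ep.ResourceKind.PERSONNEL, ep.Calibre.POPULATION
        )
        import math

        groups = alloc.aggregate_zones()
        # exact per-zone summation: regrouping error is at most a couple ulp
        M_total, E_total = math.fsum(alloc.m), math.fsum(alloc.e)
        assert abs(math.fsum(M for _, M, _ in groups) - M_total) <= 2 * np.spacing(M_total)
        assert abs(math.fsum(E for _, _, E in groups) - E_total) <= 2 * np.spacing(E_total)
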