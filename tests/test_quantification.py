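import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cxplaque.colocalization import (CombinationClass, PARENCHYMAL, Plaque,
                                     VASCULAR)
from cxplaque.quantification import (MissingFieldsError, SamplingPlan,
                                     aggregate_fields, density_to_total,
                                     load_reference_totals, number_times_size,
                                     percent_change, percent_change_table,
                                     summarize_group, summarize_retina,
                                     tabulate_plaques, vessel_surface_area)

VOX = (8.2, 0.25, 0.25)


def make_plaque(pid, members, compartment, n_voxels=4):
    voxels = np.column_stack([np.zeros(n_voxels, int),
                              np.zeros(n_voxels, int),
                              np.arange(n_voxels)])
    return Plaque(pid, CombinationClass(members), voxels, VOX, compartment)


def field_table(count, compartment=PARENCHYMAL, label="Cx30"):
    plaques = [make_plaque(i, label.split("/"), compartment)
               for i in range(count)]
    return tabulate_plaques(plaques, mode="class")


class TestTabulate:
    def test_class_mode_counts_each_plaque_once(self):
        plaques = [make_plaque(1, ["Cx26", "Cx30"], PARENCHYMAL),
                   make_plaque(2, ["Cx30"], VASCULAR)]
        tab = tabulate_plaques(plaques, mode="class")
        assert tab["count"].sum() == 2
        row = tab[(tab.compartment == PARENCHYMAL) & (tab.key == "Cx26/Cx30")]
        assert row["count"].iloc[0] == 1

    def test_connexin_mode_counts_each_member(self):
        plaques = [make_plaque(1, ["Cx26", "Cx30"], PARENCHYMAL)]
        tab = tabulate_plaques(plaques, mode="connexin")
        assert tab["count"].sum() == 2
        assert set(tab[tab["count"] > 0]["key"]) == {"Cx26", "Cx30"}


class TestAggregateFields:
    def test_identical_fields_average_to_field_value(self):
        plan = SamplingPlan()
        tables = {k: field_table(10) for k in plan.field_keys()}
        out = aggregate_fields(tables, plan)
        row = out[(out.compartment == PARENCHYMAL) & (out.key == "Cx30")]
        assert row["count"].iloc[0] == 10.0
        retinas = [summarize_retina(out, 1.0, 0.1, 50.0, 10.0) for _ in range(4)]
        grp = summarize_group(retinas)
        g = grp[(grp.compartment == PARENCHYMAL) & (grp.key == "Cx30")]
        assert g["count_sem"].iloc[0] == 0.0
        assert g["n_retinas"].iloc[0] == 4

    def test_counts_1_to_24_average_to_12_5(self):
        plan = SamplingPlan()
        tables = {k: field_table(i + 1)
                  for i, k in enumerate(plan.field_keys())}
        out = aggregate_fields(tables, plan)
        row = out[(out.compartment == PARENCHYMAL) & (out.key == "Cx30")]
        assert row["count"].iloc[0] == pytest.approx(12.5)

    def test_missing_fields_reported(self):
        plan = SamplingPlan()
        tables = {k: field_table(1) for k in plan.field_keys()[:-2]}
        with pytest.raises(MissingFieldsError) as err:
            aggregate_fields(tables, plan)
        assert ("peripheral", 6) in err.value.missing
        assert ("peripheral", 7) in err.value.missing


class TestDensityAndTotals:
    def test_density_to_total_examples(self):
        assert density_to_total(10.0, 50.0) == 500.0
        assert density_to_total(0.0, 123.0) == 0.0

    def test_total_equals_density_times_area_exactly(self):
        tab = field_table(7)
        summary = summarize_retina(tab, 0.5, 0.05, 52.0, 15.0)
        df = summary.table
        par = df[df.compartment == PARENCHYMAL]
        np.testing.assert_array_equal(par["total_per_retina"],
                                      par["density_per_mm2"] * 52.0)
        vas = df[df.compartment == VASCULAR]
        np.testing.assert_array_equal(vas["total_per_retina"],
                                      vas["density_per_mm2"] * 15.0)


class TestVesselSurfaceArea:
    class Tube:
        def __init__(self, p0, p1, radius):
            self.p0, self.p1, self.radius = p0, p1, radius

    def test_cylinder_closed_form(self):
        area = vessel_surface_area(tubes=[self.Tube((0, 0, 0), (0, 0, 1000.0), 5.0)])
        assert area == pytest.approx(2 * np.pi * 5 * 1000 * 1e-6)

    def test_mask_estimate_close_to_closed_form(self):
        # fine isotropic voxels; compare marching-cubes area to 2*pi*r*L
        voxel = (1.0, 1.0, 1.0)
        shape = (40, 21, 21)
        zz, yy, xx = np.meshgrid(*[np.arange(n) + 0.5 for n in shape],
                                 indexing="ij")
        r, L = 6.0, 40.0
        mask = ((yy - 10.5) ** 2 + (xx - 10.5) ** 2) <= r ** 2
        est = vessel_surface_area(mask=mask, voxel_size=voxel)
        lateral = 2 * np.pi * r * L * 1e-6
        caps = 2 * np.pi * r ** 2 * 1e-6
        assert est == pytest.approx(lateral + caps, rel=0.08)

    def test_empty_geometry_is_zero(self):
        assert vessel_surface_area(tubes=[]) == 0.0
        assert vessel_surface_area(mask=np.zeros((2, 2, 2), bool),
                                   voxel_size=(1, 1, 1)) == 0.0


class TestPercentChange:
    @pytest.mark.parametrize("start,end,expected", [
        (924662.2, 437637.8, -52),
        (2526.5, 13212.6, 422),
        (428717.9, 1185838.8, 176),
        (100.0, 300.0, 200),
        (5.0, 5.0, 0),
    ])
    def test_truncation_examples(self, start, end, expected):
        assert percent_change(start, end).truncated == expected

    def test_untruncated_float_carried(self):
        pc = percent_change(592002.0, 4355278.7)
        assert pc.raw == pytest.approx(635.686, abs=0.001)
        assert pc.truncated == 635  # truncation toward zero

    def test_undefined_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(0.0, 5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(1.0, 1e6), b=st.floats(1.0, 1e6))
    def test_reciprocal_relation_before_truncation(self, a, b):
        p_ab = percent_change(a, b).raw
        p_ba = percent_change(b, a).raw
        assert (1 + p_ab / 100) * (1 + p_ba / 100) == pytest.approx(1.0)

    def test_table_between_groups(self):
        g0 = pd.DataFrame({"compartment": [PARENCHYMAL], "key": ["Cx30"],
                           "total_per_retina": [100.0]})
        g1 = pd.DataFrame({"compartment": [PARENCHYMAL], "key": ["Cx30"],
                           "total_per_retina": [700.0]})
        out = percent_change_table(g0, g1)
        assert out["percent_change_printed"].iloc[0] == 600


class TestNumberTimesSize:
    def test_examples(self):
        assert number_times_size(100, 5) == 500.0
        assert number_times_size(0, 7.3) == 0.0

    def test_product_ranks_follow_planted_abundance_times_size(self, rng):
        counts = rng.integers(1, 200, size=4)
        sizes = rng.uniform(2, 30, size=4)
        prod = number_times_size(counts, sizes)
        assert list(np.argsort(prod)) == list(np.argsort(counts * sizes))


class TestReferenceTotals:
    def test_table_has_15_classes_in_both_compartments(self):
        df = load_reference_totals()
        assert len(df) == 30
        assert df["combination"].nunique() == 15
        assert set(df["compartment"]) == {PARENCHYMAL, "vascular"}
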