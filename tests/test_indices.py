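"""Derived plant indices: formulas, domain errors, algebraic properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peonyforce.errors import DomainError
from peonyforce.indices import (
    OrganNSC,
    crown_width_index,
    derive_plant_indices,
    nsc_accumulation,
    organ_fraction,
    percent_change,
    seedling_index,
    summarize_group,
    total_nsc,
    water_use_efficiency,
)
from peonyforce.table import TraitTable

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestWaterUseEfficiency:
    def test_unit_denominator_is_identity(self):
        assert water_use_efficiency(7.3, 1.0) == 7.3

    def test_control_group_means(self):
        # quotient of the published control means; the printed group
        # value (3.54) averages per-plant ratios instead
        assert water_use_efficiency(10.21, 2.89) == pytest.approx(3.533, abs=5e-4)

    def test_zero_photosynthesis(self):
        assert water_use_efficiency(0.0, 5.0) == 0.0

    def test_nonpositive_transpiration_rejected(self):
        with pytest.raises(DomainError):
            water_use_efficiency(10.0, 0.0)


class TestSeedlingIndex:
    @pytest.mark.parametrize(
        "sd, sl, wpb, printed",
        [(6.2, 111.6, 344.8, 19.2), (5.3, 87.2, 333.3, 20.3)],
    )
    def test_published_group_means(self, sd, sl, wpb, printed):
        assert round(seedling_index(sd, sl, wpb), 1) == printed

    @given(d=positive, w=positive)
    def test_equal_diameter_and_length_gives_biomass(self, d, w):
        assert seedling_index(d, d, w) == pytest.approx(w)

    @given(sd=positive, sl=positive, wpb=positive, c=st.floats(0.5, 2.0))
    def test_scale_invariant_in_sd_sl_and_linear_in_wpb(self, sd, sl, wpb, c):
        base = seedling_index(sd, sl, wpb)
        assert seedling_index(c * sd, c * sl, wpb) == pytest.approx(base)
        assert seedling_index(sd, sl, c * wpb) == pytest.approx(c * base)

    def test_zero_stem_length_rejected(self):
        with pytest.raises(DomainError):
            seedling_index(6.0, 0.0, 300.0)


class TestCrownWidthIndex:
    def test_equal_width_and_height(self):
        assert crown_width_index(42.0, 42.0) == 1.0

    def test_group_mean_quotient(self):
        assert crown_width_index(55.8, 41.5) == pytest.approx(1.3446, abs=5e-5)

    def test_zero_crown(self):
        assert crown_width_index(0.0, 10.0) == 0.0

    def test_zero_height_rejected(self):
        with pytest.raises(DomainError):
            crown_width_index(50.0, 0.0)


class TestNscAccumulation:
    def test_zero_content_or_biomass(self):
        assert nsc_accumulation(OrganNSC("root", 0.0, 320.0)) == 0.0
        assert nsc_accumulation(OrganNSC("stem", 0.3, 0.0)) == 0.0

    def test_hand_multiplication(self):
        assert nsc_accumulation(OrganNSC("root", 0.25, 320.0)) == pytest.approx(80.0)

    def test_invalid_organ_rejected(self):
        with pytest.raises(DomainError):
            OrganNSC("leaf", 0.2, 10.0)


class TestTotalNsc:
    @pytest.mark.parametrize(
        "parts, printed",
        [([2.01, 89.0], 91.0), ([1.42, 81.3], 82.7)],
    )
    def test_published_stem_plus_root_totals(self, parts, printed):
        assert round(total_nsc(parts), 1) == printed

    def test_empty_sum_is_zero(self):
        assert total_nsc([]) == 0.0

    def test_negative_entry_rejected(self):
        with pytest.raises(DomainError):
            total_nsc([1.0, -0.1])

    @given(
        parts=st.lists(st.floats(0, 1e3, allow_nan=False), max_size=6),
        extra=st.lists(st.floats(0, 1e3, allow_nan=False), max_size=6),
    )
    def test_permutation_invariant_and_additive(self, parts, extra):
        assert total_nsc(parts[::-1]) == pytest.approx(total_nsc(parts))
        assert total_nsc(parts + extra) == pytest.approx(
            total_nsc(parts) + total_nsc(extra)
        )


class TestOrganFraction:
    def test_full_pool(self):
        assert organ_fraction(5.0, 5.0) == 100.0

    def test_control_root_share(self):
        assert organ_fraction(81.3, 82.7) == pytest.approx(98.31, abs=5e-3)

    def test_part_exceeding_total_rejected(self):
        with pytest.raises(DomainError):
            organ_fraction(10.0, 9.0)

    @given(
        parts=st.lists(st.floats(0.01, 100, allow_nan=False), min_size=2, max_size=5)
    )
    def test_disjoint_partition_sums_to_100(self, parts):
        total = sum(parts)
        assert sum(organ_fraction(p, total) for p in parts) == pytest.approx(100.0)


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_published_height_reduction(self):
        assert percent_change(47.8, 34.0) == pytest.approx(-28.87, abs=5e-3)

    def test_published_branch_increase(self):
        assert percent_change(1.8, 3.5) == pytest.approx(94.4, abs=0.05)

    @given(a=positive, p=st.floats(-0.9, 9.0))
    def test_relative_increase_identity(self, a, p):
        assert percent_change(a, a * (1 + p)) == pytest.approx(100 * p, abs=1e-6)

    def test_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)


class TestSummarizeGroup:
    def test_constant_replicates(self):
        t = TraitTable.from_records(
            [(f"p{i}", "T0", "defoliation", "SL", 5.0) for i in range(4)]
        )
        s = summarize_group(t)
        assert s.loc[0, "mean"] == 5.0
        assert s.loc[0, "se"] == 0.0
        assert s.loc[0, "n"] == 4

    def test_hand_computed_se(self):
        t = TraitTable.from_records(
            [(f"p{i}", "T0", "defoliation", "SL", v) for i, v in enumerate([1, 2, 3, 4])]
        )
        s = summarize_group(t)
        assert s.loc[0, "mean"] == pytest.approx(2.5)
        assert s.loc[0, "se"] == pytest.approx(0.6455, abs=5e-5)

    def test_single_replicate_warns_and_reports_nan(self):
        t = TraitTable.from_records([("p1", "T0", "defoliation", "SL", 3.0)])
        with pytest.warns(UserWarning, match="SE undefined"):
            s = summarize_group(t)
        assert np.isnan(s.loc[0, "se"])


class TestDerivePlantIndices:
    def test_si_added_per_plant(self, small_table):
        out = derive_plant_indices(small_table)
        si = out.data[out.data["trait_code"] == "SI"].set_index("plant_id")
        assert si.loc["p1", "value"] == pytest.approx(6.0 / 100.0 * 300.0)
        assert si.loc["p2", "value"] == pytest.approx(6.4 / 110.0 * 320.0)

    def test_existing_trait_not_overwritten(self, small_table):
        import pandas as pd

        extra = pd.DataFrame(
            [
                {
                    "plant_id": "p1", "group_id": "T0", "stage": "defoliation",
                    "trait_code": "SI", "value": 99.0,
                }
            ]
        )
        with_si = TraitTable(
            data=pd.concat([small_table.data, extra], ignore_index=True)
        )
        out = derive_plant_indices(with_si)
        si = out.data[out.data["trait_code"] == "SI"]
        assert si["value"].tolist() == [99.0]
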