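"""Tanimoto drug-likeness, descriptor scaling, merging and the ADME screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm import (
    CompoundRecord,
    HerbCompoundList,
    ScreeningCriteria,
    ValidationError,
    compute_dl,
    compute_reference_profile,
    merge_herb_lists,
    scale_descriptors,
    screen_compounds,
)
from netpharm.screening import reference_mean_dl

#: The five compounds in the reference table that fail the default screen
#: and are rescued on documented pharmacological grounds.
RESCUED = {"MOL000043", "MOL000263", "MOL000409", "MOL000902", "MOL007134"}


def _record(mol_id, ob, dl, caco2, herbs=("H1",)):
    return CompoundRecord(mol_id, mol_id.lower(), frozenset(herbs), ob, dl, caco2)


nonneg_vectors = st.integers(1, 6).flatmap(
    lambda d: st.lists(
        st.floats(0, 1, allow_nan=False, allow_infinity=False), min_size=d, max_size=d
    )
)


class TestTanimoto:
    def test_worked_arithmetic_example(self):
        # A·B = 4, |A|² = 9, |B|² = 5 → 4 / (9 + 5 − 4) = 0.4
        assert compute_dl([1, 2, 2], [2, 1, 0]) == pytest.approx(0.4, abs=1e-12)

    def test_self_identity_is_one(self):
        assert compute_dl([0.3, 0.8], [0.3, 0.8]) == pytest.approx(1.0)

    def test_zero_against_nonzero_is_zero(self):
        assert compute_dl([0, 0], [0.5, 0.1]) == 0.0

    def test_both_zero_defined_as_zero(self):
        assert compute_dl([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            compute_dl([-0.1, 0.2], [0.1, 0.2])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_dl([0.1], [0.1, 0.2])

    @given(a=nonneg_vectors)
    def test_bounded_and_symmetric(self, a):
        b = list(reversed(a))
        t = compute_dl(a, b)
        assert 0.0 <= t <= 1.0 + 1e-12
        assert t == pytest.approx(compute_dl(b, a))


class TestReferenceProfile:
    def test_endpoint_scaling_and_clamping(self):
        profile = compute_reference_profile(pd.DataFrame({"x": [2.0, 10.0], "y": [0.0, 4.0]}))
        assert scale_descriptors({"x": 2.0, "y": 4.0}, profile).tolist() == [0.0, 1.0]
        assert scale_descriptors({"x": 99.0, "y": -1.0}, profile).tolist() == [1.0, 0.0]

    def test_constant_column_scales_to_zero(self):
        profile = compute_reference_profile(pd.DataFrame({"x": [3.0, 3.0], "y": [0.0, 2.0]}))
        assert scale_descriptors({"x": 3.0, "y": 1.0}, profile).tolist() == [0.0, 0.5]

    def test_mean_of_endpoints_is_half(self):
        profile = compute_reference_profile(pd.DataFrame({"x": [0.0, 1.0], "y": [2.0, 6.0]}))
        assert profile.b_vector.tolist() == [0.5, 0.5]

    def test_unknown_descriptor_rejected(self):
        profile = compute_reference_profile(pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValidationError):
            scale_descriptors({"z": 1.0}, profile)

    def test_reference_mean_scores_dl_one(self):
        # Scaling is affine, so the scaled raw mean equals the profile mean.
        table = pd.DataFrame({"x": [1.0, 5.0, 3.0], "y": [0.0, 2.0, 1.0]})
        profile = compute_reference_profile(table)
        scaled_mean = scale_descriptors(table.mean().to_dict(), profile)
        assert compute_dl(scaled_mean, profile) == pytest.approx(1.0)

    def test_reference_mean_dl_between_zero_and_one(self):
        table = pd.DataFrame({"x": [1.0, 5.0, 3.0], "y": [0.0, 2.0, 1.0]})
        assert 0.0 < reference_mean_dl(table) <= 1.0

    def test_too_small_reference_rejected(self):
        with pytest.raises(ValidationError):
            compute_reference_profile(pd.DataFrame({"x": [1.0]}))


class TestMerge:
    def test_cross_herb_duplicate_unions_sources(self):
        a = HerbCompoundList("HMM", [_record("MOL000098", 46.43, 0.28, 0.05, ("HMM",))])
        b = HerbCompoundList("HDW", [_record("MOL000098", 46.43, 0.28, 0.05, ("HDW",))])
        (rec,) = merge_herb_lists([a, b])
        assert rec.herb_sources == {"HMM", "HDW"}

    def test_single_list_is_identity(self):
        lst = HerbCompoundList("H1", [_record("A", 31, 0.2, 0.1), _record("B", 32, 0.3, 0.2)])
        merged = merge_herb_lists([lst])
        assert [r.mol_id for r in merged] == ["A", "B"]

    def test_conflicting_adme_values_rejected(self):
        a = HerbCompoundList("H1", [_record("A", 31, 0.2, 0.1)])
        b = HerbCompoundList("H2", [_record("A", 35, 0.2, 0.1)])
        with pytest.raises(ValidationError, match="A"):
            merge_herb_lists([a, b])

    def test_study_shape_counts(self, study_fixture):
        """Six herb lists of sizes 87/25/55/202/81/37 with 55 cross-herb
        duplicates merge to 432 unique compounds."""
        from netpharm import read_compound_table

        lists = [
            read_compound_table(study_fixture.files[f"compounds_{h}"], herb_code=h)
            for h in ("HMM", "PHP", "AMK", "RMB", "CZR", "HDW")
        ]
        assert sorted(len(l) for l in lists) == sorted([87, 25, 55, 202, 81, 37])
        merged = merge_herb_lists(lists)
        assert len(merged) == 432
        n_multi = sum(1 for r in merged if len(r.herb_sources) > 1)
        assert n_multi == 55


class TestScreen:
    def test_passing_record(self):
        result = screen_compounds([_record("L", 36.16, 0.25, 0.19)])
        assert result.passed == ["L"]

    def test_whitelisted_failure_is_rescued_with_flags(self):
        result = screen_compounds(
            [_record("D", 36.91, 0.06, -0.27)], whitelist={"D"}
        )
        assert result.rescued == ["D"]
        assert set(result.failures["D"]) == {"DL", "Caco-2"}

    def test_boundary_values_pass(self):
        result = screen_compounds([_record("B", 30.0, 0.18, 0.0)])
        assert result.passed == ["B"]

    def test_reference_table_screen(self, representative_table):
        """The 24-row reference table yields 19 passes; the failing five are
        exactly the rescued whitelist, and with the whitelist nothing is
        rejected."""
        result = screen_compounds(representative_table.compounds, whitelist=RESCUED)
        assert len(result.passed) == 19
        assert set(result.rescued) == RESCUED
        assert result.rejected == []

    @given(
        records=st.lists(
            st.tuples(
                st.floats(0, 120, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
                st.floats(-3, 3, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        ),
        bump=st.floats(0, 20, allow_nan=False),
    )
    def test_partition_and_monotonicity(self, records, bump):
        table = [_record(f"C{i}", ob, dl, c2) for i, (ob, dl, c2) in enumerate(records)]
        base = screen_compounds(table, ScreeningCriteria())
        assert len(base.passed) + len(base.rescued) + len(base.rejected) == len(table)
        stricter = screen_compounds(table, ScreeningCriteria(ob_min=30 + bump))
        assert set(stricter.passed) <= set(base.passed)
        rescued = screen_compounds(table, whitelist={t.mol_id for t in table[:3]})
        assert set(base.active) <= set(rescued.active)
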