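import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import blockscape as bs
from blockscape.tenure import (
    MatchWeights,
    classify_tenure,
    match_score,
    normalize_address,
)

# strategy producing plausible address strings from realistic parts
_street = st.sampled_from(["MAIN", "OAK", "MAPLE HILL", "MLK", "5TH"])
_dir = st.sampled_from(["", "North", "S", "southwest", "NE"])
_type = st.sampled_from(["", "Street", "Ave.", "ROAD", "blvd", "Way"])
_unit = st.sampled_from(["", "Apt 4", "#12", "UNIT B", "Suite 300"])


@st.composite
def addresses(draw):
    parts = [
        str(draw(st.integers(1, 9999))),
        draw(_dir),
        draw(_street),
        draw(_type),
        draw(_unit),
    ]
    return " ".join(p for p in parts if p)


class TestNormalize:
    def test_canonical_decomposition(self):
        a = normalize_address("123 North Main Street")
        assert (a.house_number, a.directional, a.street_name, a.street_type) == (
            "123", "N", ("MAIN",), "ST",
        )

    @pytest.mark.parametrize(
        "raw,field,expected",
        [
            ("456 Oak Avenue Apt 7", "unit", "7"),
            ("456 Oak Avenue #7", "unit", "7"),
            ("9 W Elm Blvd", "directional", "W"),
            ("12 Chestnut", "street_type", ""),
        ],
    )
    def test_component_extraction(self, raw, field, expected):
        assert getattr(normalize_address(raw), field) == expected

    def test_empty_input_gives_empty_form(self):
        assert normalize_address("").is_empty
        assert normalize_address(None).is_empty

    @given(addresses())
    def test_idempotent_on_address_strings(self, raw):
        once = normalize_address(raw)
        twice = normalize_address(once.canonical_text)
        assert (once.house_number, once.directional, once.street_name,
                once.street_type, once.unit) == (
            twice.house_number, twice.directional, twice.street_name,
            twice.street_type, twice.unit,
        )


class TestMatchScore:
    def test_identical_forms_score_one(self):
        a = normalize_address("123 N Main St")
        assert match_score(a, a) == 1.0

    def test_po_box_owner_scores_at_most_cap(self):
        a = normalize_address("123 MAIN ST")
        b = normalize_address("PO BOX 442")
        assert match_score(a, b) <= 0.2

    def test_house_number_mismatch_caps_score(self):
        a = normalize_address("123 N Main St")
        b = normalize_address("125 N Main St")
        assert match_score(a, b) == MatchWeights().house_mismatch_cap

    def test_empty_side_scores_zero(self):
        a = normalize_address("123 Main St")
        assert match_score(a, normalize_address("")) == 0.0

    @given(addresses(), addresses())
    def test_symmetric(self, raw_a, raw_b):
        a, b = normalize_address(raw_a), normalize_address(raw_b)
        assert match_score(a, b) == match_score(b, a)

    @given(addresses(), addresses())
    def test_bounded(self, raw_a, raw_b):
        score = match_score(normalize_address(raw_a), normalize_address(raw_b))
        assert 0.0 <= score <= 1.0


class TestClassify:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["parcel_id", "situs_address", "owner_address"])

    def test_verbatim_match_is_owner_occupied(self):
        calls, errors = classify_tenure(
            self._frame([("p1", "12 Oak St", "12 Oak St")])
        )
        assert not errors
        assert calls.loc[0, "call"] == "owner_occupied"
        assert calls.loc[0, "score"] == 1.0

    def test_equivalent_spellings_match(self):
        calls, _ = classify_tenure(
            self._frame([("p1", "12 North Oak Street", "12 N OAK ST")])
        )
        assert calls.loc[0, "call"] == "owner_occupied"

    def test_missing_owner_address_codes_renter_with_zero_score(self):
        calls, errors = classify_tenure(self._frame([("p1", "12 Oak St", "")]))
        assert not errors
        assert calls.loc[0, "call"] == "renter_occupied"
        assert calls.loc[0, "score"] == 0.0

    def test_strict_mode_emits_unknown_instead(self):
        calls, _ = classify_tenure(self._frame([("p1", "12 Oak St", "")]), strict=True)
        assert calls.loc[0, "call"] == "unknown"

    def test_missing_situs_is_collected_error_and_skipped(self):
        calls, errors = classify_tenure(
            self._frame([("p1", "", "12 Oak St"), ("p2", "3 Elm Ave", "3 Elm Ave")])
        )
        assert len(calls) == 1 and calls.loc[0, "parcel_id"] == "p2"
        assert len(errors) == 1 and "p1" in errors[0]

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_tenure(self._frame([]), threshold=1.5)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_raising_threshold_never_converts_renter_to_owner(self, t1, t2):
        lo, hi = sorted((t1, t2))
        frame = self._frame(
            [
                ("a", "12 Oak St", "12 Oak St"),
                ("b", "12 Oak St", "12 Oak Ave"),
                ("c", "12 Oak St", "99 Pine Rd"),
                ("d", "12 N Oak St", "12 Oak St"),
            ]
        )
        calls_lo, _ = classify_tenure(frame, threshold=lo)
        calls_hi, _ = classify_tenure(frame, threshold=hi)
        owners_hi = set(calls_hi[calls_hi["call"] == "owner_occupied"]["parcel_id"])
        owners_lo = set(calls_lo[calls_lo["call"] == "owner_occupied"]["parcel_id"])
        assert owners_hi <= owners_lo

    def test_recovers_planted_renter_fraction_exactly(self):
        city = bs.generate_city(
            bs.SyntheticConfig(grid_nx=4, grid_ny=4, parcels_per_block=25,
                               renter_fraction=0.3, seed=5)
        )
        calls, errors = classify_tenure(city.parcels)
        assert not errors
        renter_calls = calls["call"] == "renter_occupied"
        truth = city.truth["renter"].reindex(calls["parcel_id"]).to_numpy()
        assert (renter_calls.to_numpy() == truth).all()
        assert renter_calls.mean() == city.truth["renter_fraction_realized"]
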