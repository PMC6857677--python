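"""Lake table I/O, transformation/standardization, consensus filter, splitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from laketsi import (
    LakeSample,
    StandardizationSpec,
    TrophicState,
    apply_standardization,
    consensus_filter,
    fit_standardization,
    holdout_split,
    read_lakes,
    write_lakes,
)
from laketsi.lake_data import (
    DegenerateDataError,
    InsufficientDataError,
    ParseError,
    SchemaError,
    ValidationError,
)


def _write(tmp_path, text, name="lakes.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadLakes:
    def test_well_formed_file_read_in_order(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m\n"
            "A,1.5,600,30,250\n"
            "B,0.4,2100,110,12\n",
        )
        samples = read_lakes(path)
        assert [s.lake_id for s in samples] == ["A", "B"]
        assert samples[0].secchi_depth == 1.5
        assert samples[1].total_phosphorus == 110

    def test_missing_phosphorus_column_is_schema_error(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,elevation_m\nA,1.5,600,250\n",
        )
        with pytest.raises(SchemaError, match="total_phosphorus"):
            read_lakes(path)

    def test_nonpositive_tp_strict_raises_log_domain(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m\nA,1.5,600,0,250\n",
        )
        with pytest.raises(ValidationError, match="log transform domain"):
            read_lakes(path, strict=True)

    def test_nonpositive_tp_lenient_drops_row(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m\n"
            "A,1.5,600,0,250\nB,2.0,500,20,100\n",
        )
        samples = read_lakes(path, strict=False)
        assert [s.lake_id for s in samples] == ["B"]

    def test_non_numeric_value_reports_row(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m\nA,deep,600,30,250\n",
        )
        with pytest.raises(ParseError, match="row 1"):
            read_lakes(path)

    def test_missing_required_field_rows_dropped(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m\n"
            "A,1.5,,30,250\nB,2.0,500,20,100\n",
        )
        samples = read_lakes(path)
        assert [s.lake_id for s in samples] == ["B"]

    def test_labels_and_dialect_round_trip(self, tmp_path, small_lakes):
        path = tmp_path / "out.csv"
        write_lakes(small_lakes, path)
        back = read_lakes(path)
        assert [s.lake_id for s in back] == [s.lake_id for s in small_lakes]
        assert [s.observed_state for s in back] == [s.observed_state for s in small_lakes]

    def test_ordinal_codes_accepted_on_read(self, tmp_path):
        path = _write(
            tmp_path,
            "lake_id,secchi_m,tn_ugl,tp_ugl,elevation_m,trophic_state\n"
            "A,1.5,600,30,250,3\n",
        )
        assert read_lakes(path)[0].observed_state is TrophicState.EUTROPHIC


class TestStandardization:
    def test_symmetric_log_tn_center_and_scale(self):
        lakes = [
            LakeSample(f"l{i}", 1.0 + i, float(np.exp(i + 1)), 10.0 + i, 100.0 * i)
            for i in range(3)
        ]
        spec = fit_standardization(lakes)
        assert spec.centers[1] == pytest.approx(2.0)
        assert spec.scales[1] == pytest.approx(1.0)

    def test_secchi_center_scale_hand_computed(self):
        # logs of {1, 2, 4} m are {0, ln2, 2 ln2}: mean ln2, sample SD ln2
        lakes = [
            LakeSample("a", 1.0, 100.0, 10.0, 0.0),
            LakeSample("b", 2.0, 200.0, 20.0, 10.0),
            LakeSample("c", 4.0, 400.0, 40.0, 20.0),
        ]
        spec = fit_standardization(lakes)
        assert spec.centers[0] == pytest.approx(math.log(2))
        assert spec.scales[0] == pytest.approx(math.log(2))

    def test_constant_elevation_is_degenerate(self):
        lakes = [LakeSample(f"l{i}", 1.0 + i, 100.0 + i, 10.0 + i, 100.0) for i in range(3)]
        with pytest.raises(DegenerateDataError, match="elevation"):
            fit_standardization(lakes)

    def test_sample_at_training_centers_maps_to_zero_row(self, small_lakes):
        spec = fit_standardization(small_lakes)
        center_sample = LakeSample(
            "center",
            float(np.exp(spec.centers[0])),
            float(np.exp(spec.centers[1])),
            float(np.exp(spec.centers[2])),
            spec.centers[3],
        )
        design = apply_standardization([center_sample], spec)
        np.testing.assert_allclose(design.X, np.zeros((1, 4)), atol=1e-12)

    def test_training_set_standardizes_to_mean0_sd1(self, small_lakes):
        spec = fit_standardization(small_lakes)
        design = apply_standardization(small_lakes, spec)
        np.testing.assert_allclose(design.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(design.X.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_direct_arithmetic_with_given_spec(self):
        spec = StandardizationSpec(
            centers=(1.0, 1.0, 1.0, 1.0),
            scales=(2.0, 2.0, 2.0, 2.0),
            log_transformed=(False, False, False, False),
        )
        row = spec.transform(np.array([[3.0, 3.0, 3.0, 3.0]]))
        np.testing.assert_allclose(row, [[1.0, 1.0, 1.0, 1.0]])

    def test_round_trip_recovers_raw_values(self, small_lakes):
        spec = fit_standardization(small_lakes)
        raw = np.array(
            [[s.secchi_depth, s.total_nitrogen, s.total_phosphorus, s.elevation]
             for s in small_lakes]
        )
        back = spec.inverse_transform(spec.transform(raw))
        np.testing.assert_allclose(back, raw, rtol=1e-9)


class TestConsensusFilter:
    def _lake(self, i, refs):
        return LakeSample(
            f"l{i}", 1.0, 100.0, 10.0, 50.0,
            reference_labels=tuple(TrophicState(r) for r in refs) if refs else None,
        )

    def test_unanimous_kept_with_consensus_state(self):
        kept = consensus_filter([self._lake(0, (3, 3, 3))])
        assert len(kept) == 1
        assert kept[0].observed_state is TrophicState.EUTROPHIC

    def test_disagreement_dropped(self):
        kept = consensus_filter([self._lake(0, (1, 2, 1)), self._lake(1, (2, 2, 2))])
        assert [s.lake_id for s in kept] == ["l1"]

    def test_count_over_mixed_fixture(self):
        # brute-force expectation: exactly the all-identical label triples survive
        labels = [(1, 1, 1), (1, 2, 1), (2, 2, 2), (3, 3, 3), (3, 4, 3),
                  (4, 4, 4), (1, 1, 2), (2, 3, 4), (2, 2, 3), (1, 2, 1)]
        expected = sum(1 for t in labels if len(set(t)) == 1)
        kept = consensus_filter([self._lake(i, t) for i, t in enumerate(labels)])
        assert len(kept) == expected == 4

    def test_no_labels_anywhere_is_error(self):
        with pytest.raises(InsufficientDataError):
            consensus_filter([self._lake(0, None)])

    def test_invariant_to_reference_label_order(self):
        labels = [(1, 2, 2), (2, 2, 2), (4, 4, 3)]
        kept_fwd = consensus_filter([self._lake(i, t) for i, t in enumerate(labels)])
        kept_rev = consensus_filter(
            [self._lake(i, tuple(reversed(t))) for i, t in enumerate(labels)]
        )
        assert [s.lake_id for s in kept_fwd] == [s.lake_id for s in kept_rev]


class TestHoldoutSplit:
    def _lakes(self, n):
        return [LakeSample(f"l{i}", 1.0 + i, 100.0 + i, 10.0 + i, float(i)) for i in range(n)]

    def test_90_10_split_sizes(self):
        train, evaluation = holdout_split(self._lakes(100), eval_fraction=0.10, seed=1)
        assert (len(train), len(evaluation)) == (90, 10)

    def test_same_seed_identical_partition(self):
        lakes = self._lakes(37)
        a = holdout_split(lakes, 0.2, seed=9)
        b = holdout_split(lakes, 0.2, seed=9)
        assert [s.lake_id for s in a[0]] == [s.lake_id for s in b[0]]
        assert [s.lake_id for s in a[1]] == [s.lake_id for s in b[1]]

    @given(n=st.integers(2, 120), frac=st.floats(0.05, 0.9), seed=st.integers(0, 2**16))
    def test_partition_law(self, n, frac, seed):
        lakes = self._lakes(n)
        train, evaluation = holdout_split(lakes, frac, seed=seed)
        train_ids = {s.lake_id for s in train}
        eval_ids = {s.lake_id for s in evaluation}
        assert train_ids | eval_ids == {s.lake_id for s in lakes}
        assert not train_ids & eval_ids
        assert len(evaluation) == max(1, round(n * frac))

    def test_different_seeds_same_sizes(self):
        lakes = self._lakes(53)
        sizes = {
            tuple(map(len, holdout_split(lakes, 0.1, seed=s))) for s in range(5)
        }
        assert len(sizes) == 1

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            holdout_split(self._lakes(1), 0.1, seed=0)
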