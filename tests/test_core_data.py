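"""Core data structures, delimited I/O and fit metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoextract import (
    ConfigurationError,
    DomainError,
    ExtractionCurve,
    ParseError,
    StudyDataset,
    ValidationError,
    celsius_to_kelvin,
    goodness_of_fit,
    read_curves,
    relative_change,
    write_curves,
)


class TestExtractionCurve:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValidationError):
            ExtractionCurve(times=[10, 10, 30], concentrations=[1, 2, 3], temperature=30)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValidationError):
            ExtractionCurve(times=[10, 20], concentrations=[1, -2], temperature=30)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError):
            ExtractionCurve(times=[10, 20, 30], concentrations=[1, 2], temperature=30)

    def test_dataset_rejects_duplicate_cell(self):
        curve = ExtractionCurve(times=[10.0], concentrations=[1.0], temperature=30)
        with pytest.raises(ValidationError):
            StudyDataset(curves=[curve, curve])


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        q = goodness_of_fit([1, 2, 3], [1, 2, 3])
        assert q.r_squared == 1.0 and q.mse == 0.0 and q.rmse == 0.0

    def test_hand_computed_example(self):
        # SStot = 2, SSres = 1 -> R2 = 0.5, MSE = 1/3
        q = goodness_of_fit([1, 2, 3], [1, 2, 4])
        assert q.r_squared == pytest.approx(0.5)
        assert q.mse == pytest.approx(1 / 3)
        assert q.rmse == pytest.approx(0.57735, abs=1e-5)

    def test_constant_observations_rejected(self):
        with pytest.raises(DomainError):
            goodness_of_fit([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            goodness_of_fit([1, 2, 3], [1, 2])

    def test_negative_r_squared_not_clipped(self):
        q = goodness_of_fit([1, 2, 3], [10, -10, 10])
        assert q.r_squared < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=3,
            max_size=20,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_equivariance_and_rmse_identity(self, data, seed):
        obs = np.array([d[0] for d in data])
        pred = np.array([d[1] for d in data])
        if np.ptp(obs) == 0:
            return
        q = goodness_of_fit(obs, pred)
        assert q.rmse**2 == pytest.approx(q.mse, rel=1e-12)
        perm = np.random.default_rng(seed).permutation(obs.size)
        q2 = goodness_of_fit(obs[perm], pred[perm])
        assert q2.r_squared == pytest.approx(q.r_squared, rel=1e-9, abs=1e-12)
        assert q2.mse == pytest.approx(q.mse, rel=1e-9, abs=1e-15)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "reference, value, expected",
        [
            (8.728, 10.410, 19.27),  # diffusivity rise 30 -> 40 degC
            (12.690, 11.050, -12.92),  # diffusivity fall 50 -> 60 degC
            (5.0, 5.0, 0.0),
        ],
    )
    def test_signed_percent_change(self, reference, value, expected):
        assert relative_change(reference, value) == pytest.approx(expected, abs=0.005)

    def test_zero_reference_rejected(self):
        with pytest.raises(DomainError):
            relative_change(0.0, 1.0)


def test_kelvin_convention_uses_integer_offset():
    assert celsius_to_kelvin(30.0) == 303.0
    assert list(celsius_to_kelvin([30.0, 70.0])) == [303.0, 343.0]


class TestDelimitedIO:
    def _write(self, tmp_path, text, name="data.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_times_sorted_on_read(self, tmp_path):
        p = self._write(
            tmp_path,
            "time,concentration,temperature,method,replicate\n"
            "20,5,30,UAE,1\n10,2,30,UAE,1\n30,7,30,UAE,1\n",
        )
        ds = read_curves(p)
        assert len(ds) == 1
        assert list(ds.curves[0].times) == [10, 20, 30]
        assert list(ds.curves[0].concentrations) == [2, 5, 7]

    def test_dialect_renames_columns(self, tmp_path):
        p = self._write(
            tmp_path,
            "t_min,conc,temp_C,method,replicate\n10,2,40,UAE,1\n20,5,40,UAE,1\n",
        )
        ds = read_curves(
            p, dialect={"time": "t_min", "concentration": "conc", "temperature": "temp_C"}
        )
        assert ds.curves[0].temperature == 40.0

    def test_missing_column_names_the_column(self, tmp_path):
        p = self._write(tmp_path, "time,concentration,method,replicate\n10,2,UAE,1\n")
        with pytest.raises(ConfigurationError, match="temperature"):
            read_curves(p)

    def test_non_numeric_cell_cites_row(self, tmp_path):
        p = self._write(
            tmp_path,
            "time,concentration,temperature,method,replicate\n"
            "10,2,30,UAE,1\n20,NA,30,UAE,1\n",
        )
        with pytest.raises(ParseError, match="row 3"):
            read_curves(p)

    def test_duplicate_time_rows_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "time,concentration,temperature,method,replicate\n"
            "10,2,30,UAE,1\n10,3,30,UAE,1\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_curves(p)

    def test_unknown_columns_preserved_in_meta(self, tmp_path):
        p = self._write(
            tmp_path,
            "time,concentration,temperature,method,replicate,ethanol_pct\n"
            "10,2,30,UAE,1,50\n20,5,30,UAE,1,50\n",
        )
        assert read_curves(p).curves[0].meta["ethanol_pct"] == "50"

    def test_tab_separated_accepted(self, tmp_path):
        p = self._write(
            tmp_path,
            "time\tconcentration\ttemperature\tmethod\treplicate\n"
            "10\t2\t30\tUAE\t1\n20\t5\t30\tUAE\t1\n",
            name="data.tsv",
        )
        assert len(read_curves(p)) == 1

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        curves = [
            ExtractionCurve(
                times=np.arange(10.0, 90, 10),
                concentrations=rng.uniform(10, 150, 8),
                temperature=t,
                method=m,
                replicate=str(r),
                meta={"ethanol_pct": "50"},
            )
            for t in (30.0, 50.0)
            for m in ("UAE", "CSE")
            for r in (1, 2)
        ]
        ds = StudyDataset(curves=curves)
        path = tmp_path / "roundtrip.csv"
        write_curves(ds, path)
        back = read_curves(path)
        assert len(back) == len(ds)
        by_key = {c.key: c for c in back}
        for curve in ds:
            other = by_key[curve.key]
            np.testing.assert_allclose(other.times, curve.times, rtol=1e-9)
            np.testing.assert_allclose(
                other.concentrations, curve.concentrations, rtol=1e-9
            )
            assert other.meta["ethanol_pct"] == "50"
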