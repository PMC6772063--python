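"""Container validation, CSV round-trip, missing-data policies and plotting."""

import numpy as np
import pytest

from scedmed import (ConfigurationError, InfeasibleError, MissingPolicy,
                     SCEDDataset, SCEDSeries, ValidationError,
                     apply_missing_policy, plot_dataset, read_sced_csv,
                     write_sced_csv)

from conftest import make_series


def _write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCsv:
    def test_well_formed_round_trip(self, tmp_path, simple_dataset):
        path = tmp_path / "rt.csv"
        write_sced_csv(simple_dataset, path)
        ds = read_sced_csv(path, {"mediator": "coping", "outcome": "anxiety"})
        assert ds.n_phases == 2
        assert len(ds.mediator.time) == 10
        np.testing.assert_array_equal(ds.mediator.value,
                                      simple_dataset.mediator.value)

    def test_round_trip_preserves_missingness_exactly(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 72
        values = rng.integers(0, 9, size=(2, n)).astype(float)
        miss = rng.choice(n, size=10, replace=False)
        values[0, miss[:5]] = np.nan
        values[1, miss[5:]] = np.nan
        phase = np.array(["B"] * 26 + ["C"] * 32 + ["D"] * 14, dtype=object)
        ds = SCEDDataset(make_series(values[0], phase, name="m"),
                         make_series(values[1], phase, name="y"))
        path = tmp_path / "rt.csv"
        write_sced_csv(ds, path)
        back = read_sced_csv(path, {"mediator": "m", "outcome": "y"})
        for a, b in ((ds.mediator, back.mediator), (ds.outcome, back.outcome)):
            np.testing.assert_array_equal(a.time, b.time)
            assert list(a.phase) == list(b.phase)
            np.testing.assert_array_equal(np.isnan(a.value), np.isnan(b.value))
            np.testing.assert_array_equal(a.value[~np.isnan(a.value)],
                                          b.value[~np.isnan(b.value)])

    def test_missing_cells_counted(self, tmp_path):
        # 14.5% of 72 days -> 10 empty mediator cells, preserved as NaN
        rows = ["day,phase,coping,anxiety"]
        missing_days = {3, 9, 15, 30, 33, 41, 50, 61, 65, 70}
        for d in range(1, 73):
            ph = "B" if d <= 26 else ("C" if d <= 58 else "D")
            c = "" if d in missing_days else "4"
            rows.append(f"{d},{ph},{c},5")
        path = _write_csv(tmp_path, "\n".join(rows) + "\n")
        ds = read_sced_csv(path, {"time": "day", "phase": "phase",
                                  "mediator": "coping", "outcome": "anxiety"})
        assert int(np.isnan(ds.mediator.value).sum()) == 10
        by_phase = {p: int(np.isnan(ds.mediator.phase_values(p, drop_missing=False)).sum())
                    for p in ds.phase_order}
        assert by_phase == {"B": 3, "C": 4, "D": 3}

    def test_noncontiguous_phase_rejected(self, tmp_path):
        path = _write_csv(tmp_path, "time,phase,mediator,outcome\n"
                          "1,B,1,1\n2,B,1,1\n3,C,1,1\n4,C,1,1\n5,B,1,1\n")
        with pytest.raises(ValidationError) as e:
            read_sced_csv(path)
        assert e.value.code == "noncontiguous_phase"
        assert "5" in str(e.value)  # names the offending time point

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = _write_csv(tmp_path, "time,phase,mediator\n1,B,1\n")
        with pytest.raises(ConfigurationError):
            read_sced_csv(path)

    def test_duplicate_time_rejected(self, tmp_path):
        path = _write_csv(tmp_path, "time,phase,mediator,outcome\n"
                          "1,B,1,1\n1,B,2,2\n2,B,1,1\n3,C,1,1\n")
        with pytest.raises(ValidationError) as e:
            read_sced_csv(path)
        assert e.value.code == "duplicate_time"


class TestValidationCorpus:
    """Every structurally bad input is rejected with a distinct error code."""

    def test_nonmonotone_time(self):
        with pytest.raises(ValidationError) as e:
            make_series([1, 2, 3], ["B", "B", "C"], time=[3, 2, 5])
        assert e.value.code == "nonmonotone_time"

    def test_interleaved_phases(self):
        with pytest.raises(ValidationError) as e:
            make_series([1, 2, 3, 4], ["B", "C", "B", "C"])
        assert e.value.code == "noncontiguous_phase"

    def test_out_of_bounds_score(self):
        with pytest.raises(ValidationError) as e:
            make_series([1, 9, 3], ["B", "B", "C"], scale_bounds=(0, 8))
        assert e.value.code == "out_of_bounds"

    def test_missing_values_exempt_from_bounds(self):
        s = make_series([1, np.nan, 3], ["B", "B", "C"], scale_bounds=(0, 8))
        assert np.isnan(s.value[1])

    def test_mismatched_index(self):
        m = make_series([1, 2], ["B", "C"])
        y = make_series([1, 2], ["B", "C"], time=[1, 3])
        with pytest.raises(ValidationError) as e:
            SCEDDataset(m, y)
        assert e.value.code == "index_mismatch"

    def test_phase_order_must_match(self):
        m = make_series([1, 2, 3, 4], ["B", "B", "C", "C"])
        y = make_series([1, 2, 3, 4], ["B", "B", "C", "C"])
        with pytest.raises(ValidationError) as e:
            SCEDDataset(m, y, phase_order=["C", "B"])
        assert e.value.code == "phase_order"


class TestMissingPolicy:
    def test_bad_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            MissingPolicy("impute")

    def test_listwise_identity_when_complete(self, simple_dataset):
        out = apply_missing_policy(simple_dataset, MissingPolicy("listwise"))
        np.testing.assert_array_equal(out.mediator.value,
                                      simple_dataset.mediator.value)
        np.testing.assert_array_equal(out.mediator.time, simple_dataset.mediator.time)

    def test_listwise_compresses_calendar(self, dataset_with_gap):
        out = apply_missing_policy(dataset_with_gap, MissingPolicy("listwise"))
        np.testing.assert_array_equal(out.mediator.time, [1, 2, 3, 4, 5, 6])
        np.testing.assert_array_equal(out.mediator.value, [1, 2, 4, 5, 6, 7])
        assert out.time_basis == "compressed"

    def test_calendar_drops_nothing(self, dataset_with_gap):
        out = apply_missing_policy(dataset_with_gap, MissingPolicy("calendar"))
        assert len(out.mediator.time) == 7
        assert np.isnan(out.mediator.value[2])
        assert out.time_basis == "calendar"

    def test_listwise_idempotent(self, dataset_with_gap):
        once = apply_missing_policy(dataset_with_gap, MissingPolicy("listwise"))
        twice = apply_missing_policy(once, MissingPolicy("listwise"))
        np.testing.assert_array_equal(once.mediator.time, twice.mediator.time)
        np.testing.assert_array_equal(once.mediator.value, twice.mediator.value)

    def test_listwise_can_starve_a_phase(self):
        time = np.arange(1, 9)
        phase = np.array(["B"] * 4 + ["C"] * 4, dtype=object)
        med = np.array([1, 2, 3, 4, np.nan, np.nan, 5, 6])
        out_ = np.ones(8)
        ds = SCEDDataset(make_series(med, phase), make_series(out_, phase))
        with pytest.raises(InfeasibleError) as e:
            apply_missing_policy(ds, MissingPolicy("listwise"))
        assert "C" in str(e.value)


class TestPlot:
    def test_plot_written_and_nonempty(self, tmp_path, simple_dataset):
        out = tmp_path / "fig.png"
        fig = plot_dataset(simple_dataset, out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt
        plt.close(fig)

    def test_three_phases_two_boundary_lines(self, tmp_path):
        phase = np.array(["B"] * 4 + ["C"] * 4 + ["D"] * 4, dtype=object)
        vals = np.arange(12, dtype=float)
        ds = SCEDDataset(make_series(vals, phase), make_series(vals, phase))
        fig = plot_dataset(ds)
        for ax in fig.axes:
            vlines = [ln for ln in ax.lines
                      if len(set(ln.get_xdata())) == 1 and len(ln.get_xdata()) == 2]
            assert len(vlines) == 2
        import matplotlib.pyplot as plt
        plt.close(fig)

    def test_missing_points_stay_gaps(self, dataset_with_gap):
        fig = plot_dataset(dataset_with_gap)
        ydata = fig.axes[0].lines[0].get_ydata()
        assert np.isnan(np.asarray(ydata, dtype=float)).any()
        import matplotlib.pyplot as plt
        plt.close(fig)
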