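"""Round trips and validation for image stacks and cohort tables."""

import numpy as np
import pandas as pd
import pytest

import retvol as rv
from retvol import oct_io, phantom as ph


@pytest.fixture(scope="module")
def rendered_stack(default_phantom):
    vol, _ = default_phantom
    return ph.render_bscan_images(vol, ph.PhantomParams())


class TestBScanStackIO:
    @pytest.mark.parametrize("fmt", ["png", "bmp"])
    def test_roundtrip_bit_exact(self, rendered_stack, tmp_path, fmt):
        oct_io.write_bscan_stack(rendered_stack, tmp_path / "stack", fmt=fmt)
        back = oct_io.read_bscan_stack(tmp_path / "stack")
        assert (back.images == rendered_stack.images).all()
        assert back.geometry == rendered_stack.geometry

    def test_count_mismatch_is_named(self, rendered_stack, tmp_path):
        d = oct_io.write_bscan_stack(rendered_stack, tmp_path / "stack")
        next(iter(sorted(d.glob("bscan_*.png")))).unlink()
        with pytest.raises(ValueError, match="expected 25 .* found 24"):
            oct_io.read_bscan_stack(d)

    def test_dimension_mismatch_names_file(self, rendered_stack, tmp_path):
        import imageio.v3 as iio

        d = oct_io.write_bscan_stack(rendered_stack, tmp_path / "stack")
        bad = d / "bscan_007.png"
        iio.imwrite(bad, np.zeros((496, 513), dtype=np.uint8))
        with pytest.raises(ValueError, match="bscan_007.png"):
            oct_io.read_bscan_stack(d)

    def test_label_volume_roundtrip(self, default_phantom, tmp_path):
        vol, _ = default_phantom
        oct_io.write_label_volume(vol, tmp_path / "labels")
        back = oct_io.read_label_volume(tmp_path / "labels")
        assert (back.labels == vol.labels).all()
        assert back.geometry == vol.geometry


class TestCohortTableIO:
    def test_roundtrip_identity(self, default_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        oct_io.write_cohort_table(default_cohort, p)
        back = oct_io.read_cohort_table(p)
        assert len(back) == len(default_cohort)
        assert back.rejected == []
        a = default_cohort.to_dataframe()
        b = back.to_dataframe()
        assert (a[["animal_id", "eye", "sex", "origin"]] == b[["animal_id", "eye", "sex", "origin"]]).all().all()
        for col in rv.RegionVolumes.from_slices(np.ones(9)).as_dict():
            if col == "clipped_fraction":
                continue
            assert np.abs(a[col] - b[col]).max() <= 1e-9

    def test_empty_cohort_writes_header_only(self, tmp_path):
        p = oct_io.write_cohort_table(oct_io.CohortTable(), tmp_path / "empty.csv")
        df = pd.read_csv(p)
        assert len(df) == 0
        assert "Z1" in df.columns and "S9" in df.columns

    def test_z1_field_equals_s1_field(self, tmp_path):
        rec = oct_io.EyeRecord(
            animal_id="A1",
            eye="OD",
            sex="male",
            origin="Asia",
            volumes=rv.RegionVolumes.from_slices(np.linspace(0.1, 0.3, 9)),
        )
        p = oct_io.write_cohort_table(oct_io.CohortTable(records=[rec]), tmp_path / "one.csv")
        df = pd.read_csv(p)
        assert df.loc[0, "Z1"] == df.loc[0, "S1"]

    def test_origin_case_variants_normalised(self, tmp_path):
        df = pd.DataFrame(
            {
                "animal_id": ["A1", "A2", "A3"],
                "eye": ["OD", "os", "Right"],
                "sex": ["M", "female", "f"],
                "origin": ["MAURITIUS", "asian", "Vietnam"],
                **{f"S{i}": [0.2] * 3 for i in range(1, 10)},
            }
        )
        p = tmp_path / "foreign.csv"
        df.to_csv(p, index=False)
        cohort = oct_io.read_cohort_table(p)
        origins = [r.origin for r in cohort.records]
        assert origins == ["Mauritius", "Asia", "unknown"]
        assert [r.eye for r in cohort.records] == ["OD", "OS", "OD"]

    def test_column_map_for_foreign_schema(self, tmp_path):
        df = pd.DataFrame(
            {
                "monkey": ["A1"],
                "side": ["OD"],
                "gender": ["male"],
                "source": ["Mauritius"],
                **{f"slice{i}": [0.2] for i in range(1, 10)},
            }
        )
        p = tmp_path / "foreign.csv"
        df.to_csv(p, index=False)
        cmap = {"monkey": "animal_id", "side": "eye", "gender": "sex", "source": "origin"}
        cmap |= {f"slice{i}": f"S{i}" for i in range(1, 10)}
        cohort = oct_io.read_cohort_table(p, column_map=cmap)
        assert len(cohort) == 1
        assert cohort.records[0].volumes.Z2 == pytest.approx(0.8)

    def test_missing_mandatory_columns_listed(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"animal_id": ["A1"], "eye": ["OD"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="sex"):
            oct_io.read_cohort_table(p)

    def test_unparseable_rows_rejected_with_diagnostics(self, tmp_path):
        rows = {
            "animal_id": ["A1", "A2"],
            "eye": ["OD", "OD"],
            "sex": ["male", "male"],
            "origin": ["Asia", "Asia"],
        }
        rows |= {f"S{i}": [0.2, 0.2] for i in range(1, 10)}
        df = pd.DataFrame(rows)
        df["S5"] = df["S5"].astype(object)
        df.loc[1, "S5"] = "oops"
        p = tmp_path / "partial.csv"
        df.to_csv(p, index=False)
        cohort = oct_io.read_cohort_table(p)
        # no silent drops: records + rejected account for every input row
        assert len(cohort) + len(cohort.rejected) == 2
        assert cohort.rejected[0][1] == "unparseable slice volume"

    def test_inconsistent_zone_cross_check_rejects_row(self, tmp_path):
        rows = {
            "animal_id": ["A1"],
            "eye": ["OD"],
            "sex": ["male"],
            "origin": ["Asia"],
            **{f"S{i}": [0.2] for i in range(1, 10)},
            "Z2": [0.9],  # slices say 0.8
        }
        p = tmp_path / "inconsistent.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        cohort = oct_io.read_cohort_table(p)
        assert len(cohort) == 0
        assert "Z2 inconsistent" in cohort.rejected[0][1]

    def test_zones_reconstructed_when_only_slices_present(self, tmp_path):
        rows = {
            "animal_id": ["A1"],
            "eye": ["OS"],
            "sex": ["female"],
            "origin": ["Mauritius"],
            "Z1": [0.2],  # stands in for S1
            **{f"S{i}": [0.25] for i in range(2, 10)},
        }
        p = tmp_path / "slices_only.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        cohort = oct_io.read_cohort_table(p)
        v = cohort.records[0].volumes
        assert v.S1 == 0.2
        assert v.Z3 == pytest.approx(1.0)
        assert v.Q1 == pytest.approx(0.2 / 4 + 0.5)

    def test_duplicate_eye_rejected(self):
        vols = rv.RegionVolumes.from_slices(np.full(9, 0.2))
        rec = dict(animal_id="A1", eye="OD", sex="male", origin="Asia", volumes=vols)
        with pytest.raises(ValueError, match="duplicate"):
            oct_io.CohortTable(records=[oct_io.EyeRecord(**rec), oct_io.EyeRecord(**rec)])

    def test_summary_statistics_survive_roundtrip(self, default_cohort, tmp_path):
        from retvol.refstats import summarize

        p = oct_io.write_cohort_table(default_cohort, tmp_path / "c.csv")
        back = oct_io.read_cohort_table(p)
        a = summarize(default_cohort)
        b = summarize(back)
        assert a.mean == pytest.approx(b.mean, abs=1e-9)
        assert a.cv == pytest.approx(b.cv, abs=1e-7)
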