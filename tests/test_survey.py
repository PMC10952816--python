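"""Survey data container, CSV round-trips, and the packaged 30-site table."""

import numpy as np
import pandas as pd
import pytest

from msam.exceptions import SchemaError, ValidationError
from msam.survey import (DetectionRecord, SurveyDataset, detection_site_count,
                         fixture_to_json, pearson_r, read_survey_csv,
                         summary_stats, write_survey_csv)


def make_dataset(S=2, J=3, K=2, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3, size=(S, J, K))
    days = rng.uniform(0, 180, size=(J, K))
    temp = rng.uniform(5, 25, size=(J, K))
    dry = np.zeros((J, K), bool)
    dry[0, 1] = True
    counts[:, 0, 1] = 0
    return SurveyDataset([f"s{i}" for i in range(S)], [f"p{j}" for j in range(J)],
                         counts, days, temp, dry)


class TestSurveyDataset:
    def test_roundtrip_csv_is_lossless(self, tmp_path):
        d = make_dataset()
        path = tmp_path / "counts.csv"
        write_survey_csv(d, path)
        back = read_survey_csv(path)
        assert back.equals(d)

    def test_row_order_does_not_matter(self, tmp_path):
        d = make_dataset()
        path = tmp_path / "counts.csv"
        write_survey_csv(d, path)
        df = pd.read_csv(path).sample(frac=1.0, random_state=1)
        shuffled = tmp_path / "shuffled.csv"
        df.to_csv(shuffled, index=False)
        back = read_survey_csv(shuffled)
        assert back.reindexed(d.species_ids, d.site_ids).equals(d)

    @pytest.mark.parametrize("bad_count", [-1, 2.5])
    def test_invalid_counts_rejected(self, tmp_path, bad_count):
        d = make_dataset()
        path = tmp_path / "counts.csv"
        write_survey_csv(d, path)
        df = pd.read_csv(path)
        df["count"] = df["count"].astype(object)
        df.loc[3, "count"] = bad_count
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_survey_csv(path)

    def test_missing_column_named_in_error(self, tmp_path):
        d = make_dataset()
        path = tmp_path / "counts.csv"
        write_survey_csv(d, path)
        df = pd.read_csv(path).drop(columns=["water_temp"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="water_temp"):
            read_survey_csv(path)

    def test_shapes_from_long_file(self, tmp_path):
        d = make_dataset(S=4, J=30, K=3)
        d.dry_flag[:] = False
        path = tmp_path / "counts.csv"
        write_survey_csv(d, path)
        back = read_survey_csv(path)
        assert back.counts.shape == (4, 30, 3)

    def test_site_table_roundtrip_preserves_missing(self, tmp_path):
        from msam.survey import SiteTable, read_site_csv, write_site_csv

        df = pd.DataFrame({
            "sampled_area_m2": [300.0, 5000.0, 90.5],
            "pct_connected": [0.0, 55.5, 100.0],
            "ph": [7.1, np.nan, 8.2],
            "conductivity": [300.0, 420.0, np.nan],
        }, index=pd.Index(["a", "b", "c"], name="site"))
        blocks = {"chemistry": ["ph", "conductivity"]}
        table = SiteTable(df, blocks)
        path = tmp_path / "sites.csv"
        write_site_csv(table, path)
        back = read_site_csv(path, blocks=blocks)
        pd.testing.assert_frame_equal(back.data, table.data, check_names=False)
        assert np.isnan(back.data.loc["b", "ph"])

    def test_dry_surveys_must_be_zero(self):
        d = make_dataset()
        counts = d.counts.copy()
        counts[0, 0, 1] = 5  # dry cell
        with pytest.raises(ValidationError, match="dry"):
            SurveyDataset(d.species_ids, d.site_ids, counts, d.days,
                          d.water_temp, d.dry_flag)


class TestFixtureTable:
    def test_dimensions(self, fixture_table):
        table, records = fixture_table
        assert len(table.data) == 30
        assert len({r.species_id for r in records}) == 4

    @pytest.mark.parametrize("species,stage,n_sites", [
        ("Bufbuf", "larvae", 11),
        ("Pelcom", "larvae", 6),
        ("Hylarb", "larvae", 4),
        ("Randal", "larvae", 4),
        ("Randal", "egg_mass", 20),
    ])
    def test_detection_tallies(self, fixture_table, species, stage, n_sites):
        _, records = fixture_table
        assert detection_site_count(records, species, stage) == n_sites

    def test_site_1_and_14_rows(self, fixture_table):
        table, records = fixture_table
        by = {(r.species_id, r.site_id, r.stage): r.detected for r in records}
        assert by[("Bufbuf", "1", "larvae")] and not by[("Bufbuf", "1", "egg_mass")]
        assert by[("Randal", "1", "egg_mass")] and by[("Randal", "1", "larvae")]
        assert table.data.loc["1", "hydroperiod"] == "permanent"
        assert table.data.loc["1", "pct_connected"] == 0
        assert table.data.loc["1", "large_fish_richness"] == 2
        assert table.data.loc["14", "pct_connected"] == 1.5
        assert table.data.loc["14", "large_fish_richness"] == 1

    def test_hydrology_and_fish_site_classes(self, fixture_table):
        table, _ = fixture_table
        eph = table.data["hydroperiod"] == "ephemeral"
        zero_fish = table.data["large_fish_richness"] == 0
        assert eph.sum() == 5
        assert zero_fish.sum() == 4
        assert (zero_fish & eph).sum() == 3

    def test_json_export_roundtrips(self, tmp_path, fixture_table):
        import json
        text = fixture_to_json(tmp_path / "t1.json")
        payload = json.loads((tmp_path / "t1.json").read_text())
        assert payload == json.loads(text)
        assert len(payload["sites"]) == 30
        assert len(payload["detections"]) == 30 * 4 * 2


class TestSummaries:
    def test_connectivity_and_fish_summaries(self, fixture_table):
        table, _ = fixture_table
        from msam.survey import round_half_up
        m, sd, lo, hi = summary_stats(table.data["pct_connected"])
        assert (round_half_up(m, 1), round_half_up(sd, 1)) == (36.3, 35.7)
        assert (lo, hi) == (0.0, 100.0)
        m, sd, _, _ = summary_stats(table.data["large_fish_richness"])
        assert (round_half_up(m, 1), round_half_up(sd, 1)) == (4.5, 2.5)

    def test_summary_edge_cases(self):
        assert summary_stats([5, 5, 5]) == (5.0, 0.0, 5.0, 5.0)
        with pytest.raises(ValidationError):
            summary_stats([])

    def test_fish_connectivity_correlation(self, fixture_table):
        table, _ = fixture_table
        r = pearson_r(table.data["large_fish_richness"], table.data["pct_connected"])
        assert round(r, 3) == 0.703

    def test_correlation_identities(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValidationError):
            pearson_r(x, np.zeros(20))

    def test_detection_count_edge_cases(self, fixture_table):
        _, records = fixture_table
        assert detection_site_count([], "anything", "larvae") == 0
        with pytest.raises(KeyError):
            detection_site_count(records, "Tritur", "larvae")
        with pytest.raises(ValidationError):
            DetectionRecord("Bufbuf", "1", "adult", True)
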