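import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtrap_msom.ingest import (aggregate_taxa, build_detection_history,
                                 detection_categories, filter_independent,
                                 image_category_percentages, naive_estimates,
                                 read_camera_records, read_deployments,
                                 DetectionHistory)
from conftest import make_deployments, make_records


class TestReadCameraRecords:
    def test_reads_valid_rows_in_order(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,kind,species,timestamp\n"
            "A,wildlife,deer,2017-01-01 10:00:00\n"
            "B,human,,2017-01-02 11:00:00\n"
            "A,blank,,2017-01-03 12:00:00\n")
        df = read_camera_records(path)
        assert len(df) == 3
        assert list(df["site"]) == ["A", "B", "A"]
        assert df["timestamp"].dt.hour.tolist() == [10, 11, 12]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("site,kind,species\nA,wildlife,deer\n")
        with pytest.raises(ValueError, match="timestamp"):
            read_camera_records(path)

    def test_unparseable_timestamp_cites_line(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "site,kind,species,timestamp\n"
            "A,wildlife,deer,2017-01-01 10:00:00\n"
            "A,wildlife,deer,2017-13-45 99:00\n")
        with pytest.raises(ValueError, match="line.*3"):
            read_camera_records(path)


class TestAggregateTaxa:
    def test_clumps_mapped_labels(self):
        recs = make_records([
            ("A", "wildlife", "Apodemus gorkha", "2017-01-01 10:00"),
            ("A", "wildlife", "Mus cervicolor", "2017-01-01 12:00"),
            ("A", "wildlife", "deer", "2017-01-01 14:00")])
        mapping = {"Apodemus gorkha": "Mouse spp.",
                   "Mus cervicolor": "Mouse spp."}
        out = aggregate_taxa(recs, mapping)
        assert list(out["species"]) == ["Mouse spp.", "Mouse spp.", "deer"]
        assert len(out) == len(recs)

    @pytest.mark.parametrize("mapping", [{}, {"absent label": "group"}])
    def test_identity_when_nothing_matches(self, mapping):
        recs = make_records([("A", "wildlife", "deer", "2017-01-01 10:00")])
        out = aggregate_taxa(recs, mapping)
        pd.testing.assert_frame_equal(out, recs)


class TestFilterIndependent:
    def _two_apart(self, minutes):
        return make_records([
            ("A", "wildlife", "deer", "2017-01-01 10:00:00"),
            ("A", "wildlife", "deer",
             pd.Timestamp("2017-01-01 10:00:00")
             + pd.Timedelta(minutes=minutes))])

    @pytest.mark.parametrize("gap,expected", [(30, 1), (61, 2), (60, 2)])
    def test_window_rule_with_inclusive_tie(self, gap, expected):
        assert len(filter_independent(self._two_apart(gap))) == expected

    def test_greedy_chain_keeps_every_other(self):
        base = pd.Timestamp("2017-01-01 08:00:00")
        recs = make_records([
            ("A", "wildlife", "deer", base + pd.Timedelta(minutes=m))
            for m in (0, 30, 60, 90, 120)])
        kept = filter_independent(recs)
        minutes = ((kept["timestamp"] - base).dt.total_seconds() / 60).tolist()
        assert minutes == [0, 60, 120]

    def test_streams_are_per_site_species_and_kind(self):
        recs = make_records([
            ("A", "wildlife", "deer", "2017-01-01 10:00"),
            ("A", "wildlife", "boar", "2017-01-01 10:10"),
            ("B", "wildlife", "deer", "2017-01-01 10:20"),
            ("A", "human", None, "2017-01-01 10:30"),
            ("A", "livestock", None, "2017-01-01 10:40")])
        assert len(filter_independent(recs)) == 5

    def test_window_zero_retains_all(self):
        recs = self._two_apart(1)
        assert len(filter_independent(recs, 0)) == 2

    def test_idempotent_and_monotone_in_window(self):
        rng = np.random.default_rng(42)
        base = pd.Timestamp("2017-01-01")
        recs = make_records([
            ("A", "wildlife", "deer",
             base + pd.Timedelta(minutes=float(m)))
            for m in np.sort(rng.uniform(0, 600, size=40))])
        prev = len(recs) + 1
        for window in (0, 15, 60, 120):
            once = filter_independent(recs, window)
            twice = filter_independent(once, window)
            pd.testing.assert_frame_equal(
                once.reset_index(drop=True), twice.reset_index(drop=True))
            assert len(once) <= prev
            prev = len(once)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 5000), min_size=1, max_size=25),
           st.integers(0, 180))
    def test_retained_gaps_respect_window(self, minutes, window):
        """Every pair of consecutive retained records is >= window apart,
        and re-filtering is a no-op."""
        base = pd.Timestamp("2017-01-01")
        recs = make_records([
            ("A", "wildlife", "deer", base + pd.Timedelta(minutes=m))
            for m in sorted(minutes)])
        kept = filter_independent(recs, window)
        gaps = kept["timestamp"].diff().dropna()
        assert (gaps >= pd.Timedelta(minutes=window)).all()
        again = filter_independent(kept, window)
        assert len(again) == len(kept)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            filter_independent(self._two_apart(30), -1)


class TestBuildDetectionHistory:
    def test_effort_is_inclusive_day_count(self):
        dep = make_deployments(["A"], days=74)
        recs = make_records([("A", "wildlife", "deer", "2017-01-05 10:00")])
        h = build_detection_history(recs, dep)
        assert h.n.tolist() == [74]

    def test_counts_detection_days_not_records(self):
        dep = make_deployments(["A"], days=30)
        recs = make_records([
            ("A", "wildlife", "deer", "2017-01-02 08:00"),
            ("A", "wildlife", "deer", "2017-01-02 20:00"),  # same occasion
            ("A", "wildlife", "deer", "2017-01-10 08:00"),
            ("A", "wildlife", "deer", "2017-01-20 08:00")])
        h = build_detection_history(recs, dep)
        assert h.y.tolist() == [[3]]

    def test_same_day_collapse_matches_brute_force(self):
        rng = np.random.default_rng(3)
        dep = make_deployments(["A", "B"], days=20)
        rows = []
        for _ in range(60):
            site = rng.choice(["A", "B"])
            ts = (pd.Timestamp("2017-01-01")
                  + pd.Timedelta(days=int(rng.integers(0, 20)),
                                 hours=float(rng.uniform(0, 24))))
            rows.append((site, "wildlife", "deer", ts))
        recs = make_records(rows)
        h = build_detection_history(recs, dep)
        for j, site in enumerate(["A", "B"]):
            days = {ts.date() for s, _, _, ts in rows if s == site}
            assert h.y[0, j] == len(days)

    def test_occasion_days_floor_drops_trailing_partial(self):
        dep = make_deployments(["A"], days=10)
        recs = make_records([
            ("A", "wildlife", "deer", "2017-01-01 10:00"),
            ("A", "wildlife", "deer", "2017-01-10 10:00")])  # day 9 -> occ 3
        h = build_detection_history(recs, dep, occasion_days=3)
        assert h.n.tolist() == [3]
        assert h.y.tolist() == [[1]]  # second record fell in the dropped tail

    def test_record_outside_window_is_error(self):
        dep = make_deployments(["A"], days=10)
        recs = make_records([("A", "wildlife", "deer", "2017-03-01 10:00")])
        with pytest.raises(ValueError, match="outside"):
            build_detection_history(recs, dep)

    def test_unknown_site_is_error(self):
        dep = make_deployments(["A"], days=10)
        recs = make_records([("Z", "wildlife", "deer", "2017-01-02 10:00")])
        with pytest.raises(ValueError, match="Z"):
            build_detection_history(recs, dep)

    def test_row_order_invariance_and_bounds(self):
        rng = np.random.default_rng(11)
        dep = make_deployments(["A", "B", "C"], days=15)
        rows = [(rng.choice(["A", "B", "C"]), "wildlife",
                 rng.choice(["deer", "cat"]),
                 pd.Timestamp("2017-01-01")
                 + pd.Timedelta(days=int(rng.integers(0, 15)),
                                hours=float(rng.uniform(0, 24))))
                for _ in range(50)]
        recs = make_records(rows)
        h1 = build_detection_history(recs, dep)
        h2 = build_detection_history(
            recs.sample(frac=1.0, random_state=5), dep)
        assert np.array_equal(h1.y, h2.y)
        assert (h1.y <= h1.n[None, :]).all()

    def test_nonwildlife_records_do_not_contribute(self):
        dep = make_deployments(["A"], days=10)
        recs = make_records([
            ("A", "wildlife", "deer", "2017-01-02 10:00"),
            ("A", "human", None, "2017-01-03 10:00"),
            ("A", "blank", None, "2017-01-04 10:00")])
        h = build_detection_history(recs, dep)
        assert h.species == ["deer"]
        assert h.y.sum() == 1

    def test_csv_round_trip(self, tmp_path):
        dep = make_deployments(["A", "B"], days=10)
        recs = make_records([
            ("A", "wildlife", "deer", "2017-01-02 10:00"),
            ("B", "wildlife", "cat", "2017-01-03 10:00")])
        h = build_detection_history(recs, dep)
        h.to_csv(tmp_path / "h.csv", tmp_path / "e.csv")
        h2 = DetectionHistory.from_csv(tmp_path / "h.csv", tmp_path / "e.csv")
        assert np.array_equal(h.y, h2.y)
        assert np.array_equal(h.n, h2.n)
        assert h.species == h2.species


class TestSummaries:
    def _history(self, y, n):
        y = np.atleast_2d(y)
        return DetectionHistory(
            species=[f"s{i}" for i in range(y.shape[0])],
            sites=[f"site{j}" for j in range(y.shape[1])], y=y,
            n=np.asarray(n))

    def test_detection_categories_bins(self):
        # totals: 623 abundant, 50 common, 5 uncommon, 1 rare
        y = np.zeros((4, 45), dtype=int)
        y[0, :20] = 31; y[0, 20] = 623 - 20 * 31
        y[1, :10] = 5
        y[2, :5] = 1
        y[3, 0] = 1
        h = self._history(y, np.full(45, 97))
        out = detection_categories(h, est_richness=9)
        got = dict(zip(out["category"], out["species_count"]))
        assert got == {"Abundant": 1, "Common": 1, "Uncommon": 1,
                       "Rare": 1, "Undetected": 5}

    def test_undetected_is_richness_minus_observed(self):
        h = self._history(np.ones((21, 45), dtype=int), np.full(45, 97))
        out = detection_categories(h, est_richness=26)
        assert out.loc[out["category"] == "Undetected",
                       "species_count"].item() == 5

    def test_naive_estimates_ratios(self):
        y = np.zeros((1, 45), dtype=int)
        y[0, :36] = 2
        h = self._history(y, np.full(45, 10))
        out = naive_estimates(h)
        assert out["naive_psi"].item() == pytest.approx(36 / 45)
        assert out["naive_p"].item() == pytest.approx(72 / 450)

    def test_naive_two_site_example(self):
        h = self._history(np.array([[2, 0]]), np.array([10, 10]))
        out = naive_estimates(h)
        assert out["naive_psi"].item() == pytest.approx(0.5)
        assert out["naive_p"].item() == pytest.approx(0.1)

    def test_naive_psi_matches_brute_force(self, default_survey):
        h, _ = default_survey
        out = naive_estimates(h)
        for k in range(h.n_species):
            frac = sum(1 for i in range(h.n_sites) if h.y[k, i] > 0) / h.n_sites
            assert out["naive_psi"].iloc[k] == pytest.approx(frac)

    def test_image_category_percentages(self):
        out = image_category_percentages(
            {"wildlife": 2541, "human_livestock": 497,
             "unidentified": 80, "blank": 12208})
        pct = dict(zip(out["category"], out["percent"].round(2)))
        assert pct == {"wildlife": 16.58, "human_livestock": 3.24,
                       "unidentified": 0.52, "blank": 79.66}


def test_read_deployments_validates(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("site,x,y,start,end\nA,0,0,2017-01-10,2017-01-01\n")
    with pytest.raises(ValueError, match="end before start"):
        read_deployments(path)
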