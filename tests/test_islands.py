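import numpy as np
import pandas as pd
import pytest

from hrrscan import (call_islands, export_islands_bed, intersect_methods,
                     make_sample_table, merge_across_breeds, select_top_snps,
                     snp_incidence)
from hrrscan.detect import RUN_COLUMNS
from hrrscan.islands import read_bed, ISLAND_COLUMNS
from conftest import evenly_spaced_map


def run_table(rows):
    recs = [(s, b, meth, c, a, e, 10, e - a) for s, b, meth, c, a, e in rows]
    return pd.DataFrame(recs, columns=RUN_COLUMNS)


def ten_ind_samples(breed="X"):
    ids = [f"{breed}_i{k}" for k in range(10)]
    return make_sample_table(ids, [breed] * 10)


class TestIncidence:
    def test_no_runs_all_zero(self):
        m = evenly_spaced_map(30)
        inc = snp_incidence(run_table([]), ten_ind_samples(), m, "CR")
        assert (inc["incidence"] == 0).all()
        assert inc["z"].isna().all()

    def test_single_run_covers_snp_span(self):
        m = evenly_spaced_map(30)
        pos = m["pos_bp"].to_numpy()
        runs = run_table([("X_i0", "X", "CR", "1", pos[5], pos[20])])
        inc = snp_incidence(runs, ten_ind_samples(), m, "CR")
        expected = np.where((np.arange(30) >= 5) & (np.arange(30) <= 20), 0.1, 0.0)
        np.testing.assert_allclose(inc["incidence"], expected)

    def test_matches_interval_stabbing_oracle(self, rng):
        m = evenly_spaced_map(50)
        pos = m["pos_bp"].to_numpy()
        s = ten_ind_samples()
        rows = []
        for _ in range(25):
            i = rng.integers(0, 10)
            a, b = sorted(rng.choice(50, size=2, replace=False))
            rows.append((f"X_i{i}", "X", "CR", "1", int(pos[a]), int(pos[b])))
        runs = run_table(rows)
        inc = snp_incidence(runs, s, m, "CR")
        for j in range(50):
            covered = {sid for sid, _, _, _, a, b in rows if a <= pos[j] <= b}
            assert inc.loc[j, "incidence"] == pytest.approx(len(covered) / 10)


class TestSelection:
    def _inc(self, values, breed="X"):
        m = evenly_spaced_map(len(values))
        inc = values - values.mean()
        sd = values.std()
        from scipy.stats import norm
        return pd.DataFrame({
            "breed": breed, "method": "CR", "snp_id": m["snp_id"],
            "chrom": "1", "pos_bp": m["pos_bp"],
            "incidence": values,
            "z": inc / sd if sd > 0 else np.nan,
            "p": norm.sf(inc / sd) if sd > 0 else np.nan,
        })

    def test_constant_incidence_empty_with_warning(self):
        t = self._inc(np.full(100, 0.3))
        with pytest.warns(UserWarning, match="constant incidence"):
            sel = select_top_snps(t)
        assert sel["X"] == set()

    def test_planted_outliers_selected_exactly(self, rng):
        values = np.clip(rng.normal(0.05, 0.01, size=10_000), 0, 1)
        planted = rng.choice(10_000, size=50, replace=False)
        values[planted] = 0.6
        t = self._inc(values)
        sel = select_top_snps(t, top_frac=0.001)
        # sort oracle: the 50 planted SNPs are exactly the top block
        expected = set(t.loc[sorted(planted), "snp_id"])
        assert sel["X"] == expected

    def test_ties_at_threshold_included(self):
        values = np.full(1000, 0.05)
        values[:7] = 0.5  # 7 tied SNPs, top 0.1% of 1000 is k=1
        t = self._inc(values)
        sel = select_top_snps(t, top_frac=0.001)
        assert len(sel["X"]) == 7


class TestIntersection:
    def test_identity_and_empty(self):
        a = {"X": {"s1", "s2"}}
        assert intersect_methods(a, {"X": {"s1", "s2"}})["X"] == {"s1", "s2"}
        assert intersect_methods(a, {"X": {"s3"}})["X"] == set()
        assert intersect_methods(a, {})["X"] == set()

    def test_random_sets_match_membership_oracle(self, rng):
        universe = [f"s{i}" for i in range(200)]
        a = {"X": set(rng.choice(universe, 60, replace=False))}
        b = {"X": set(rng.choice(universe, 60, replace=False))}
        got = intersect_methods(a, b)["X"]
        assert got == {s for s in universe if s in a["X"] and s in b["X"]}


def _incidence_frame(m, values, breed="X"):
    from scipy.stats import norm
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else np.full(len(values), np.nan)
    return pd.DataFrame({
        "breed": breed, "method": "CR", "snp_id": m["snp_id"],
        "chrom": m["chrom"], "pos_bp": m["pos_bp"],
        "incidence": values, "z": z, "p": norm.sf(z),
    })


class TestCallIslands:
    def test_three_snp_stretch_rejected(self):
        m = evenly_spaced_map(20)
        values = np.full(20, 0.02)
        values[5:8] = 0.5
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][5:8])}
        islands, _ = call_islands(sel, inc, m)
        assert islands.empty

    def test_low_frequency_stretch_rejected(self):
        m = evenly_spaced_map(20)
        values = np.full(20, 0.02)
        values[5:11] = 0.15
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][5:11])}
        islands, _ = call_islands(sel, inc, m)
        assert islands.empty

    def test_qualifying_stretch_called_with_bounds(self):
        m = evenly_spaced_map(40)
        values = np.full(40, 0.02)
        values[10:16] = 0.5
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][10:16])}
        islands, _ = call_islands(sel, inc, m)
        assert len(islands) == 1
        row = islands.iloc[0]
        assert row["start_bp"] == m["pos_bp"][10]
        assert row["end_bp"] == m["pos_bp"][15]
        assert row["n_snp"] == 6
        assert row["freq"] == pytest.approx(0.5)

    def test_nearby_fragments_merge(self):
        # two qualifying stretches separated by one unselected SNP (<1 Mb)
        m = evenly_spaced_map(40)
        values = np.full(40, 0.02)
        values[10:15] = 0.5
        values[16:21] = 0.4
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][10:15]) | set(m["snp_id"][16:21])}
        islands, _ = call_islands(sel, inc, m)
        assert len(islands) == 1
        assert islands.iloc[0]["n_snp"] == 10
        assert islands.iloc[0]["freq"] == pytest.approx(0.45)

    def test_monotone_in_thresholds(self):
        m = evenly_spaced_map(60)
        values = np.full(60, 0.02)
        values[5:9] = 0.25
        values[20:30] = 0.5
        values[40:43] = 0.6
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][5:9]) | set(m["snp_id"][20:30])
               | set(m["snp_id"][40:43])}
        base, _ = call_islands(sel, inc, m, min_snp=4, min_freq=0.20)
        lo_snp, _ = call_islands(sel, inc, m, min_snp=3, min_freq=0.20)
        lo_freq, _ = call_islands(sel, inc, m, min_snp=4, min_freq=0.10)
        assert len(lo_snp) >= len(base)
        assert len(lo_freq) >= len(base)

    def test_diagnostic_counts_runs_hit(self):
        m = evenly_spaced_map(40)
        pos = m["pos_bp"].to_numpy()
        values = np.full(40, 0.0)
        values[10:16] = 0.5
        inc = _incidence_frame(m, values)
        sel = {"X": set(m["snp_id"][10:16])}
        runs = run_table([
            ("X_i0", "X", "CR", "1", int(pos[9]), int(pos[17])),   # hits
            ("X_i1", "X", "CR", "1", int(pos[30]), int(pos[35])),  # misses
        ])
        _, diag = call_islands(sel, inc, m, runs=runs)
        assert diag["X"] == 1


class TestSharedIslands:
    def _islands(self, rows):
        recs = [{"breed": b, "chrom": c, "start_bp": s, "end_bp": e,
                 "n_snp": 5, "freq": 0.4, "snp_ids": []}
                for b, c, s, e in rows]
        return pd.DataFrame(recs, columns=ISLAND_COLUMNS)

    def test_disjoint_islands_stay_separate(self):
        t = self._islands([("A", "1", 100, 200), ("B", "1", 500, 600)])
        shared, tallies = merge_across_breeds(t)
        assert len(shared) == 2
        assert all(shared["n_breeds"] == 1)
        assert tallies.iloc[0]["total_islands"] == 2
        assert tallies.iloc[0]["unique_islands"] == 2

    def test_transitive_overlap_union(self):
        t = self._islands([("A", "1", 100, 300), ("B", "1", 250, 500),
                           ("C", "1", 450, 700)])
        shared, _ = merge_across_breeds(t)
        assert len(shared) == 1
        row = shared.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (100, 700)
        assert row["breeds"] == ["A", "B", "C"]

    def test_codes_by_breed_count_then_position(self):
        t = self._islands([
            ("A", "5", 1000, 2000), ("B", "5", 1500, 2500),  # 2 breeds
            ("C", "5", 9000, 9500),                           # 1 breed
        ])
        shared, _ = merge_across_breeds(t)
        by_code = shared.set_index("code")
        assert by_code.loc["CHI5-A", "n_breeds"] == 2
        assert by_code.loc["CHI5-B", "n_breeds"] == 1

    def test_matches_interval_union_oracle(self, rng):
        rows = []
        for k in range(30):
            s = int(rng.integers(0, 5_000_000))
            rows.append((f"B{k % 6}", "1", s, s + int(rng.integers(50_000, 800_000))))
        shared, _ = merge_across_breeds(self._islands(rows))
        # oracle: pointwise union of covered bp via sorted sweep
        ivs = sorted((s, e) for _, _, s, e in rows)
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        got = sorted(zip(shared["start_bp"], shared["end_bp"]))
        assert got == [tuple(x) for x in merged]


class TestBedExport:
    def test_coordinate_convention(self, tmp_path):
        t = pd.DataFrame([{"breed": "A", "chrom": "1", "start_bp": 100,
                           "end_bp": 200, "n_snp": 5, "freq": 0.4,
                           "snp_ids": []}], columns=ISLAND_COLUMNS)
        export_islands_bed(t, tmp_path / "x.bed")
        line = (tmp_path / "x.bed").read_text().splitlines()[1].split("\t")
        assert (line[1], line[2]) == ("99", "200")
        assert line[4] == "400"

    def test_empty_table_header_only(self, tmp_path):
        t = pd.DataFrame(columns=ISLAND_COLUMNS)
        export_islands_bed(t, tmp_path / "x.bed")
        lines = (tmp_path / "x.bed").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_round_trip(self, tmp_path, rng):
        rows = []
        for k in range(8):
            s = int(rng.integers(1, 1_000_000))
            rows.append({"breed": f"B{k}", "chrom": "3", "start_bp": s,
                         "end_bp": s + 10_000, "n_snp": 5, "freq": 0.3,
                         "snp_ids": []})
        t = pd.DataFrame(rows, columns=ISLAND_COLUMNS)
        export_islands_bed(t, tmp_path / "x.bed")
        back = read_bed(tmp_path / "x.bed")
        np.testing.assert_array_equal(back["start_bp"], t["start_bp"])
        np.testing.assert_array_equal(back["end_bp"], t["end_bp"])
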