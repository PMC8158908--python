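"""The 60-configuration experiment: enumeration, determinism, comparisons."""

import numpy as np
import pandas as pd
import pytest

from hrasim.loads import LOAD_CASES
from hrasim.sweep import (
    DEFAULT_CUP_POSES,
    DEFAULT_VERSIONS,
    derive_comparisons,
    enumerate_configs,
    export,
    run_sweep,
)


class TestEnumeration:
    def test_default_grid_has_60_configs(self):
        assert len(enumerate_configs()) == 60

    def test_single_config(self):
        assert len(enumerate_configs([0.0], [(40.0, 15.0)], ["flex0"])) == 1

    def test_product_count(self):
        configs = enumerate_configs(
            [0.0, -15.0], [(40.0, 15.0), (40.0, 25.0), (50.0, 15.0)], ["flex0", "flex90"]
        )
        assert len(configs) == 12

    def test_deterministic_ordering(self):
        configs = enumerate_configs()
        assert configs[0] == (30.0, (40.0, 15.0), "flex0")
        assert configs[-1] == (-30.0, (50.0, 25.0), "flex90")
        # version outer, cup middle, load inner
        assert [c[2] for c in configs[:3]] == ["flex0", "flex45", "flex90"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configs([], DEFAULT_CUP_POSES, ["flex0"])


class TestRunSweep:
    def test_full_run_has_60_rows_no_failures(self, sweep_table):
        assert len(sweep_table) == 60
        assert (sweep_table.status == "ok").all()
        assert sweep_table.peak_pressure.notna().all()

    def test_subset_equals_standalone_solve(self, engine):
        table = run_sweep(
            configs=[(-30.0, (50.0, 15.0), "flex90")], engine=engine
        )
        assert len(table) == 1
        sol = engine.solve_one_contact(-30.0, (50.0, 15.0), LOAD_CASES["flex90"])
        assert table.peak_pressure.iloc[0] == pytest.approx(
            sol.peak_pressure, abs=0.0
        )

    def test_rerun_bit_identical(self, engine, tmp_path):
        configs = enumerate_configs([0.0, -30.0], [(50.0, 15.0)], ["flex90"])
        paths = []
        for i in range(2):
            table = run_sweep(configs=configs, engine=engine)
            p = tmp_path / f"run{i}.csv"
            table.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestComparisons:
    def test_equal_peaks_give_zero_change(self):
        rows = []
        for v in (30.0, 0.0, -30.0):
            rows.append(
                dict(
                    femoral_version=v,
                    cup_inclination=40.0,
                    cup_version=15.0,
                    load_case="flex90",
                    peak_pressure=5.0,
                    contact_area=500.0,
                )
            )
        out = derive_comparisons(pd.DataFrame(rows))["pressure_vs_neutral"]
        assert np.allclose(out.pct_change_vs_neutral, 0.0)

    def test_hand_built_18_percent(self):
        rows = [
            dict(
                femoral_version=0.0,
                cup_inclination=50.0,
                cup_version=15.0,
                load_case="flex90",
                peak_pressure=5.0,
                contact_area=500.0,
            ),
            dict(
                femoral_version=-30.0,
                cup_inclination=50.0,
                cup_version=15.0,
                load_case="flex90",
                peak_pressure=5.9,
                contact_area=450.0,
            ),
        ]
        out = derive_comparisons(pd.DataFrame(rows))["pressure_vs_neutral"]
        got = out[out.femoral_version == -30.0].pct_change_vs_neutral.iloc[0]
        assert got == pytest.approx(18.0)

    def test_missing_comparator_rejected(self):
        rows = [
            dict(
                femoral_version=-30.0,
                cup_inclination=40.0,
                cup_version=15.0,
                load_case="flex90",
                peak_pressure=5.9,
                contact_area=450.0,
            )
        ]
        with pytest.raises(ValueError):
            derive_comparisons(pd.DataFrame(rows))

    def test_retroverted_has_largest_increase_at_sitting_load(self, sweep_table):
        comp = derive_comparisons(sweep_table)["pressure_vs_neutral"]
        sub = comp[
            (comp.load_case == "flex90")
            & (comp.cup_inclination == 50.0)
            & (comp.cup_version == 15.0)
        ]
        best = sub.loc[sub.pct_change_vs_neutral.idxmax()]
        assert best.femoral_version == -30.0
        assert best.pct_change_vs_neutral > 0


class TestTrends:
    def test_sitting_pressure_non_decreasing_with_retroversion(self, sweep_table):
        sub = sweep_table[sweep_table.load_case == "flex90"]
        for _, grp in sub.groupby(["cup_inclination", "cup_version"]):
            g = grp.sort_values("femoral_version", ascending=False)
            assert np.all(np.diff(g.peak_pressure.to_numpy()) >= -1e-9)

    def test_inverse_pressure_area_relation_at_sitting_load(self, sweep_table):
        sub = sweep_table[sweep_table.load_case == "flex90"]
        for _, grp in sub.groupby(["cup_inclination", "cup_version"]):
            assert grp.contact_area.idxmin() == grp.peak_pressure.idxmax()

    def test_version_insensitivity_at_low_flexion_loads(self, sweep_table):
        for load in ("flex0", "flex45"):
            sub = sweep_table[sweep_table.load_case == load]
            for _, grp in sub.groupby(["cup_inclination", "cup_version"]):
                spread = (
                    grp.peak_pressure.max() - grp.peak_pressure.min()
                ) / grp.peak_pressure.min()
                assert spread < 0.05

    def test_contact_area_not_increased_by_steeper_cup(self, sweep_table):
        comp = derive_comparisons(sweep_table)["area_inclination_40_to_50"]
        sub = comp[comp.load_case != "flex90"]
        # non-increase within discretization tolerance (0.5%)
        assert (sub.pct_area_reduction_40_to_50 >= -0.5).all()


class TestExport:
    def test_empty_table_writes_headers_only(self, tmp_path):
        with pytest.warns(UserWarning):
            written = export(pd.DataFrame(), tmp_path / "empty")
        assert len(written) == 1
        assert written[0].read_text().strip() == ""

    def test_full_export_and_roundtrip(self, sweep_table, tmp_path):
        written = export(sweep_table, tmp_path / "out")
        names = {p.name for p in written}
        assert "results.csv" in names and "per_config.json" in names
        assert sum(p.suffix == ".png" for p in written) == 3
        back = pd.read_csv(tmp_path / "out" / "results.csv")
        assert len(back) == 60
        pd.testing.assert_frame_equal(
            back[["femoral_version", "peak_pressure"]],
            sweep_table[["femoral_version", "peak_pressure"]].reset_index(drop=True),
        )
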