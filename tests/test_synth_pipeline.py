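"""Generators, plate layout, end-to-end pipeline, and CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from qpiscreen import (
    PlateLayout,
    SyntheticPopulationSpec,
    TrackFilterParams,
    compute_sgr,
    dataframe_to_tracks,
    dilution_series,
    generate_cell_tracks,
    generate_dose_response_tracks,
    run_pipeline,
)
from qpiscreen.cli import main as cli_main
from qpiscreen.pipeline import dose_response_table, sgr_table, tor_table


@pytest.fixture(scope="module")
def small_layout():
    return PlateLayout.default_screen(
        drugs=("drugA",), concentrations_uM=(0.032, 0.16, 0.8, 4.0, 20.0),
        n_replicates=2,
    )


@pytest.fixture(scope="module")
def dr_tracks(small_layout):
    return generate_dose_response_tracks(
        e0=0.025, emax=-0.012, ec50_uM=0.8, hs=1.2, layout=small_layout,
        n_cells_per_location=6, noise_cv=0.003, seed=11,
    )


class TestLayout:
    def test_default_screen_enumerations(self):
        layout = PlateLayout.default_screen()
        assert len(layout.wells) == 96
        assert layout.n_locations() == 864
        assert len(layout.locations_for_condition("drugA", 20.0)) == 27

    def test_yaml_round_trip(self, tmp_path):
        layout = PlateLayout.default_screen()
        p = tmp_path / "plate.yaml"
        layout.to_yaml(p)
        back = PlateLayout.from_yaml(p)
        assert back.wells.keys() == layout.wells.keys()
        w = sorted(layout.wells)[0]
        assert back.wells[w].drug == layout.wells[w].drug
        assert back.wells[w].concentration_uM == layout.wells[w].concentration_uM

    def test_dilution_series_halving_cascade(self):
        series = dilution_series(40.0, 6)
        assert series[0] == 20.0
        assert np.allclose(np.array(series[:-1]) / np.array(series[1:]), 2.0)


class TestGenerator:
    def test_deterministic_per_seed(self):
        spec = SyntheticPopulationSpec(n_cells=10, seed=7)
        assert generate_cell_tracks(spec).equals(generate_cell_tracks(spec))

    def test_no_variation_recovers_mean_exactly(self):
        spec = SyntheticPopulationSpec(n_cells=5, sgr_sd_h=0.0, noise_cv=0.0, seed=0)
        recs = [compute_sgr(t) for t in dataframe_to_tracks(generate_cell_tracks(spec))]
        for r in recs:
            assert r.sgr_h == pytest.approx(0.02, rel=1e-9)

    def test_all_dying_tracks_decay(self):
        spec = SyntheticPopulationSpec(
            n_cells=5, death_fraction=1.0, death_time_range_h=(0.0, 0.0),
            death_rate_h=-0.05, duration_h=4.0, noise_cv=0.0, seed=0,
        )
        params = TrackFilterParams(min_frames=5, min_mean_mass_pg=1.0)
        recs = [compute_sgr(t, params) for t in dataframe_to_tracks(generate_cell_tracks(spec))]
        for r in recs:
            assert r.sgr_h == pytest.approx(-0.05, rel=1e-6)

    def test_population_mean_recovery(self):
        spec = SyntheticPopulationSpec(n_cells=500, sgr_mean_h=0.02, sgr_sd_h=0.008, seed=1)
        recs = [compute_sgr(t) for t in dataframe_to_tracks(generate_cell_tracks(spec))]
        sgr = np.array([r.sgr_h for r in recs if r.accepted])
        sem = sgr.std(ddof=1) / np.sqrt(len(sgr))
        assert abs(sgr.mean() - 0.02) < 2 * sem

    def test_sd_recovery_within_15_percent(self):
        spec = SyntheticPopulationSpec(n_cells=500, sgr_mean_h=0.02, sgr_sd_h=0.008,
                                       noise_cv=0.003, seed=2)
        recs = [compute_sgr(t) for t in dataframe_to_tracks(generate_cell_tracks(spec))]
        sgr = np.array([r.sgr_h for r in recs if r.accepted])
        assert abs(sgr.std(ddof=1) - 0.008) / 0.008 < 0.15


class TestDoseResponseRoundTrip:
    def test_zero_noise_ec50_recovery(self, small_layout):
        tracks = generate_dose_response_tracks(
            e0=0.025, emax=-0.012, ec50_uM=0.8, hs=1.2, layout=small_layout,
            n_cells_per_location=4, sgr_sd_h=0.0, noise_cv=0.0, seed=5,
        )
        sgr_df, _ = sgr_table(tracks)
        dr = dose_response_table(sgr_df, small_layout)
        row = dr[dr["drug"] == "drugA"].iloc[0]
        assert row["responded"]
        assert row["ec50_uM"] == pytest.approx(0.8, rel=1e-3)
        assert row["e0"] == pytest.approx(0.025, rel=1e-3)
        assert row["emax"] == pytest.approx(-0.012, rel=1e-3)
        assert row["cytotoxic"]  # emax < 0 -> DoR > 1

    def test_flat_truth_no_response(self, small_layout):
        tracks = generate_dose_response_tracks(
            e0=0.02, emax=0.02, ec50_uM=1.0, hs=1.0, layout=small_layout,
            n_cells_per_location=4, sgr_sd_h=0.004, noise_cv=0.003, seed=6,
        )
        sgr_df, _ = sgr_table(tracks)
        dr = dose_response_table(sgr_df, small_layout)
        assert not dr.iloc[0]["responded"]


class TestPipeline:
    def test_tracks_entry_full_bundle(self, dr_tracks, small_layout, tmp_path):
        result = run_pipeline(dr_tracks, small_layout, out_dir=tmp_path,
                              compute_tor_stage=False)
        assert set(result.sgr.columns) >= {"track_id", "well", "sgr_h", "accepted", "reason"}
        assert len(result.dose_response) == 1
        assert (tmp_path / "sgr.csv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_filter_count_bookkeeping(self, dr_tracks):
        sgr_df, counts = sgr_table(dr_tracks)
        rejected = sum(v for k, v in counts.items() if k not in ("input", "accepted"))
        assert counts["accepted"] + rejected == counts["input"]

    def test_rerun_reproduces_outputs(self, dr_tracks, small_layout, tmp_path):
        a = run_pipeline(dr_tracks, small_layout, out_dir=tmp_path / "a",
                         compute_tor_stage=False)
        b = run_pipeline(dr_tracks, small_layout, out_dir=tmp_path / "b",
                         compute_tor_stage=False)
        assert (tmp_path / "a" / "sgr.csv").read_bytes() == (tmp_path / "b" / "sgr.csv").read_bytes()
        assert a.dose_response.equals(b.dose_response)

    def test_tor_stage_on_responding_drug(self, small_layout):
        # treated populations drift down over time -> Hellinger rises -> ToR
        rng = np.random.default_rng(0)
        frames = []
        dt = 1.0
        times = np.arange(0.0, 48.0 + 1e-9, dt)
        for well, cond in small_layout.wells.items():
            drift = 0.0
            if cond.concentration_uM >= 0.8:
                drift = -0.04
            for i in range(2):  # 2 locations per well to keep runtime low
                n = 10
                sgr0 = rng.normal(0.02, 0.005, n)
                m0 = rng.uniform(200, 400, n)
                for cell in range(n):
                    g = sgr0[cell] + drift * (1 - np.exp(-times / 10.0))
                    mass = m0[cell] * np.exp(np.cumsum(g) * dt / 24)
                    frames.append(pd.DataFrame({
                        "track_id": cell, "well": well, "location": f"{well}_{i}",
                        "frame": np.arange(len(times)), "time_h": times,
                        "x": 0.0, "y": 0.0, "area_um2": mass / 2, "mass_pg": mass,
                    }))
        tracks = pd.concat(frames, ignore_index=True)
        params = TrackFilterParams(min_frames=10, min_mean_mass_pg=50.0)
        tor = tor_table(tracks, small_layout, duration_h=48.0, frame_interval_min=60.0,
                        params=params, bin_size=4)
        high = tor[tor["concentration_uM"] >= 0.8]
        assert (high["status"] == "ok").any()
        assert (high.loc[high["status"] == "ok", "tor_h"] > 0).all()


class TestCLI:
    def test_simulate_sgr_dose_response_chain(self, tmp_path, small_layout):
        runner = CliRunner()
        tracks_csv = tmp_path / "tracks.csv"
        layout_yaml = tmp_path / "plate.yaml"
        small_layout.to_yaml(layout_yaml)
        tracks = generate_dose_response_tracks(
            e0=0.025, emax=-0.01, ec50_uM=1.0, hs=1.0, layout=small_layout,
            n_cells_per_location=4, noise_cv=0.003, seed=3,
        )
        tracks.to_csv(tracks_csv, index=False)

        sgr_csv = tmp_path / "sgr.csv"
        res = runner.invoke(cli_main, ["sgr", "--tracks", str(tracks_csv),
                                       "--out", str(sgr_csv)])
        assert res.exit_code == 0, res.output
        assert sgr_csv.exists()

        dr_csv = tmp_path / "dr.csv"
        res = runner.invoke(cli_main, ["dose-response", "--sgr", str(sgr_csv),
                                       "--layout", str(layout_yaml), "--out", str(dr_csv)])
        assert res.exit_code == 0, res.output
        dr = pd.read_csv(dr_csv)
        assert bool(dr.iloc[0]["responded"])

    def test_mixing_command(self, tmp_path):
        runner = CliRunner()
        rng = np.random.default_rng(1)
        sgr_csv = tmp_path / "sgr.csv"
        pd.DataFrame({
            "track_id": np.arange(400),
            "well": ["A1"] * 200 + ["B1"] * 200,
            "location": "L",
            "sgr_h": np.concatenate([rng.normal(0.025, 0.006, 200),
                                     rng.normal(-0.01, 0.005, 200)]),
            "accepted": True,
        }).to_csv(sgr_csv, index=False)
        out_csv = tmp_path / "mix.csv"
        res = runner.invoke(cli_main, [
            "mixing", "--sgr", str(sgr_csv), "--control-well", "A1",
            "--treated-well", "B1", "--out", str(out_csv), "--repeats", "10",
        ])
        assert res.exit_code == 0, res.output
        mix = pd.read_csv(out_csv)
        assert {"ratio", "repeat", "normalized_auprc"} <= set(mix.columns)

    def test_reconstruct_command_round_trip(self, tmp_path):
        import tifffile

        from qpiscreen import (
            OpticalConfig,
            PhaseImage,
            read_phase_tiff,
            simulate_dpc_frames,
        )

        config = OpticalConfig()
        yy, xx = np.indices((64, 64))
        phi = 0.3 * np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 5**2))
        phi -= phi.mean()
        frames = simulate_dpc_frames(PhaseImage(phi, config.pixel_size_um), config)
        in_dir = tmp_path / "frames"
        in_dir.mkdir()
        for half in ("top", "bottom", "left", "right"):
            tifffile.imwrite(in_dir / f"loc0_000_{half}.tif",
                             getattr(frames, half).astype(np.float32))
        out_dir = tmp_path / "phases"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["reconstruct", "--in", str(in_dir),
                                       "--out", str(out_dir)])
        assert res.exit_code == 0, res.output
        rec = read_phase_tiff(out_dir / "loc0_000_phase.tif")
        corr = np.corrcoef(rec.phase.ravel(), phi.ravel())[0, 1]
        assert corr > 0.95

    def test_track_command_on_synthetic_phases(self, tmp_path):
        import tifffile

        shape = (96, 96)
        yy, xx = np.indices(shape)
        in_dir = tmp_path / "phases"
        in_dir.mkdir()
        for i in range(4):
            # one blob drifting slowly to the right, growing in phase
            blob = (0.4 + 0.02 * i) * np.exp(
                -((xx - (40 + 2 * i)) ** 2 + (yy - 48) ** 2) / (2 * 6**2)
            )
            tifffile.imwrite(in_dir / f"A1_0_{i:03d}_phase.tif", blob.astype(np.float32))
        out_csv = tmp_path / "tracks.csv"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["track", "--in", str(in_dir),
                                       "--out", str(out_csv)])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(out_csv)
        assert df["track_id"].nunique() == 1
        assert len(df) == 4
        assert (df.sort_values("time_h")["mass_pg"].diff().dropna() > 0).all()

    def test_simulate_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "t.csv"
        res = runner.invoke(cli_main, ["simulate", "--out", str(out), "--n-cells", "5"])
        assert res.exit_code == 0, res.output
        assert len(pd.read_csv(out)) == 5 * 217
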