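"""Protocol orchestration: reproducibility, provenance, variant alignment."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coevonet import RunConfig, Trajectory, run_ensemble, run_simulation

TINY = dict(
    n_agents=30,
    mean_degree=4,
    equilibration_steps=6,
    forcing_steps=12,
    cp_max_distance=3,
)


def test_trajectory_covers_equilibration_plus_forcing():
    cfg = RunConfig(**TINY)
    traj = run_simulation(cfg, 1)
    assert len(traj.metrics) == 18
    assert (traj.metrics["phase"] == "equilibration").sum() == 6
    assert (traj.metrics["phase"] == "forcing").sum() == 12


def test_same_seed_reproduces_bitwise():
    cfg = RunConfig(**TINY)
    a = run_simulation(cfg, 5).metrics
    b = run_simulation(cfg, 5).metrics
    pd.testing.assert_frame_equal(a, b)


def test_variants_share_equilibration_dynamics():
    """Cross-variant runs with one seed consume identical substrate,
    dispositions and RNG substreams, so the equilibration phase (coupled
    dynamics for every variant) must match exactly."""
    base = RunConfig(**TINY)
    frames = {}
    for variant in ("coupled", "network", "mean_field"):
        cfg = dataclasses.replace(base, variant=variant)
        m = run_simulation(cfg, 3).metrics
        frames[variant] = m[m["phase"] == "equilibration"].reset_index(drop=True)
    pd.testing.assert_frame_equal(frames["coupled"], frames["network"])
    pd.testing.assert_frame_equal(frames["coupled"], frames["mean_field"])


def test_frozen_dispositions_and_zero_noise_freeze_prevalence():
    cfg = RunConfig(
        **{**TINY, "forcing_steps": 0, "equilibration_steps": 10},
        switch_scale=0.0,
        variant="network",
    )
    m = run_simulation(cfg, 2).metrics
    assert m["prevalence"].nunique() == 1


def test_degree_bound_respected_in_snapshots():
    cfg = RunConfig(**TINY, snapshot_every=4)
    traj = run_simulation(cfg, 7)
    assert traj.snapshots
    from coevonet.rng import Stream, stream_rng
    from coevonet import sample_degree_preferences

    q = sample_degree_preferences(30, 10, 3, stream_rng(7, Stream.DEGREE_PREFERENCE))
    for adj in traj.snapshots.values():
        assert np.all(adj.sum(1) <= q)


def test_ensemble_mean_is_average_of_trajectories():
    cfg = RunConfig(**TINY, metrics=("prevalence",))
    summary = run_ensemble(cfg, n_runs=2, base_seed=0, keep_runs=True)
    manual = np.mean([r.metrics["prevalence"].to_numpy() for r in summary.runs], axis=0)
    assert np.allclose(summary.series["prevalence"].to_numpy(), manual)
    assert summary.seeds == [0, 1]


def test_ensemble_bands_contain_each_other():
    cfg = RunConfig(**TINY, metrics=("prevalence",))
    summary = run_ensemble(cfg, n_runs=4, base_seed=0)
    wide = summary.bands.pivot_table(index=["step", "metric"], columns="level", values=["lo", "hi"])
    assert np.all(wide[("lo", 0.99)] <= wide[("lo", 0.95)] + 1e-12)
    assert np.all(wide[("hi", 0.99)] >= wide[("hi", 0.95)] - 1e-12)


def test_trajectory_round_trips_through_disk(tmp_path):
    cfg = RunConfig(**TINY, snapshot_every=6)
    traj = run_simulation(cfg, 4)
    traj.save(tmp_path)
    back = Trajectory.load(tmp_path)
    pd.testing.assert_frame_equal(back.metrics, traj.metrics, check_dtype=False)
    assert back.provenance == traj.provenance
    assert set(back.snapshots) == set(traj.snapshots)
    for step in traj.snapshots:
        assert np.array_equal(back.snapshots[step], traj.snapshots[step])


def test_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(**TINY, variant="mean_field")
    cfg.to_yaml(tmp_path / "c.yaml")
    back = RunConfig.from_yaml(tmp_path / "c.yaml")
    assert back == cfg
    assert back.digest() == cfg.digest()


def test_cli_run_and_ensemble(tmp_path):
    from click.testing import CliRunner

    from coevonet.cli import main

    cfg = RunConfig(**TINY, metrics=("prevalence",))
    cfg.to_yaml(tmp_path / "cfg.yaml")
    runner = CliRunner()
    out = runner.invoke(
        main, ["run", "--config", str(tmp_path / "cfg.yaml"), "--seed", "1",
               "--out", str(tmp_path / "run")],
    )
    assert out.exit_code == 0, out.output
    assert (tmp_path / "run" / "metrics.csv").exists()
    out = runner.invoke(
        main, ["ensemble", "--config", str(tmp_path / "cfg.yaml"), "--runs", "2",
               "--out", str(tmp_path / "ens")],
    )
    assert out.exit_code == 0, out.output
    assert (tmp_path / "ens" / "ensemble_series.csv").exists()


def test_panel_figure_renders_from_ensemble_series(tmp_path):
    from coevonet.plotting import panel_figure

    cfg = RunConfig(**TINY)
    summary = run_ensemble(cfg, n_runs=2, base_seed=0)
    fig = panel_figure({"coupled": summary.series}, onset_step=6,
                       path=tmp_path / "panels.png")
    assert (tmp_path / "panels.png").exists()
    assert fig.axes
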