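import numpy as np
import pytest

from mptkit import SimulationConfig, Trajectory, TrajectorySet, simulate_brownian


@pytest.fixture(scope="session")
def brownian_set():
    """A small seeded Brownian population reused across tests."""
    cfg = SimulationConfig(
        n_trajectories=20, n_frames=100, seed=42,
        regime="brownian", regime_params={"D": 0.5},
    )
    ts, labels = simulate_brownian(cfg)
    return ts, labels


@pytest.fixture()
def random_trajectory_factory():
    """Build random-walk trajectories with arbitrary lengths for oracle tests."""

    def make(n_points: int, seed: int, dt: float = 0.05) -> Trajectory:
        rng = np.random.default_rng(seed)
        frames = np.arange(n_points)
        xy = np.cumsum(rng.normal(0, 0.3, size=(n_points, 2)), axis=0)
        return Trajectory(f"rw_{seed}", frames, frames * dt, xy[:, 0], xy[:, 1])

    return make


@pytest.fixture()
def tracking_xml_factory(tmp_path):
    """Write a minimal TrackMate-style tracks XML with given track lengths."""

    def make(track_lengths, name="tracks.xml", dialect="particle"):
        lines = ['<?xml version="1.0" encoding="UTF-8"?>']
        if dialect == "particle":
            lines.append(f'<Tracks nTracks="{len(track_lengths)}">')
            for ti, length in enumerate(track_lengths):
                lines.append(f'  <particle nSpots="{length}">')
                for f in range(length):
                    lines.append(
                        f'    <detection t="{f}" x="{ti + 0.25 * f}" y="{2.0 * ti - 0.5 * f}" z="0"/>'
                    )
                lines.append("  </particle>")
            lines.append("</Tracks>")
        else:
            lines.append("<Model><AllTracks>")
            for ti, length in enumerate(track_lengths):
                lines.append(f'  <Track TRACK_ID="{ti}">')
                for f in range(length):
                    lines.append(
                        f'    <Spot FRAME="{f}" POSITION_X="{ti + 0.25 * f}" POSITION_Y="{2.0 * ti - 0.5 * f}"/>'
                    )
                lines.append("  </Track>")
            lines.append("</AllTracks></Model>")
        path = tmp_path / name
        path.write_text("\n".join(lines))
        return path

    return make


@pytest.fixture()
def assay_schedule():
    """A 6-timepoint NC schedule plus the TX-100 acute lysis control."""
    tps = ["acute", "1DIV", "4DIV", "7DIV", "11DIV", "14DIV"]
    schedule = [
        {"group": "NC", "timepoint": tp, "n_slices": 6, "mean": 0.5 + 0.05 * i,
         "noise_sd": 0.02}
        for i, tp in enumerate(tps)
    ]
    schedule.append(
        {"group": "TX100_acute", "timepoint": "acute", "n_slices": 3,
         "mean": 2.0, "noise_sd": 0.02}
    )
    return schedule
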