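"""Synthetic data with known ground truth.

Three generator families emulate the study's raw inputs so the whole analysis
pipeline can be exercised end to end:

* 2-D particle trajectories sampled on a video frame grid (33.3 frames per
  second, 651 frames by default) under Brownian, fractional-Brownian,
  immobile, directed, or mixture dynamics, with i.i.d. Gaussian localization
  noise added per frame;
* two-channel fluorescence nuclei images (a nuclear stain channel plus a
  marker channel covering a known fraction of the nuclei);
* longitudinal plate-reader assay tables with triplicate wells and a
  full-lysis (TX-100) control group.

Every generator is deterministic given its seed and returns the exact ground
truth alongside the data, so parameter-recovery tests never depend on
external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectories import Trajectory, TrajectorySet

REGIMES = ("brownian", "fbm", "immobile", "directed", "mixture")

#: Acquisition defaults: 33.3 frames per second for 651 frames.
DEFAULT_FRAME_INTERVAL = 1.0 / 33.3
DEFAULT_N_FRAMES = 651

#: Localization precision default (μm); a config parameter, not a measured value.
DEFAULT_NOISE_SD = 0.02

#: Pixel size default (μm/pixel) for optional pixel-unit output.
DEFAULT_PIXEL_SIZE = 0.1


@dataclass
class SimulationConfig:
    """Parameters of a trajectory simulation.

    ``regime_params`` holds the regime-specific physics:

    * ``brownian``: ``D`` (μm²/s)
    * ``fbm``: ``D`` (generalized coefficient, μm²/s^2H) and ``hurst`` in (0, 1)
    * ``immobile``: nothing (only localization noise moves the readout)
    * ``directed``: ``velocity`` (μm/s) and optionally ``D`` (μm²/s, default 0)
    * ``mixture``: ``components``, a list of dicts each carrying ``regime``,
      ``fraction`` (nonnegative, summing to 1) and that regime's parameters.
    """

    n_trajectories: int = 100
    n_frames: int = DEFAULT_N_FRAMES
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = DEFAULT_PIXEL_SIZE
    localization_noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    regime: str = "brownian"
    regime_params: dict = field(default_factory=lambda: {"D": 0.5})

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.regime == "mixture":
            comps = self.regime_params.get("components", [])
            if not comps:
                raise ValueError("mixture regime requires 'components'")
            fracs = np.array([c.get("fraction", -1.0) for c in comps], dtype=float)
            if np.any(fracs < 0):
                raise ValueError("mixture fractions must be nonnegative")
            if abs(fracs.sum() - 1.0) > 1e-9:
                raise ValueError("mixture fractions must sum to 1 within 1e-9")


def _labels_frame(ids: Sequence[str], regime: str, true_D, true_alpha) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trajectory_id": list(ids),
            "regime": regime,
            "true_D": true_D,
            "true_alpha": true_alpha,
        }
    )


def _make_set(cfg: SimulationConfig, positions: np.ndarray, regime: str) -> TrajectorySet:
    """Wrap an (n_traj, n_frames, 2) position array into a TrajectorySet."""
    frames = np.arange(cfg.n_frames, dtype=np.int64)
    t = frames * cfg.frame_interval
    trajs = [
        Trajectory(f"{regime}_{i:04d}", frames, t, positions[i, :, 0], positions[i, :, 1])
        for i in range(positions.shape[0])
    ]
    return TrajectorySet(trajs, cfg.frame_interval, source=f"simulated:{regime}")


def _add_noise(rng: np.random.Generator, positions: np.ndarray, sd: float) -> np.ndarray:
    if sd > 0:
        positions = positions + rng.normal(0.0, sd, size=positions.shape)
    return positions


def simulate_brownian(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Free 2-D diffusion: increments per axis are N(0, 2·D·Δt).

    ``D = 0`` is allowed as the degenerate stationary case; negative D errors.
    """
    D = float(cfg.regime_params.get("D", 0.5))
    if D < 0:
        raise ValueError("Brownian D must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_trajectories, cfg.n_frames
    steps = rng.normal(0.0, math.sqrt(2.0 * D * cfg.frame_interval), size=(n, m - 1, 2))
    positions = np.concatenate(
        [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    positions = _add_noise(rng, positions, cfg.localization_noise_sd)
    ts = _make_set(cfg, positions, "brownian")
    labels = _labels_frame(ts.ids(), "brownian", D, 1.0)
    return ts, labels


def _fgn_cholesky(n_steps: int, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit-scale fractional-Gaussian-noise covariance.

    gamma(k) = 0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H) for unit-variance steps.
    """
    k = np.arange(n_steps, dtype=np.float64)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    cov = gamma[np.abs(np.subtract.outer(k, k)).astype(np.int64)]
    return np.linalg.cholesky(cov)


def simulate_fbm(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Fractional Brownian motion per axis with Hurst exponent H.

    The per-axis increment variance over one frame is 2·D·Δt^2H, so the
    ensemble MSD scales as 4·D·τ^2H and the true anomalous exponent is 2H.
    H = 0.5 reduces to ordinary Brownian motion.
    """
    H = float(cfg.regime_params.get("hurst", 0.5))
    D = float(cfg.regime_params.get("D", 0.5))
    if not (0.0 < H < 1.0):
        raise ValueError("hurst must lie strictly inside (0, 1)")
    if D < 0:
        raise ValueError("fbm D must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_trajectories, cfg.n_frames
    sigma = math.sqrt(2.0 * D * cfg.frame_interval ** (2.0 * H))
    L = _fgn_cholesky(m - 1, H)
    z = rng.standard_normal(size=(n, m - 1, 2))
    # correlated fGn increments: sigma * L @ z along the time axis
    steps = sigma * np.einsum("ij,njk->nik", L, z)
    positions = np.concatenate(
        [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    positions = _add_noise(rng, positions, cfg.localization_noise_sd)
    ts = _make_set(cfg, positions, "fbm")
    labels = _labels_frame(ts.ids(), "fbm", D, 2.0 * H)
    return ts, labels


def simulate_immobile(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Stuck particles: constant true position plus per-frame localization noise.

    The expected time-averaged MSD plateaus at 4·σ² for every lag ≥ 1
    (each endpoint contributes 2·σ² across the two axes).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_trajectories, cfg.n_frames
    origins = rng.uniform(0.0, 10.0, size=(n, 1, 2))
    positions = np.broadcast_to(origins, (n, m, 2)).copy()
    positions = _add_noise(rng, positions, cfg.localization_noise_sd)
    ts = _make_set(cfg, positions, "immobile")
    labels = _labels_frame(ts.ids(), "immobile", np.nan, 0.0)
    return ts, labels


def simulate_directed(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Ballistic transport: v·t along a random unit direction, plus optional
    Brownian motion and localization noise. At long lags MSD → v²τ² (α → 2)."""
    v = float(cfg.regime_params.get("velocity", 0.5))
    D = float(cfg.regime_params.get("D", 0.0))
    if v <= 0:
        raise ValueError("directed velocity must be > 0")
    if D < 0:
        raise ValueError("directed D must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_trajectories, cfg.n_frames
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    u = np.column_stack([np.cos(theta), np.sin(theta)])  # unit direction
    t = np.arange(m) * cfg.frame_interval
    positions = v * t[None, :, None] * u[:, None, :]
    if D > 0:
        steps = rng.normal(0.0, math.sqrt(2.0 * D * cfg.frame_interval), size=(n, m - 1, 2))
        positions = positions + np.concatenate(
            [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
    positions = _add_noise(rng, positions, cfg.localization_noise_sd)
    ts = _make_set(cfg, positions, "directed")
    labels = _labels_frame(ts.ids(), "directed", D, 2.0)
    labels["direction_x"] = u[:, 0]
    labels["direction_y"] = u[:, 1]
    return ts, labels


_SIMULATORS = {
    "brownian": simulate_brownian,
    "fbm": simulate_fbm,
    "immobile": simulate_immobile,
    "directed": simulate_directed,
}


def _mixture_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment so component counts sum to total."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def simulate_mixture(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """A population mixing several regimes at stated fractions."""
    comps = cfg.regime_params["components"]
    fracs = np.array([c["fraction"] for c in comps], dtype=float)
    counts = _mixture_counts(fracs, cfg.n_trajectories)
    rng = np.random.default_rng(cfg.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(comps))
    all_trajs: list[Trajectory] = []
    all_labels: list[pd.DataFrame] = []
    for ci, (comp, count, child_seed) in enumerate(zip(comps, counts, child_seeds)):
        if count == 0:
            continue
        params = {k: v for k, v in comp.items() if k not in ("regime", "fraction")}
        sub = SimulationConfig(
            n_trajectories=int(count),
            n_frames=cfg.n_frames,
            frame_interval=cfg.frame_interval,
            pixel_size=cfg.pixel_size,
            localization_noise_sd=cfg.localization_noise_sd,
            seed=int(child_seed),
            regime=comp["regime"],
            regime_params=params,
        )
        ts, labels = _SIMULATORS[comp["regime"]](sub)
        for tr in ts:
            tr.trajectory_id = f"c{ci}_{tr.trajectory_id}"
        labels["trajectory_id"] = [f"c{ci}_{i}" for i in labels["trajectory_id"]]
        all_trajs.extend(ts.trajectories)
        all_labels.append(labels)
    out = TrajectorySet(all_trajs, cfg.frame_interval, source="simulated:mixture")
    return out, pd.concat(all_labels, ignore_index=True)


def simulate_trajectories(cfg: SimulationConfig) -> tuple[TrajectorySet, pd.DataFrame]:
    """Dispatch on ``cfg.regime``; the uniform entry point used by the CLI."""
    if cfg.regime == "mixture":
        return simulate_mixture(cfg)
    return _SIMULATORS[cfg.regime](cfg)


# ---------------------------------------------------------------------------
# Nuclei image fixture
# ---------------------------------------------------------------------------


@dataclass
class ImageSimConfig:
    """Two-channel nuclei image fixture parameters (pixels and arbitrary
    intensity units)."""

    width: int = 512
    height: int = 512
    n_nuclei: int = 100
    positive_fraction: float = 0.4
    blob_sigma: float = 2.5
    blob_amplitude: float = 150.0
    min_separation: float = 12.0
    background_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


def _place_centers(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nuclei centers at pairwise distance >= min_separation."""
    margin = 3.0 * cfg.blob_sigma
    centers: list[np.ndarray] = []
    max_tries = 500 * max(cfg.n_nuclei, 1)
    tries = 0
    while len(centers) < cfg.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} nuclei at separation "
                f"{cfg.min_separation} within {max_tries} tries"
            )
        c = np.array(
            [
                rng.uniform(margin, cfg.height - margin),
                rng.uniform(margin, cfg.width - margin),
            ]
        )
        if all(np.linalg.norm(c - p) >= cfg.min_separation for p in centers):
            centers.append(c)
    return np.array(centers).reshape(-1, 2)


def _render_blobs(
    shape: tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    half = int(math.ceil(4.0 * sigma))
    for cy, cx in centers:
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0, x1 = int(cx) - half, int(cx) + half + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
        )
    return img


def generate_nuclei_image(cfg: ImageSimConfig):
    """Render a two-channel nuclei image with a known marker-positive fraction.

    Channel 1 (nuclear stain) has ``n_nuclei`` Gaussian blobs placed at
    pairwise distance ≥ ``min_separation``; channel 2 (marker) re-renders a
    ``round(positive_fraction · n_nuclei)``-sized subset of the same centers
    (perfect colocalization). Gaussian background noise is added to both
    channels and intensities are clipped at zero.

    Returns
    -------
    (TwoChannelImage, NucleiQuantResult)
        The image plus the exact ground-truth counts.
    """
    from .imaging import NucleiQuantResult, TwoChannelImage

    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    centers = _place_centers(cfg, rng)
    n_pos = int(round(cfg.positive_fraction * cfg.n_nuclei))
    pos_idx = rng.choice(cfg.n_nuclei, size=n_pos, replace=False) if n_pos else np.array([], dtype=int)
    nuclear = _render_blobs(shape, centers, cfg.blob_sigma, cfg.blob_amplitude)
    marker = _render_blobs(shape, centers[pos_idx], cfg.blob_sigma, cfg.blob_amplitude)
    if cfg.background_sd > 0:
        nuclear = nuclear + rng.normal(0.0, cfg.background_sd, shape)
        marker = marker + rng.normal(0.0, cfg.background_sd, shape)
    nuclear = np.clip(nuclear, 0.0, None)
    marker = np.clip(marker, 0.0, None)
    centroids = pd.DataFrame(
        {
            "y": centers[:, 0],
            "x": centers[:, 1],
            "marker_positive": np.isin(np.arange(cfg.n_nuclei), pos_idx),
        }
    )
    percent = 100.0 * n_pos / cfg.n_nuclei if cfg.n_nuclei else float("nan")
    truth = NucleiQuantResult(
        total_nuclei=cfg.n_nuclei,
        positive_nuclei=n_pos,
        percent_positive=percent,
        centroids=centroids,
    )
    return TwoChannelImage(nuclear=nuclear, marker=marker), truth


# ---------------------------------------------------------------------------
# Plate-reader assay table fixture
# ---------------------------------------------------------------------------


def generate_assay_table(
    schedule: Sequence[dict],
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a longitudinal plate-reader table with replicate wells.

    Each ``schedule`` entry is a dict with keys ``group``, ``timepoint``,
    ``n_slices``, ``mean`` and ``noise_sd``; one row is emitted per slice per
    replicate, with readings drawn N(mean, noise_sd). Exactly one entry must
    describe the full-lysis acute control (``group == "TX100_acute"``), which
    anchors %LDH normalization downstream.

    Returns a DataFrame with columns
    ``slice_id, group, timepoint, replicate, reading, is_control``.
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    n_ctrl = sum(1 for e in schedule if e["group"] == "TX100_acute")
    if n_ctrl != 1:
        raise ValueError(
            f"schedule must contain exactly one TX100_acute control entry, found {n_ctrl}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for entry in schedule:
        group = entry["group"]
        tp = entry["timepoint"]
        mean = float(entry["mean"])
        sd = float(entry.get("noise_sd", 0.0))
        for s in range(int(entry["n_slices"])):
            slice_id = f"{group}_s{s:02d}"
            for r in range(n_replicates):
                reading = mean if sd == 0 else rng.normal(mean, sd)
                rows.append(
                    {
                        "slice_id": slice_id,
                        "group": group,
                        "timepoint": tp,
                        "replicate": r,
                        "reading": max(reading, 0.0),
                        "is_control": group.startswith("TX100"),
                    }
                )
    return pd.DataFrame(rows)
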