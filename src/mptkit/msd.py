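"""Time-averaged MSD, effective diffusion coefficients, anomalous-exponent
fits, and diffusion-mode classification.

For a trajectory with N points on a uniform frame grid, the time-averaged
mean squared displacement at lag n (lag time τ = n·Δt) is

    MSD(n) = (1/(N−n)) · Σ_{i=0}^{N−n−1} [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²]

The effective diffusion coefficient follows from the Einstein–Smoluchowski
relation for two-dimensional diffusion, D_eff = MSD/(4τ), and the anomalous
diffusion exponent α from fitting MSD = 4·D·τ^α (ordinary least squares of
ln MSD on ln τ). Trajectories are classified by α into immobile (α < 0.1),
subdiffusive (0.1 ≤ α < 0.9), normally diffusive (0.9 ≤ α ≤ 1.1), or
superdiffusive (α > 1.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trajectories import Trajectory, TrajectorySet

MODES = ("immobile", "subdiffusive", "normal", "superdiffusive")

#: default lag window (inclusive) over which D_eff averages MSD/(4τ)
DEFAULT_DEFF_LAGS = (1, 10)
#: default lag window (inclusive) for the log-log α fit
DEFAULT_ALPHA_LAGS = (1, 30)

LagSpec = Union[int, tuple[int, int]]


@dataclass
class MSDProfile:
    """Per-trajectory time-averaged MSD versus lag.

    ``n_pairs(n) = N − n`` counts the displacement pairs entering each lag,
    used downstream for precision weighting.
    """

    trajectory_id: str
    lags: np.ndarray       # lag in frames, 1..max_lag
    tau: np.ndarray        # lag time in seconds
    msd: np.ndarray        # μm²
    n_pairs: np.ndarray    # N − n
    frame_interval: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.msd = np.asarray(self.msd, dtype=np.float64)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(self.msd < 0):
            raise ValueError("MSD values must be nonnegative")
        if np.any(np.diff(self.n_pairs) >= 0):
            if len(self.n_pairs) > 1:
                raise ValueError("n_pairs must be strictly decreasing in lag")

    @property
    def max_lag(self) -> int:
        return int(self.lags[-1])


@dataclass
class EnsembleMSD:
    """Precision-weighted geometric ensemble MSD across trajectories."""

    lags: np.ndarray
    tau: np.ndarray
    geo_msd: np.ndarray
    weight_sum: np.ndarray
    n_trajectories: np.ndarray
    weighting: str


@dataclass
class AlphaFit:
    alpha: float
    D_fit: float
    fit_r2: float
    fit_range: tuple[int, int]
    degenerate: bool = False


@dataclass
class DiffusionSummary:
    """Per-trajectory diffusion descriptors."""

    trajectory_id: str
    D_eff: float
    alpha: float
    fit_r2: float
    fit_range: tuple[int, int]
    mode: str
    degenerate_fit: bool = False


@dataclass
class PopulationSummary:
    """Median/IQR population summary plus diffusion-mode fractions."""

    n: int
    deff_median: float
    deff_iqr: tuple[float, float]
    alpha_median: float
    mode_fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "deff_median_um2_s": self.deff_median,
            "deff_iqr_um2_s": list(self.deff_iqr),
            "alpha_median": self.alpha_median,
            "mode_fractions": dict(self.mode_fractions),
        }


def default_max_lag(n_points: int) -> int:
    """floor(N/3), clipped to [1, N−1] — limits high-variance long lags."""
    return min(max(n_points // 3, 1), n_points - 1)


def compute_msd(traj: Trajectory, max_lag: Optional[int] = None) -> MSDProfile:
    """Time-averaged MSD of one trajectory for lags 1..max_lag.

    Requires a uniform frame grid (run the gap filter first); ``max_lag``
    defaults to floor(N/3).
    """
    steps = np.diff(traj.frames)
    if not np.all(steps == steps[0]):
        raise ValueError(
            f"trajectory {traj.trajectory_id!r}: non-uniform frame grid; "
            "split or drop gapped trajectories before computing MSD"
        )
    n_points = traj.n_points
    if max_lag is None:
        max_lag = default_max_lag(n_points)
    if not (1 <= max_lag <= n_points - 1):
        raise ValueError(f"max_lag must be in [1, {n_points - 1}], got {max_lag}")
    dt = (traj.t[1] - traj.t[0])  # uniform by construction
    r = traj.positions
    lags = np.arange(1, max_lag + 1, dtype=np.int64)
    msd = np.empty(max_lag, dtype=np.float64)
    for j, n in enumerate(lags):
        d = r[n:] - r[:-n]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        msd[j] = np.sum(sq) / (n_points - n)
    return MSDProfile(
        trajectory_id=traj.trajectory_id,
        lags=lags,
        tau=lags * dt,
        msd=msd,
        n_pairs=n_points - lags,
        frame_interval=float(dt / steps[0]),
    )


def ensemble_msd(
    profiles: Sequence[MSDProfile], weighting: str = "pairs"
) -> EnsembleMSD:
    """Precision-weighted geometric mean MSD across trajectories, per lag.

    geo_msd(n) = exp( Σ_i w_i ln msd_i(n) / Σ_i w_i ) over trajectories with
    msd_i(n) > 0 and at least one displacement pair. Weight schemes:
    ``pairs`` (w = N−n, the default), ``none`` (w = 1), and
    ``inverse_variance`` (w = (N−n)/msd², since Var[MSD-hat] ∝ msd²/(N−n)).
    Lags where every trajectory has msd = 0 report geo_msd = 0.
    """
    if not profiles:
        raise ValueError("ensemble_msd requires at least one profile")
    if weighting not in ("pairs", "inverse_variance", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    dts = np.array([p.frame_interval for p in profiles])
    if np.any(np.abs(dts - dts[0]) > 1e-9 * max(dts[0], 1.0)):
        raise ValueError("profiles must share a frame interval")
    max_lag = max(p.max_lag for p in profiles)
    lags = np.arange(1, max_lag + 1, dtype=np.int64)
    geo = np.zeros(max_lag)
    wsum = np.zeros(max_lag)
    ntraj = np.zeros(max_lag, dtype=np.int64)
    for j, n in enumerate(lags):
        logs, ws = [], []
        present = 0
        for p in profiles:
            if n > p.max_lag:
                continue
            idx = n - 1  # lags are 1..max_lag in order
            m, npair = p.msd[idx], p.n_pairs[idx]
            if npair < 1:
                continue
            present += 1
            if m <= 0:
                continue
            if weighting == "pairs":
                w = float(npair)
            elif weighting == "inverse_variance":
                w = float(npair) / (m * m)
            else:
                w = 1.0
            logs.append(math.log(m))
            ws.append(w)
        ntraj[j] = present
        if ws:
            wsum[j] = sum(ws)
            geo[j] = math.exp(float(np.dot(ws, logs)) / wsum[j])
        else:
            geo[j] = 0.0  # all-zero (or absent) lag
    tau = lags * float(np.median([p.tau[0] / p.lags[0] for p in profiles]))
    return EnsembleMSD(lags, tau, geo, wsum, ntraj, weighting)


def _resolve_lags(profile: MSDProfile, spec: LagSpec) -> np.ndarray:
    if isinstance(spec, (int, np.integer)):
        lo = hi = int(spec)
    else:
        lo, hi = int(spec[0]), int(spec[1])
    sel = (profile.lags >= lo) & (profile.lags <= hi)
    return np.nonzero(sel)[0]


def compute_deff(profile: MSDProfile, at_lag: LagSpec = DEFAULT_DEFF_LAGS) -> float:
    """Effective diffusion coefficient D_eff = MSD/(4τ) (2-D).

    ``at_lag`` is a single lag or an inclusive (lo, hi) window; a window
    averages MSD/(4τ) over the lags available in the profile.
    """
    idx = _resolve_lags(profile, at_lag)
    if idx.size == 0:
        raise ValueError(f"lag window {at_lag} is empty for {profile.trajectory_id!r}")
    return float(np.mean(profile.msd[idx] / (4.0 * profile.tau[idx])))


def fit_alpha(
    profile: MSDProfile, fit_range: tuple[int, int] = DEFAULT_ALPHA_LAGS
) -> AlphaFit:
    """Log-log OLS fit of MSD = 4·D·τ^α over ``fit_range`` (inclusive lags).

    Zero-MSD lags carry no information on a log scale and are excluded; a
    trajectory with fewer than 3 positive-MSD lags in range is flagged
    degenerate and assigned α = 0 (a perfectly static particle is immobile,
    not an error).
    """
    lo, hi = int(fit_range[0]), int(fit_range[1])
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid fit_range {fit_range}")
    if lo > profile.max_lag:
        raise ValueError(f"fit_range {fit_range} lies outside the profile")
    idx = _resolve_lags(profile, (lo, hi))
    idx = idx[profile.msd[idx] > 0]
    if idx.size < 3:
        return AlphaFit(alpha=0.0, D_fit=0.0, fit_r2=float("nan"),
                        fit_range=(lo, hi), degenerate=True)
    lx = np.log(profile.tau[idx])
    ly = np.log(profile.msd[idx])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return AlphaFit(
        alpha=float(slope),
        D_fit=float(math.exp(intercept) / 4.0),
        fit_r2=r2,
        fit_range=(lo, hi),
    )


def classify_mode(alpha: float) -> str:
    """Diffusion-mode label from the anomalous exponent.

    immobile: α < 0.1; subdiffusive: 0.1 ≤ α < 0.9;
    normal: 0.9 ≤ α ≤ 1.1; superdiffusive: α > 1.1.
    """
    if not np.isfinite(alpha):
        raise ValueError(f"alpha must be finite, got {alpha}")
    if alpha < 0.1:
        return "immobile"
    if alpha < 0.9:
        return "subdiffusive"
    if alpha <= 1.1:
        return "normal"
    return "superdiffusive"


def analyze_trajectory(
    traj: Trajectory,
    max_lag: Optional[int] = None,
    deff_lags: LagSpec = DEFAULT_DEFF_LAGS,
    alpha_lags: tuple[int, int] = DEFAULT_ALPHA_LAGS,
) -> DiffusionSummary:
    """MSD → D_eff → α → mode for a single trajectory."""
    profile = compute_msd(traj, max_lag=max_lag)
    # clip requested windows to what the profile offers
    deff_spec: LagSpec
    if isinstance(deff_lags, (int, np.integer)):
        deff_spec = min(int(deff_lags), profile.max_lag)
    else:
        deff_spec = (deff_lags[0], min(deff_lags[1], profile.max_lag))
    fit = fit_alpha(profile, (alpha_lags[0], min(alpha_lags[1], profile.max_lag)))
    return DiffusionSummary(
        trajectory_id=traj.trajectory_id,
        D_eff=compute_deff(profile, deff_spec),
        alpha=fit.alpha,
        fit_r2=fit.fit_r2,
        fit_range=fit.fit_range,
        mode=classify_mode(fit.alpha),
        degenerate_fit=fit.degenerate,
    )


def analyze_set(
    ts: TrajectorySet,
    max_lag: Optional[int] = None,
    deff_lags: LagSpec = DEFAULT_DEFF_LAGS,
    alpha_lags: tuple[int, int] = DEFAULT_ALPHA_LAGS,
) -> list[DiffusionSummary]:
    """Per-trajectory diffusion summaries for a whole set."""
    return [
        analyze_trajectory(tr, max_lag=max_lag, deff_lags=deff_lags,
                           alpha_lags=alpha_lags)
        for tr in ts
    ]


def summaries_frame(summaries: Sequence[DiffusionSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per trajectory)."""
    return pd.DataFrame(
        {
            "trajectory_id": [s.trajectory_id for s in summaries],
            "D_eff_um2_s": [s.D_eff for s in summaries],
            "alpha": [s.alpha for s in summaries],
            "fit_r2": [s.fit_r2 for s in summaries],
            "mode": [s.mode for s in summaries],
            "degenerate_fit": [s.degenerate_fit for s in summaries],
        }
    )


def summarize_population(summaries: Sequence[DiffusionSummary]) -> PopulationSummary:
    """Median and IQR of D_eff, median α, and the four mode fractions.

    Mode fractions partition the population and sum to 1.
    """
    if not summaries:
        raise ValueError("summarize_population requires at least one summary")
    deff = np.array([s.D_eff for s in summaries])
    alpha = np.array([s.alpha for s in summaries])
    modes = [s.mode for s in summaries]
    n = len(summaries)
    fractions = {m: modes.count(m) / n for m in MODES}
    return PopulationSummary(
        n=n,
        deff_median=float(np.median(deff)),
        deff_iqr=(float(np.percentile(deff, 25)), float(np.percentile(deff, 75))),
        alpha_median=float(np.median(alpha)),
        mode_fractions=fractions,
    )
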