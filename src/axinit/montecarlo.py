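"""Monte Carlo model of stochastic AP initiation along an expanding zone.

Each trial draws an initiation site x* from a zone on the proximal axon and
a recording position x; the soma–axon latency is modelled kinematically:

    t_a − t_s = T(x*, x) − δ_soma + ε

where T is the travel time between the initiation site and the recording
position at the local conduction velocity v(x), δ_soma is the (constant)
lag with which the somatic spike follows initiation — the soma is
electrotonically compact and driven by the whole proximal axon — and ε is
Gaussian measurement noise.  Third-spike trials use an expanded zone and,
optionally, a proximally decelerated velocity
``v3(x) = v·(1 − a·exp(−x/λ))``; deceleration also delays the somatic spike
by the total added travel time of the decelerated proximal path.

Defaults represent the study conditions: a ~5-µm first-spike zone centred
22.5 µm from the soma, a 110-µm third-spike zone starting at 20 µm, uniform
initiation-site distribution, 180 µm/ms baseline velocity, recording
positions uniform on 10–350 µm, 50 µs measurement noise, 1,000 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MCLatencyConfig",
    "LatencyDataset",
    "simulate_latency_dataset",
    "mc_regression_test",
    "latency_sd_by_spike",
]


@dataclass(frozen=True)
class MCLatencyConfig:
    zone_center_first: float = 22.5  # µm
    zone_length_first: float = 5.0  # µm
    zone_center_third: float = 75.0  # µm (zone 20-130 µm)
    zone_length_third: float = 110.0  # µm
    site_distribution: str = "uniform"  # or "truncated_gaussian"
    velocity: float = 180.0  # µm/ms baseline
    decel_factor_third: float = 0.0  # a in v3 = v (1 - a exp(-x/λ))
    decel_length: float = 50.0  # λ, µm
    recording_range: tuple[float, float] = (10.0, 350.0)
    noise_sd_us: float = 50.0
    soma_delay_us: float = 150.0
    n_points: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zone_length_first < 0 or self.zone_length_third < 0:
            raise ValueError("zone lengths must be >= 0")
        if self.velocity <= 0 or not 0.0 <= self.decel_factor_third < 1.0:
            raise ValueError("v(x) must be positive everywhere")
        if self.decel_length <= 0:
            raise ValueError("deceleration length constant must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.noise_sd_us < 0:
            raise ValueError("noise s.d. must be >= 0")
        if self.site_distribution not in ("uniform", "truncated_gaussian"):
            raise ValueError(f"unknown distribution {self.site_distribution!r}")


@dataclass
class LatencyDataset:
    """Simulated (distance, spike index, t_a − t_s) records; bit-reproducible."""

    records: pd.DataFrame  # distance_um, spike_index, latency_us, trial
    config: MCLatencyConfig

    def provenance(self) -> dict:
        return asdict(self.config)

    def __len__(self) -> int:
        return len(self.records)


def _travel_time_table(cfg: MCLatencyConfig, xmax: float, dx: float = 0.25):
    """Cumulative travel-time functions (ms) for spikes 1 and 3 on a grid."""
    grid = np.arange(0.0, xmax + dx, dx)
    inv_v1 = np.full_like(grid, 1.0 / cfg.velocity)
    v3 = cfg.velocity * (1.0 - cfg.decel_factor_third * np.exp(-grid / cfg.decel_length))
    inv_v3 = 1.0 / v3
    tt1 = np.concatenate(([0.0], np.cumsum((inv_v1[1:] + inv_v1[:-1]) / 2.0 * dx)))
    tt3 = np.concatenate(([0.0], np.cumsum((inv_v3[1:] + inv_v3[:-1]) / 2.0 * dx)))
    return grid, tt1, tt3


def _draw_sites(rng, cfg: MCLatencyConfig, center: float, length: float, n: int):
    if length == 0:
        return np.full(n, center)
    if cfg.site_distribution == "uniform":
        return rng.uniform(center - length / 2.0, center + length / 2.0, n)
    sd = length / 4.0
    x = rng.normal(center, sd, n)
    lo, hi = center - length / 2.0, center + length / 2.0
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(center, sd, int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return np.clip(x, 0.0, None)


def simulate_latency_dataset(config: MCLatencyConfig) -> LatencyDataset:
    """Simulate paired first/third-spike latency measurements.

    Each of ``n_points`` trials yields one first-spike and one third-spike
    record at the same recording position.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_points
    x_rec = rng.uniform(*cfg.recording_range, n)
    x1 = np.clip(_draw_sites(rng, cfg, cfg.zone_center_first, cfg.zone_length_first, n), 0.0, None)
    x3 = np.clip(_draw_sites(rng, cfg, cfg.zone_center_third, cfg.zone_length_third, n), 0.0, None)
    xmax = max(cfg.recording_range[1], np.max(x1), np.max(x3)) + 10.0
    grid, tt1, tt3 = _travel_time_table(cfg, xmax)

    def travel(tt, a, b):
        return np.abs(np.interp(b, grid, tt) - np.interp(a, grid, tt))

    # deceleration delays the somatic spike by the total excess travel time
    # of the decelerated proximal path
    extra_soma = 1000.0 * (tt3[-1] - tt1[-1])
    noise1 = rng.normal(0.0, cfg.noise_sd_us, n)
    noise3 = rng.normal(0.0, cfg.noise_sd_us, n)
    lat1 = 1000.0 * travel(tt1, x1, x_rec) - cfg.soma_delay_us + noise1
    lat3 = (
        1000.0 * travel(tt3, x3, x_rec)
        - (cfg.soma_delay_us + extra_soma)
        + noise3
    )
    rec = pd.DataFrame(
        {
            "distance_um": np.concatenate([x_rec, x_rec]),
            "spike_index": np.concatenate([np.ones(n, int), np.full(n, 3)]),
            "latency_us": np.concatenate([lat1, lat3]),
            "trial": np.concatenate([np.arange(n), np.arange(n)]),
        }
    )
    return LatencyDataset(records=rec, config=cfg)


def mc_regression_test(
    dataset: LatencyDataset, dist_range: tuple[float, float] = (0.0, 200.0)
) -> tuple[float, float]:
    """OLS slope and two-sided p of the latency change vs distance.

    The per-trial latency change (third − first spike) is regressed on the
    recording distance restricted to ``dist_range``.
    """
    rec = dataset.records
    first = rec[rec.spike_index == 1].set_index("trial")
    third = rec[rec.spike_index == 3].set_index("trial")
    dlat = third.latency_us - first.latency_us
    x = first.distance_um
    m = (x >= dist_range[0]) & (x <= dist_range[1])
    if m.sum() < 3:
        raise ValueError("need >= 3 points in the distance range")
    res = stats.linregress(x[m].to_numpy(), dlat[m].to_numpy())
    return float(res.slope), float(res.pvalue)


def latency_sd_by_spike(
    dataset: LatencyDataset, distance_bins: np.ndarray | None = None
) -> pd.DataFrame:
    """Sample s.d. of the latency per spike index (optionally per distance bin)."""
    rec = dataset.records.copy()
    keys = ["spike_index"]
    if distance_bins is not None:
        rec["bin"] = pd.cut(rec.distance_um, distance_bins)
        keys.append("bin")
    g = rec.groupby(keys, observed=True)["latency_us"]
    out = g.agg(["std", "count"]).reset_index().rename(columns={"std": "sd_us", "count": "n"})
    singletons = out[out.n < 2]
    if len(singletons):
        import logging

        logging.getLogger(__name__).warning(
            "%d singleton group(s) skipped in latency s.d.", len(singletons)
        )
        out = out[out.n >= 2]
    return out
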