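"""Synthetic-data generators standing in for the study's recordings.

All generators are pure functions of (configuration, seed): noisy SBFI
fluorescence traces under the standard stimulation protocols, loose-patch
style axonal recordings mixing membrane voltage with its first derivative,
and Monte Carlo latency datasets.  Defaults emulate the stated recording
conditions: voltage sampled at 20 kHz, fluorescence at 2 kHz
(linescan-equivalent), additive Gaussian noise of 5% of baseline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import StateTrace
from .montecarlo import MCLatencyConfig, LatencyDataset, simulate_latency_dataset
from .sbfi import (
    NaKineticParams,
    protocol_duration,
    protocol_spike_times,
    sbfi_fluorescence,
    simulate_na_system,
)

__all__ = [
    "NoiseSpec",
    "LoosePatchMix",
    "make_sbfi_fixture",
    "make_loose_patch_trace",
    "make_latency_fixture",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian (fraction of baseline) plus optional shot noise."""

    sd_fraction: float = 0.05
    shot_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_fraction < 0 or self.shot_scale < 0:
            raise ValueError("noise scales must be >= 0")

    def apply(self, y: np.ndarray, baseline: float = 1.0) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        out = y + rng.normal(0.0, self.sd_fraction * baseline, y.shape)
        if self.shot_scale > 0:
            out = out + rng.normal(0.0, self.shot_scale * np.sqrt(np.abs(y)), y.shape)
        return out


@dataclass(frozen=True)
class LoosePatchMix:
    """Loose-patch signal weights: α·V(t) + β·dV/dt(t)."""

    alpha: float = 0.05
    beta: float = 1.0
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(sd_fraction=0.0))

    def __post_init__(self) -> None:
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def make_sbfi_fixture(
    params: NaKineticParams | None = None,
    protocol: str = "5AP20Hz",
    noise: NoiseSpec = NoiseSpec(sd_fraction=0.0),
    path=None,
    sample_dt: float = 0.5,  # 2 kHz linescan-equivalent
    brightness_ratio: float = 0.5,
    onset: float = 50.0,
) -> pd.DataFrame:
    """Forward-simulated SBFI ΔF/F trace for a named protocol, plus noise.

    Returns a two-column table (time ms, dff); with ``path`` it is written
    as delimited text with the generating parameters embedded as header
    comments.
    """
    if params is None:
        params = NaKineticParams()
    from dataclasses import replace

    params = replace(params, spike_times=protocol_spike_times(protocol, onset))
    duration = protocol_duration(protocol, onset)
    trace = simulate_na_system(params, duration, dt=0.01)
    fl = sbfi_fluorescence(trace, brightness_ratio)
    t = np.arange(0.0, duration, sample_dt)
    dff = np.interp(t, fl.t, fl.dff)
    dff = noise.apply(dff, baseline=1.0)
    df = pd.DataFrame({"time_ms": t, "dff": dff})
    if path is not None:
        prov = {
            "protocol": protocol, "k_on_M_ms": params.k_on, "k_d_mM": params.k_d,
            "p_na_per_ms": params.p_na, "d_na_per_s": params.d_na,
            "dna_per_spike_mM": params.dna_per_spike, "sigma_ms": params.sigma,
            "sbfi_total_mM": params.sbfi_total, "na_rest_mM": params.na_rest,
            "brightness_ratio": brightness_ratio, "noise_sd": noise.sd_fraction,
            "seed": noise.seed, "onset_ms": onset,
        }
        write_trace_csv(df, path, prov)
    return df


def write_trace_csv(df: pd.DataFrame, path, provenance: dict) -> None:
    buf = io.StringIO()
    for k, v in provenance.items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trace_csv(path) -> tuple[pd.DataFrame, dict]:
    prov = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, _, v = line[1:].partition(":")
            prov[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    return df, prov


def make_loose_patch_trace(
    trace: StateTrace,
    distance: float,
    mix: LoosePatchMix = LoosePatchMix(),
    sample_rate_khz: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic loose-patch recording at an axonal site.

    The signal is α·V(t) + β·dV/dt(t) plus noise, resampled to the target
    rate (default 20 kHz).  Returns (time ms, signal).
    """
    i = trace.site_index(distance)
    v = trace.v[:, i]
    dt = trace.dt
    dvdt = np.gradient(v, dt)
    sig = mix.alpha * v + mix.beta * dvdt
    ts = np.arange(trace.t[0], trace.t[-1], 1.0 / sample_rate_khz)
    out = np.interp(ts, trace.t, sig)
    baseline = max(float(np.std(sig)), 1e-9)
    return ts, mix.noise.apply(out, baseline=baseline)


def make_latency_fixture(config: MCLatencyConfig, path=None) -> LatencyDataset:
    """Monte Carlo latency dataset, optionally written as delimited text."""
    ds = simulate_latency_dataset(config)
    if path is not None:
        prov = {k: v for k, v in ds.provenance().items()}
        write_trace_csv(ds.records, path, prov)
    return ds
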