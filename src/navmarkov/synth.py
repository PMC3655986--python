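"""Synthetic "experimental" data with known ground truth.

Generates noisy current-trace families (simulator output plus additive
Gaussian recording noise scaled to the family's peak current, with an
optional linear baseline drift) and noisy closed-form curve samples
(Boltzmann, mono-/bi-exponential) for closed-loop tests of the analysis and
fitting machinery.  Every generator is deterministic per seed, and file
output carries the generating truth in the metadata sidecar.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .protocols import VoltageProtocol
from .scheme import KineticScheme, ModelParameters
from .simulate import SimConfig, SimulatedTrace, run_protocol, write_traces

__all__ = [
    "NoiseModel",
    "make_noisy_traces",
    "write_noisy_traces",
    "make_boltzmann_samples",
    "make_exp_samples",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: s.d. = ``sigma`` × the family's peak |I|.

    ``drift`` adds a deterministic linear baseline (fraction of peak per ms).
    """

    sigma: float = 0.01
    drift: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def make_noisy_traces(
    scheme: KineticScheme,
    params: ModelParameters,
    protocol: VoltageProtocol,
    noise: NoiseModel,
    seed: int,
    config: SimConfig | None = None,
) -> list[SimulatedTrace]:
    """Simulate ``protocol`` and overlay i.i.d. Gaussian noise on the current."""
    traces = run_protocol(scheme, params, protocol, config)
    rng = np.random.default_rng(seed)
    peak = max(np.max(np.abs(tr.current)) for tr in traces)
    scale = noise.sigma * peak
    for tr in traces:
        noisy = tr.current.copy()
        if scale > 0:
            noisy += rng.normal(0.0, scale, size=noisy.shape)
        if noise.drift:
            noisy += noise.drift * peak * tr.time
        tr.current = noisy
    return traces


def write_noisy_traces(path, scheme, params, protocol, noise, seed, config=None):
    """Generate noisy traces and write them with a ground-truth sidecar."""
    traces = make_noisy_traces(scheme, params, protocol, noise, seed, config)
    truth = {
        "scheme": scheme.name,
        "noise": asdict(noise),
        "seed": int(seed),
        "parameters": {
            k: (dict(v) if isinstance(v, dict) else float(v)) for k, v in params.items()
        },
    }
    write_traces(traces, path, metadata={"truth": truth})
    return traces


def make_boltzmann_samples(
    v50: float, k: float, voltages, sigma: float = 0.0, seed: int = 0, falling: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of a (rising or falling) Boltzmann with additive noise."""
    V = np.asarray(voltages, float)
    s = (V - v50) if falling else (v50 - V)
    y = 1.0 / (1.0 + np.exp(s / k))
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=y.shape)
    return V, y


def make_exp_samples(
    times,
    taus,
    amplitudes,
    offset: float = 1.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of ``offset − Σ aᵢ·exp(−t/τᵢ)`` (recovery-style rise) + noise."""
    t = np.asarray(times, float)
    taus = np.atleast_1d(np.asarray(taus, float))
    amps = np.atleast_1d(np.asarray(amplitudes, float))
    if taus.shape != amps.shape:
        raise ValueError("taus and amplitudes must have matching lengths")
    y = offset - sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=y.shape)
    return t, y
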