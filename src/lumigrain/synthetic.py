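"""Simulation of labeled delayed-luminescence photon-count signals.

Each storage-year class is described by the three hyperbolic-decay parameters
(initial intensity I0, relaxation exponent beta, timescale tau).  A sample is
drawn by jittering the class centre, evaluating the decay law on the
acquisition grid, adding the constant instrument background, and (optionally)
Poisson photon counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import DLSignal, write_signal_csv

__all__ = [
    "ClassProfile",
    "AcquisitionConfig",
    "DEFAULT_PROFILES",
    "sample_parameters",
    "generate_signal",
    "generate_dataset",
]


@dataclass(frozen=True)
class ClassProfile:
    """Per-class decay-parameter centres plus a relative spread knob."""

    label: str
    mean_I0: float
    mean_beta: float
    mean_tau: float
    rel_spread: float = 0.06

    def __post_init__(self) -> None:
        if self.mean_I0 <= 0 or self.mean_beta <= 0 or self.mean_tau <= 0:
            raise ValueError("profile means must be strictly positive")
        if not 0.0 <= self.rel_spread <= 0.5:
            raise ValueError("rel_spread must lie in [0, 0.5]")


#: Fitted decay parameters of one exemplar trace per storage year (2015-2019).
DEFAULT_PROFILES: tuple[ClassProfile, ...] = (
    ClassProfile("SW2015", 2907.0, 0.724, 4.47),
    ClassProfile("SW2016", 2837.0, 0.653, 4.46),
    ClassProfile("SW2017", 3080.0, 0.663, 4.58),
    ClassProfile("SW2018", 3434.0, 0.796, 3.08),
    ClassProfile("SW2019", 2876.0, 0.744, 5.63),
)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling grid and counting-noise settings of the photon counter."""

    dt: float = 0.1
    total_time: float = 100.0
    background: float = 9.0
    noise_mode: str = "poisson"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.total_time / self.dt
        if n < 1 or abs(n - round(n)) > 1e-9:
            raise ValueError("total_time must be a positive integer multiple of dt")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.noise_mode not in ("none", "poisson"):
            raise ValueError("noise_mode must be 'none' or 'poisson'")

    @property
    def n_points(self) -> int:
        return int(round(self.total_time / self.dt))


def sample_parameters(
    profile: ClassProfile, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw one (I0, beta, tau) triple around the profile centre.

    Each parameter is independent normal with sd = ``rel_spread`` x mean,
    redrawn until strictly positive.  ``rel_spread == 0`` returns the centre
    exactly.
    """

    def draw(mean: float) -> float:
        if profile.rel_spread == 0.0:
            return mean
        sd = profile.rel_spread * mean
        while True:
            v = rng.normal(mean, sd)
            if v > 0.0:
                return float(v)

    return draw(profile.mean_I0), draw(profile.mean_beta), draw(profile.mean_tau)


def generate_signal(
    params: tuple[float, float, float],
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> DLSignal:
    """Evaluate the decay law on the acquisition grid and apply counting noise.

    Bin ``k`` sits at ``t_k = k * dt`` and has expected rate
    ``I0 / (1 + t_k / tau)**beta + background``.  ``noise_mode='none'`` returns
    the rates exactly (real valued); ``'poisson'`` returns integer draws.
    """
    I0, beta, tau = params
    if I0 <= 0 or beta <= 0 or tau <= 0:
        raise ValueError("decay parameters must be strictly positive")
    times = np.arange(acq.n_points) * acq.dt
    lam = I0 / (1.0 + times / tau) ** beta + acq.background
    if acq.noise_mode == "poisson":
        if rng is None:
            raise ValueError("poisson noise requires a random generator")
        values = rng.poisson(lam).astype(float)
    else:
        values = lam
    meta = {"I0": I0, "beta": beta, "tau": tau, "background": acq.background,
            "noise_mode": acq.noise_mode}
    return DLSignal(times, values, acq.dt, meta)


def generate_dataset(
    profiles: list[ClassProfile] | tuple[ClassProfile, ...],
    n_per_class: int,
    acq: AcquisitionConfig,
    seed: int,
) -> list[DLSignal]:
    """Generate ``n_per_class`` labeled signals per profile, reproducibly.

    The returned signals carry their class label in ``meta['label']``.
    Duplicate class labels are rejected.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in profiles")
    rng = np.random.default_rng(seed)
    signals: list[DLSignal] = []
    for profile in profiles:
        for _ in range(n_per_class):
            params = sample_parameters(profile, rng)
            sig = generate_signal(params, acq, rng)
            sig.meta["label"] = profile.label
            signals.append(sig)
    return signals


def write_dataset(signals: list[DLSignal], out_dir: str | Path) -> Path:
    """Dump signals as ``sample_0000.csv`` ... plus a ``manifest.csv`` index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sig in enumerate(signals):
        name = f"sample_{i:04d}.csv"
        write_signal_csv(sig, out / name)
        rows.append({"file": name, "label": sig.meta.get("label", "")})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def profiles_with_spread(rel_spread: float) -> tuple[ClassProfile, ...]:
    """The default class profiles with a common relative spread."""
    return tuple(replace(p, rel_spread=rel_spread) for p in DEFAULT_PROFILES)
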