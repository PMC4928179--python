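"""Synthetic SAXS profiles from specified Rg ensembles.

The generator produces intensity curves under the same sphere forward
model the fitting code assumes: a weighted mixture of components, each a
single size (delta) or a log-normal distribution of sizes, evaluated on a
q grid reaching past 0.3 Å⁻¹ (the conventional minimum coverage for a
meaningful Kratky/Porod analysis).  Optional multiplicative Gaussian
noise emulates the crude statistical structure of deposited experimental
data: relative errors that grow where the intensity has decayed.

Ground truth (the generating EnsembleSpec and seed) travels with each file in a
JSON sidecar so recovery tests never have to reverse-engineer it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_dat
from .profiles import ScatteringProfile
from .rgd import RgLogNormal, entropy, model_intensity
from .sphere import sphere_intensity

DEFAULT_Q_GRID = np.linspace(0.005, 0.35, 400)


@dataclass(frozen=True)
class Component:
    """One mixture component: a delta at ``rg`` or a log-normal (μ, σ)."""

    weight: float
    kind: str  # "delta" | "lognormal"
    rg: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.kind not in ("delta", "lognormal"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("component weights must be positive")
        if self.kind == "delta" and (self.rg is None or self.rg <= 0):
            raise ValueError("delta component needs rg > 0")
        if self.kind == "lognormal" and (self.mu is None or self.sigma is None):
            raise ValueError("lognormal component needs (mu, sigma)")


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for one synthetic profile."""

    components: tuple[Component, ...]
    q_grid: np.ndarray = field(default_factory=lambda: DEFAULT_Q_GRID.copy())
    noise: str = "none"  # "none" | "multiplicative_gaussian"
    noise_level: float = 0.0
    seed: int = 0
    scale: float = 1.0
    label: str = "synthetic"

    def __post_init__(self):
        w = np.array([c.weight for c in self.components])
        if w.size == 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q grid must be positive and strictly increasing")
        if self.noise not in ("none", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def generate_profile(spec: EnsembleSpec) -> tuple[ScatteringProfile, dict]:
    """Generate a profile from an ensemble spec.

    Returns the profile and a truth descriptor (components, seed, and —
    for a single log-normal component — the true entropy) for use in
    parameter-recovery tests.
    """
    q = spec.q_grid
    clean = np.zeros_like(q)
    for c in spec.components:
        if c.kind == "delta":
            clean += c.weight * sphere_intensity(q, c.rg)
        else:
            clean += c.weight * model_intensity(q, RgLogNormal(c.mu, c.sigma))
    clean *= spec.scale

    sigma = None
    inten = clean
    if spec.noise == "multiplicative_gaussian" and spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_level * clean
        inten = clean * (1.0 + spec.noise_level * rng.standard_normal(q.size))
        keep = inten > 0
        q, inten, sigma = q[keep], inten[keep], sigma[keep]

    profile = ScatteringProfile(q, inten, sigma, spec.label)

    truth: dict = {
        "label": spec.label,
        "seed": spec.seed,
        "scale": spec.scale,
        "noise": spec.noise,
        "noise_level": spec.noise_level,
        "components": [
            {"weight": c.weight, "kind": c.kind, "rg": c.rg, "mu": c.mu, "sigma": c.sigma}
            for c in spec.components
        ],
    }
    if len(spec.components) == 1 and spec.components[0].kind == "lognormal":
        c = spec.components[0]
        truth["entropy"] = entropy(RgLogNormal(c.mu, c.sigma))
    return profile, truth


# The reference triple: a compact folded protein (narrow size distribution),
# a partially disordered one (folded core + flexible tails), and an IDP
# (broad size distribution).  True entropies are strictly increasing.
SUITE_SPECS = {
    "folded": Component(1.0, "lognormal", mu=np.log(16.0), sigma=0.10),
    "partial": Component(1.0, "lognormal", mu=3.0, sigma=0.30),
    "disordered": Component(1.0, "lognormal", mu=3.6, sigma=0.60),
}


def generate_suite(outdir, seed: int = 0, noise_level: float = 0.01) -> list[Path]:
    """Write the folded / partially-disordered / IDP fixture triple.

    Each member gets a ``.dat`` profile (with 1% multiplicative Gaussian
    noise and the matching sigma column by default) and a ``.json`` truth
    sidecar.  Byte-identical across runs for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (name, comp) in enumerate(SUITE_SPECS.items()):
        spec = EnsembleSpec(
            components=(comp,),
            noise="multiplicative_gaussian" if noise_level > 0 else "none",
            noise_level=noise_level,
            seed=seed + k,
            label=name,
        )
        profile, truth = generate_profile(spec)
        dat = outdir / f"{name}.dat"
        write_dat(profile, dat)
        (outdir / f"{name}.json").write_text(json.dumps(truth, indent=2) + "\n")
        paths.append(dat)
    return paths
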