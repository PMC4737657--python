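"""Distinguishable synaptic strengths and bits per synapse.

Signal-detection model: synaptic strength levels are Gaussian distributions
of spine size, each with the same coefficient of variation CV, tiled across
the observed dynamic range (a ``range_factor``-fold span of head volumes).
Adjacent levels are spaced so an ideal observer assigns a sample to the
correct level with probability ``confidence`` (e.g. 0.69, the SNR = 1
psychophysical threshold; the two adjacent Gaussians then overlap by
1 − confidence = 31%).

With z = √2·erf⁻¹(confidence), adjacent means are separated by
s = μ·2·CV·z, i.e. a constant ratio 1 + 2·CV·z, so the number of levels
spanning the range is

    N = ln(range_factor) / ln(1 + 2·CV·z),    bits = log₂(N).

At CV = 0.083, range 60, confidence 0.69: N ≈ 26.3 levels ≈ 4.7 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import erfinv, ndtr

from .errors import DomainError

__all__ = [
    "z_from_confidence",
    "level_spacing",
    "n_distinguishable",
    "bits_from_levels",
    "adjacent_overlap",
    "exact_adjacent_overlap",
    "DiscriminationModel",
    "build_level_ladder",
    "plot_level_ladder",
]


def z_from_confidence(confidence: float) -> float:
    """Gaussian half-width z = √2·erf⁻¹(c) containing a fraction c of the mass."""
    if not 0 <= confidence < 1:
        raise DomainError(f"confidence must be in [0, 1), got {confidence}")
    return math.sqrt(2.0) * float(erfinv(confidence))


def level_spacing(mean: float, cv: float, z: float) -> float:
    """Spacing s = μ·2·CV·z between adjacent level means around mean μ."""
    if mean <= 0:
        raise DomainError(f"mean must be > 0, got {mean}")
    if cv < 0 or z < 0:
        raise DomainError("cv and z must be >= 0")
    return mean * 2.0 * cv * z


def n_distinguishable(range_factor: float, cv: float, confidence: float) -> float:
    """Real-valued number of levels N = ln(range)/ln(1 + 2·CV·z).

    Base-independent; strictly increasing in the range factor and strictly
    decreasing in CV and confidence. A range factor of exactly 1 gives 0.
    """
    if range_factor < 1:
        raise DomainError(f"range_factor must be >= 1, got {range_factor}")
    if cv <= 0:
        raise DomainError(f"cv must be > 0, got {cv}")
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    if range_factor == 1:
        return 0.0
    z = z_from_confidence(confidence)
    return math.log(range_factor) / math.log1p(2.0 * cv * z)


def bits_from_levels(n: float) -> float:
    """Bits of storage implied by n distinguishable levels: log₂(n)."""
    if n <= 0:
        raise DomainError(f"level count must be > 0, got {n}")
    return math.log2(n)


def adjacent_overlap(confidence: float) -> float:
    """Overlap of adjacent level distributions under the equal-σ convention.

    Two unit-σ Gaussians whose means are 2z apart overlap by 2·Φ(−z); with
    z = √2·erf⁻¹(c) this equals exactly 1 − c (31% at c = 0.69).
    """
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    z = z_from_confidence(confidence)
    return 2.0 * float(ndtr(-z))


def exact_adjacent_overlap(cv: float, confidence: float) -> float:
    """Diagnostic: exact overlap when σ is proportional to the mean.

    Adjacent levels have σ = CV·μ with different μ, so their overlap
    ∫ min(f₁, f₂) differs slightly from the equal-σ convention's 1 − c
    (≈ 0.35 rather than 0.31 at CV 0.083, c 0.69). Computed by numeric
    integration; reported as a secondary check on the approximation.
    """
    if cv <= 0:
        raise DomainError(f"cv must be > 0, got {cv}")
    z = z_from_confidence(confidence)
    mu1 = 1.0
    mu2 = mu1 * (1.0 + 2.0 * cv * z)
    s1, s2 = cv * mu1, cv * mu2

    def min_density(x):
        f1 = math.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
        f2 = math.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
        return min(f1, f2)

    lo = mu1 - 8 * s1
    hi = mu2 + 8 * s2
    val, _ = quad(min_density, lo, hi, limit=200)
    return float(val)


@dataclass
class DiscriminationModel:
    """Level-ladder model: CV, dynamic range, confidence, and derived quantities."""

    cv: float = 0.083
    range_factor: float = 60.0
    confidence: float = 0.69
    z: float = field(init=False)
    spacing_ratio: float = field(init=False)
    n_levels: float = field(init=False)          # real-valued N
    n_levels_floor: int = field(init=False)
    n_levels_round: int = field(init=False)      # headline integer
    bits: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_levels = n_distinguishable(self.range_factor, self.cv, self.confidence)
        self.z = z_from_confidence(self.confidence)
        self.spacing_ratio = 1.0 + 2.0 * self.cv * self.z
        self.n_levels_floor = int(math.floor(self.n_levels)) if self.n_levels > 0 else 0
        self.n_levels_round = int(round(self.n_levels))
        self.bits = bits_from_levels(self.n_levels) if self.n_levels > 0 else float("-inf")

    def to_dict(self) -> dict:
        return {"cv": self.cv, "range_factor": self.range_factor,
                "confidence": self.confidence, "z": self.z,
                "spacing_ratio": self.spacing_ratio, "n_levels": self.n_levels,
                "n_levels_floor": self.n_levels_floor,
                "n_levels_round": self.n_levels_round, "bits": self.bits,
                "adjacent_overlap": adjacent_overlap(self.confidence)}


def build_level_ladder(min_volume: float, model: DiscriminationModel,
                       ) -> list[dict[str, float]]:
    """The ⌊N⌋ level means tiling [min, min·range] geometrically, with sd = CV·mean.

    Anchored so the first level's mean sits at the minimum observed volume;
    consecutive means have the constant ratio 1 + 2·CV·z, which makes the
    ladder uniform in width and spacing on a log scale.
    """
    if min_volume <= 0:
        raise DomainError(f"min_volume must be > 0, got {min_volume}")
    if model.n_levels < 1:
        raise DomainError(f"model yields N = {model.n_levels} < 1 level")
    means = min_volume * model.spacing_ratio ** np.arange(model.n_levels_floor)
    return [{"mean": float(m), "sd": float(model.cv * m)} for m in means]


def plot_level_ladder(ladder: list[dict[str, float]], ax=None):
    """Draw the Gaussian level ladder on a log-x axis (one curve per level)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    lo = ladder[0]["mean"] / 2
    hi = ladder[-1]["mean"] * 2
    x = np.geomspace(lo, hi, 2000)
    for level in ladder:
        mu, sd = level["mean"], level["sd"]
        ax.plot(x, np.exp(-0.5 * ((x - mu) / sd) ** 2), lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("spine head volume (µm³)")
    ax.set_ylabel("relative density")
    ax.set_title(f"{len(ladder)} distinguishable size levels")
    return ax
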