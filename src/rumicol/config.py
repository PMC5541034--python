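"""Configuration objects for the synthetic experiment generator.

The default configuration mirrors a 2 x 2 factorial fermenter experiment
(two forages x two additive levels, four replicate vessels per treatment,
each vessel seeded from one of four inoculum donors) sampled repeatedly
over a feeding cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ConfigError",
    "PlantedBlock",
    "FactorEffect",
    "CovariateCoupling",
    "SpectralEffect",
    "ColonizationCurve",
    "SimulationConfig",
    "DEFAULT_COLONIZATION_ANCHORS",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class PlantedBlock:
    """A block of taxa sharing latent correlation.

    ``rho`` is the correlation magnitude (0 <= rho < 1).  For a positive
    block all within-block pairs correlate at +rho.  For a negative block
    the taxa are given alternating latent signs so the implied correlation
    between pairs of opposite sign is -rho; this keeps the covariance
    positive semi-definite for any block size (equi-negative correlation
    would not be).
    """

    taxa: tuple[int, ...]
    rho: float
    sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(int(t) for t in self.taxa))
        if not -1 < self.rho < 1:
            raise ConfigError("planted_blocks.rho", f"|rho| must be < 1, got {self.rho}")
        if self.sign not in (-1, 1):
            raise ConfigError("planted_blocks.sign", f"sign must be +1 or -1, got {self.sign}")
        if len(self.taxa) < 2:
            raise ConfigError("planted_blocks.taxa", "a block needs at least two taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ConfigError("planted_blocks.taxa", "duplicate taxon index in block")

    def latent_signs(self) -> np.ndarray:
        """Per-taxon sign vector: all +1 for positive blocks, alternating otherwise."""
        k = len(self.taxa)
        if self.sign > 0:
            return np.ones(k)
        return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(k)])

    def edge_signs(self) -> dict[tuple[int, int], int]:
        """Ground-truth sign for every within-block taxon pair."""
        v = self.latent_signs()
        out: dict[tuple[int, int], int] = {}
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                a, b = sorted((self.taxa[i], self.taxa[j]))
                out[(a, b)] = int(np.sign(v[i] * v[j]))
        return out


@dataclass(frozen=True)
class FactorEffect:
    """A log-scale shift applied to designated taxa for one factor level.

    ``times`` restricts the effect to a subset of time points (hours);
    ``None`` applies it throughout.
    """

    factor: str
    level: str
    taxa: tuple[int, ...]
    log_fold: float
    times: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(int(t) for t in self.taxa))
        if self.times is not None:
            object.__setattr__(self, "times", tuple(float(t) for t in self.times))


@dataclass(frozen=True)
class CovariateCoupling:
    """Linear coupling of a fermentation covariate to one latent taxon."""

    covariate: str
    taxon: int
    weight: float


@dataclass(frozen=True)
class SpectralEffect:
    """Additive change to one Gaussian peak amplitude for a factor level."""

    factor: str
    level: str
    peak_wavenumber: float
    delta_amplitude: float
    times: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.times is not None:
            object.__setattr__(self, "times", tuple(float(t) for t in self.times))


# Default per-forage anchor fractions of residue nitrogen that is microbial,
# by hours after feeding.  Both forages converge by the end of the cycle.
DEFAULT_COLONIZATION_ANCHORS: dict[str, dict[float, float]] = {
    "GRA": {0.0: 0.0, 2.0: 0.16, 4.0: 0.28, 8.0: 0.42, 48.0: 0.61},
    "HAY": {0.0: 0.0, 2.0: 0.09, 4.0: 0.14, 8.0: 0.17, 48.0: 0.61},
}


class ColonizationCurve:
    """Monotone microbial-fraction curve m(t), 0 <= m <= 1.

    Two families are supported:

    * ``anchors`` -- shape-preserving (PCHIP) interpolation through the
      configured (t, fraction) anchors; exact at anchors, monotone between
      them.  This is the default so that configured fractions are
      reproduced exactly by the tracer round trip.
    * ``logistic`` -- scaled logistic ``m_max * (L(t) - L(0)) / (1 - L(0))``
      with ``L(t) = 1 / (1 + exp(-rate * (t - lag)))``, anchored to 0 at
      t = 0.
    """

    def __init__(self, anchors: Mapping[float, float] | None = None, *,
                 m_max: float | None = None, rate: float | None = None,
                 lag: float | None = None):
        if anchors is not None:
            ts = np.array(sorted(float(t) for t in anchors))
            ms = np.array([float(anchors[t]) for t in sorted(anchors)])
            if np.any(np.diff(ms) < 0):
                raise ConfigError("colonization_params", "anchor fractions must be nondecreasing")
            if np.any((ms < 0) | (ms > 1)):
                raise ConfigError("colonization_params", "anchor fractions must be in [0, 1]")
            self.kind = "anchors"
            self._ts, self._ms = ts, ms
            self._interp = PchipInterpolator(ts, ms, extrapolate=False)
        else:
            if m_max is None or rate is None or lag is None:
                raise ConfigError("colonization_params",
                                  "either anchors or (m_max, rate, lag) required")
            if not 0 <= m_max <= 1:
                raise ConfigError("colonization_params", "m_max must be in [0, 1]")
            self.kind = "logistic"
            self._m_max, self._rate, self._lag = float(m_max), float(rate), float(lag)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "anchors":
            out = self._interp(np.clip(t, self._ts[0], self._ts[-1]))
            return np.clip(out, 0.0, 1.0)
        L = 1.0 / (1.0 + np.exp(-self._rate * (t - self._lag)))
        L0 = 1.0 / (1.0 + np.exp(self._rate * self._lag))
        return self._m_max * (L - L0) / (1.0 - L0)


def _default_curves() -> dict[str, ColonizationCurve]:
    return {f: ColonizationCurve(a) for f, a in DEFAULT_COLONIZATION_ANCHORS.items()}


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    Defaults reproduce the reference design: 2 forages x 2 additive levels
    x 4 replicate vessels, sampled at 0/2/4/8/24/48 h, two community
    fractions per vessel-time, read depth at least 11265.
    """

    n_replicates: int = 4
    time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 24.0, 48.0)
    n_taxa: int = 120
    depth_range: tuple[int, int] = (11265, 30000)
    planted_blocks: tuple[PlantedBlock, ...] = ()
    colonization_params: dict[str, ColonizationCurve] = field(default_factory=_default_curves)
    effect_sizes: tuple[FactorEffect, ...] = ()
    noise_sd: float = 0.6
    seed: int = 0

    forages: tuple[str, ...] = ("GRA", "HAY")
    vitamin_e_levels: tuple[str, ...] = ("-", "+")
    fractions: tuple[str, ...] = ("SAB", "LAB")
    baseline_sd: float = 1.5
    covariate_couplings: tuple[CovariateCoupling, ...] = ()
    covariate_noise_sd: float = 0.05
    spectral_effects: tuple[SpectralEffect, ...] = ()
    spectral_noise_sd: float = 0.001

    def __post_init__(self):
        self.time_points_h = tuple(float(t) for t in self.time_points_h)
        self.depth_range = (int(self.depth_range[0]), int(self.depth_range[1]))
        self.planted_blocks = tuple(self.planted_blocks)
        self.effect_sizes = tuple(self.effect_sizes)
        self.covariate_couplings = tuple(self.covariate_couplings)
        self.spectral_effects = tuple(self.spectral_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates", "must be >= 1")
        ts = np.asarray(self.time_points_h)
        if len(ts) < 1 or np.any(np.diff(ts) <= 0):
            raise ConfigError("time_points_h", "time points must be strictly increasing")
        lo, hi = self.depth_range
        if lo < 1:
            raise ConfigError("depth_range", "minimum depth must be >= 1")
        if hi < lo:
            raise ConfigError("depth_range", f"max {hi} < min {lo}")
        if self.n_taxa < 1:
            raise ConfigError("n_taxa", "must be >= 1")
        for blk in self.planted_blocks:
            if max(blk.taxa) >= self.n_taxa:
                raise ConfigError(
                    "planted_blocks",
                    f"taxon index {max(blk.taxa)} out of range for n_taxa={self.n_taxa}")
        for eff in self.effect_sizes:
            if eff.taxa and max(eff.taxa) >= self.n_taxa:
                raise ConfigError(
                    "effect_sizes",
                    f"taxon index {max(eff.taxa)} out of range for n_taxa={self.n_taxa}")
        for f in self.forages:
            if f not in self.colonization_params:
                raise ConfigError("colonization_params", f"no curve for forage {f!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd", "must be >= 0")

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "planted_blocks" in d:
            d["planted_blocks"] = tuple(
                b if isinstance(b, PlantedBlock) else PlantedBlock(**b)
                for b in d["planted_blocks"])
        if "effect_sizes" in d:
            d["effect_sizes"] = tuple(
                e if isinstance(e, FactorEffect) else FactorEffect(**e)
                for e in d["effect_sizes"])
        if "covariate_couplings" in d:
            d["covariate_couplings"] = tuple(
                c if isinstance(c, CovariateCoupling) else CovariateCoupling(**c)
                for c in d["covariate_couplings"])
        if "spectral_effects" in d:
            d["spectral_effects"] = tuple(
                s if isinstance(s, SpectralEffect) else SpectralEffect(**s)
                for s in d["spectral_effects"])
        if "colonization_params" in d:
            curves = {}
            for forage, spec in d["colonization_params"].items():
                if isinstance(spec, ColonizationCurve):
                    curves[forage] = spec
                elif "anchors" in spec:
                    curves[forage] = ColonizationCurve(
                        {float(k): float(v) for k, v in spec["anchors"].items()})
                else:
                    curves[forage] = ColonizationCurve(
                        m_max=spec["m_max"], rate=spec["rate"], lag=spec["lag"])
            d["colonization_params"] = curves
        for key in ("time_points_h", "depth_range", "forages", "vitamin_e_levels", "fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
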