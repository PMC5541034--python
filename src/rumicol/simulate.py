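"""Synthetic experiment generator.

Produces count tables, tracer enrichments, fermentation covariates and
infrared spectra with the statistical structure the downstream analyses
assume: a 2 x 2 factorial with repeated measures over a feeding cycle,
compositional counts with planted latent correlation blocks, monotone
colonization kinetics, and covarying fermentation/spectral signals.

Counts follow a logistic-normal multinomial: latent per-taxon
log-abundances are multivariate normal with a covariance holding the
planted blocks, passed through a softmax and sampled multinomially at a
per-sample read depth.  All randomness derives from the config seed; a
distinct child stream per operation keeps the outputs independent yet
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .community import CountTable
from .tracer import EnrichmentRecord

__all__ = [
    "SyntheticTruth",
    "simulate_counts",
    "simulate_enrichment",
    "simulate_covariates",
    "simulate_spectra",
]

# stream keys so each simulate_* op gets an independent child generator
_STREAM = {"counts": 1, "enrichment": 2, "covariates": 3, "spectra": 4}


def _rng(config: SimulationConfig, op: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[op], int(config.seed)])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment, for recovery tests."""

    planted_edges: dict[tuple[int, int], int]
    true_m: dict[str, dict[float, float]]
    true_effects: dict[str, dict[int, float]]
    taxa: list[str] = field(default_factory=list)
    latents: pd.DataFrame | None = None  # samples x taxa latent log-abundances

    def __post_init__(self):
        n = len(self.taxa)
        for (a, b) in self.planted_edges:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"planted edge ({a},{b}) references missing taxon")
        for forage, curve in self.true_m.items():
            vals = [curve[t] for t in sorted(curve)]
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"m(t) out of [0,1] for {forage}")
            if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError(f"m(t) not nondecreasing for {forage}")

    def planted_edge_labels(self) -> dict[tuple[str, str], int]:
        """Planted edges keyed by taxon label instead of index."""
        return {(self.taxa[a], self.taxa[b]): s
                for (a, b), s in self.planted_edges.items()}


def _taxon_labels(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"g__Taxon{idx:0{width}d}" for idx in range(n)]


def _latent_covariance(config: SimulationConfig) -> np.ndarray:
    """Correlation matrix with planted blocks, scaled by noise_sd^2."""
    C = np.eye(config.n_taxa)
    for blk in config.planted_blocks:
        idx = np.array(blk.taxa)
        v = blk.latent_signs()
        # C_block = (1-rho) I + rho v v': PSD for 0 <= rho < 1
        block = (1 - blk.rho) * np.eye(len(idx)) + blk.rho * np.outer(v, v)
        C[np.ix_(idx, idx)] = block
    return (config.noise_sd ** 2) * C


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for forage in config.forages:
        for vit in config.vitamin_e_levels:
            for rep in range(1, config.n_replicates + 1):
                vessel = f"{forage}{vit}r{rep}"
                donor = f"A{rep}"
                for t in config.time_points_h:
                    for frac in config.fractions:
                        sid = f"{vessel}.t{t:g}h.{frac}"
                        rows.append({"sample": sid, "forage": forage,
                                     "vitamin_e": vit, "time_h": t,
                                     "vessel": vessel, "donor": donor,
                                     "fraction": frac})
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(config: SimulationConfig
                    ) -> tuple[CountTable, pd.DataFrame, SyntheticTruth]:
    """Draw a full count table for the factorial repeated-measures design.

    Returns the count table, a sample metadata frame (forage, vitamin_e,
    time_h, vessel, donor, fraction) and the ground truth (planted edges,
    configured colonization curves, applied effects, latent matrix).
    """
    config.validate()
    rng = _rng(config, "counts")
    meta = _sample_frame(config)
    n_samples = len(meta)
    n_taxa = config.n_taxa

    base_mean = rng.normal(0.0, config.baseline_sd, size=n_taxa)
    cov = _latent_covariance(config)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_taxa))
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T

    mean_shift = np.zeros((n_samples, n_taxa))
    applied: dict[str, dict[int, float]] = {}
    for eff in config.effect_sizes:
        col = meta[eff.factor].astype(str).values
        mask = col == str(eff.level)
        if eff.times is not None:
            mask &= meta["time_h"].isin(eff.times).values
        for tx in eff.taxa:
            mean_shift[mask, tx] += eff.log_fold
            applied.setdefault(f"{eff.factor}={eff.level}", {})
            applied[f"{eff.factor}={eff.level}"][tx] = \
                applied[f"{eff.factor}={eff.level}"].get(tx, 0.0) + eff.log_fold

    latent = base_mean[None, :] + mean_shift + z
    # softmax per sample
    shifted = latent - latent.max(axis=1, keepdims=True)
    p = np.exp(shifted)
    p /= p.sum(axis=1, keepdims=True)

    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depths[i], p[i])

    taxa = _taxon_labels(n_taxa)
    table = CountTable(pd.DataFrame(counts, index=meta.index, columns=taxa),
                       rank="genus")

    planted: dict[tuple[int, int], int] = {}
    for blk in config.planted_blocks:
        planted.update(blk.edge_signs())
    true_m = {
        forage: {t: float(curve(t)) for t in config.time_points_h}
        for forage, curve in config.colonization_params.items()
        if forage in config.forages
    }
    truth = SyntheticTruth(
        planted_edges=planted,
        true_m=true_m,
        true_effects=applied,
        taxa=taxa,
        latents=pd.DataFrame(latent, index=meta.index, columns=taxa),
    )
    return table, meta, truth


def simulate_enrichment(config: SimulationConfig,
                        sab_enrichment: float = 0.5,
                        nh3_enrichment: float = 2.0,
                        noise_sd: float = 0.0) -> list[EnrichmentRecord]:
    """Tracer enrichments per vessel x time consistent with the m(t) curves.

    residue_e(t) = m(t) * sab_enrichment + Gaussian noise, truncated at 0,
    so the tracer module's ratio recovers m(t) exactly at zero noise.  The
    implied ammonia-derived fraction is sab_enrichment / nh3_enrichment.
    """
    if sab_enrichment <= 0:
        raise ValueError(f"sab_enrichment must be > 0, got {sab_enrichment}")
    if nh3_enrichment <= 0:
        raise ValueError(f"nh3_enrichment must be > 0, got {nh3_enrichment}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    config.validate()
    rng = _rng(config, "enrichment")
    records = []
    for forage in config.forages:
        curve = config.colonization_params[forage]
        for vit in config.vitamin_e_levels:
            for rep in range(1, config.n_replicates + 1):
                vessel = f"{forage}{vit}r{rep}"
                for t in config.time_points_h:
                    m = float(curve(t))
                    resid = m * sab_enrichment
                    if noise_sd > 0:
                        resid += rng.normal(0.0, noise_sd)
                    records.append(EnrichmentRecord(
                        vessel=vessel, time_h=t,
                        residue_e=max(resid, 0.0),
                        sab_e=sab_enrichment,
                        nh3_e=nh3_enrichment))
    return records


# baseline fermentation curves: products peak early, pH dips reciprocally
_COVARIATE_BASE = {
    "ammonia_mm": (8.0, 12.0),   # (baseline, peak amplitude)
    "lactate_mm": (1.0, 6.0),
    "vfa_mm": (40.0, 25.0),
}
_PEAK_TIME_H = 3.0


def _pulse(t: np.ndarray) -> np.ndarray:
    """Unit pulse peaking at _PEAK_TIME_H, zero at t = 0."""
    x = np.asarray(t, dtype=float) / _PEAK_TIME_H
    return x * np.exp(1.0 - x)


def simulate_covariates(config: SimulationConfig,
                        truth: SyntheticTruth) -> pd.DataFrame:
    """Fermentation covariates per sample (ammonia, lactate, VFA, pH).

    Each covariate is its baseline time curve plus configured linear
    couplings to latent taxa plus Gaussian noise.  pH moves opposite to
    the fermentation pulse.
    """
    if truth.latents is None:
        raise ValueError("truth must carry the latent matrix from simulate_counts")
    rng = _rng(config, "covariates")
    meta_t = np.array([float(s.split(".t")[1].split("h")[0])
                       for s in truth.latents.index])
    pulse = _pulse(meta_t)
    out = pd.DataFrame(index=truth.latents.index)
    for name, (base, amp) in _COVARIATE_BASE.items():
        out[name] = base + amp * pulse
    out["ph"] = 6.9 - 0.45 * pulse

    lat = truth.latents.values
    for c in config.covariate_couplings:
        if c.covariate not in out.columns:
            raise ConfigError("covariate_couplings",
                              f"unknown covariate {c.covariate!r}")
        centred = lat[:, c.taxon] - lat[:, c.taxon].mean()
        out[c.covariate] = out[c.covariate] + c.weight * centred
    if config.covariate_noise_sd > 0:
        out += rng.normal(0.0, config.covariate_noise_sd, size=out.shape)
    return out


# fixed spectral landscape: broad baseline humps + sharp peaks (cm^-1)
_BASELINE_HUMPS = ((3400.0, 500.0, 0.15), (1600.0, 700.0, 0.10))
_PEAKS = (
    (2920.0, 30.0, 0.20),   # C-H stretch
    (1650.0, 25.0, 0.50),   # amide I
    (1540.0, 20.0, 0.30),   # amide II
    (1050.0, 40.0, 0.60),   # carbohydrate C-O
)
_COLONIZATION_PEAK = 1650.0   # amplitude grows with microbial fraction
_CARB_PEAK = 1050.0           # amplitude shrinks as feed is degraded


def default_wavenumbers(step: float = 2.0) -> np.ndarray:
    """Descending acquisition grid, 4000 -> 600 cm^-1."""
    return np.arange(4000.0, 600.0 - step / 2, -step)


def _gauss(wn: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wn - centre) / width) ** 2)


def simulate_spectra(config: SimulationConfig, truth: SyntheticTruth,
                     step: float = 2.0):
    """Residue spectra per vessel x time on the fixed descending grid.

    Each spectrum = smooth baseline + Gaussian peaks whose amplitudes
    carry treatment and colonization-time effects + Gaussian noise.
    Returns ``(SpectrumSet, metadata)``; metadata rows align with the
    spectrum columns.
    """
    from .metabolome import SpectrumSet  # local import, avoids cycle

    config.validate()
    rng = _rng(config, "spectra")
    wn = default_wavenumbers(step)
    baseline = np.zeros_like(wn)
    for centre, width, amp in _BASELINE_HUMPS:
        baseline += amp * _gauss(wn, centre, width)

    rows = []
    cols = []
    names = []
    for forage in config.forages:
        curve = config.colonization_params[forage]
        for vit in config.vitamin_e_levels:
            for rep in range(1, config.n_replicates + 1):
                vessel = f"{forage}{vit}r{rep}"
                for t in config.time_points_h:
                    m = float(curve(t))
                    amps = {c: a for c, _w, a in _PEAKS}
                    amps[_COLONIZATION_PEAK] *= (1.0 + m)
                    amps[_CARB_PEAK] *= (1.0 - 0.5 * m)
                    for eff in config.spectral_effects:
                        match = (
                            (eff.factor == "forage" and eff.level == forage)
                            or (eff.factor == "vitamin_e" and eff.level == vit))
                        if match and (eff.times is None or t in eff.times):
                            amps[eff.peak_wavenumber] = \
                                amps.get(eff.peak_wavenumber, 0.0) + eff.delta_amplitude
                    spec = baseline.copy()
                    widths = {c: w for c, w, _a in _PEAKS}
                    for centre, amp in amps.items():
                        spec += amp * _gauss(wn, centre, widths.get(centre, 25.0))
                    if config.spectral_noise_sd > 0:
                        spec = spec + rng.normal(0.0, config.spectral_noise_sd,
                                                 size=spec.shape)
                    sid = f"{vessel}.t{t:g}h"
                    cols.append(spec)
                    names.append(sid)
                    rows.append({"sample": sid, "forage": forage,
                                 "vitamin_e": vit, "time_h": t,
                                 "vessel": vessel, "donor": f"A{rep}"})
    values = np.column_stack(cols)
    meta = pd.DataFrame(rows).set_index("sample")
    return SpectrumSet(wavenumbers=wn, values=values, sample_ids=names,
                       fraction="plant_residue", provenance=("raw",)), meta
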