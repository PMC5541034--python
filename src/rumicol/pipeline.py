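"""End-to-end orchestration: simulate or load, analyse, write artifacts.

Every output file carries header lines recording the package version,
a hash of the run configuration, and the seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CountTable, bray_curtis, diversity, rarefy, upgma
from .config import ConfigError, SimulationConfig
from .metabolome import SpectrumSet, normalize, savgol_first_derivative, spectra_permanova
from .multivariate import DesignMatrix, cca, env_significance, pcoa, permanova, stratum_effect
from .network import export_graphml, network_trajectory
from .simulate import simulate_counts, simulate_covariates, simulate_enrichment, simulate_spectra
from .tracer import colonization_profile, read_enrichment_tsv

__all__ = ["RunConfig", "PipelineError", "validate_inputs", "run_pipeline"]

logger = logging.getLogger("rumicol")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Inputs (paths or a simulate block), analysis knobs, output dir."""

    output_dir: str
    inputs: dict | None = None           # counts/metadata/enrichment/covariates/spectra
    simulate: SimulationConfig | None = None
    n_perm: int = 999
    seed: int | None = None
    rho_threshold: float = 0.7
    alpha: float = 0.05
    prevalence: float = 0.75
    terms: tuple[str, ...] = ("forage", "vitamin_e", "time_h",
                              "forage:vitamin_e", "forage:time_h",
                              "vitamin_e:time_h", "forage:vitamin_e:time_h",
                              "donor")
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("inputs/simulate",
                              "exactly one of input paths or a simulate block is required")
        if self.simulate is not None and self.seed is None:
            self.seed = self.simulate.seed
        if self.seed is None:
            raise ConfigError("seed", "a seed is mandatory for permutation tests")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimulationConfig.from_dict(kwargs["simulate"])
        if "terms" in kwargs:
            kwargs["terms"] = tuple(kwargs["terms"])
        kwargs["raw"] = raw
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = dict(self.raw) if self.raw else {
            "seed": self.seed, "n_perm": self.n_perm,
            "rho_threshold": self.rho_threshold, "alpha": self.alpha,
            "prevalence": self.prevalence, "terms": list(self.terms),
            "simulate": self.simulate is not None,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header(cfg: RunConfig) -> list[str]:
    return [f"rumicol {__version__}",
            f"config_hash={cfg.config_hash()}",
            f"seed={cfg.seed}"]


def validate_inputs(counts: CountTable, metadata: pd.DataFrame,
                    enrichment=None, covariates: pd.DataFrame | None = None,
                    spectra: SpectrumSet | None = None) -> list[dict]:
    """Cross-table consistency checks; returns a machine-readable issue list."""
    issues: list[dict] = []
    meta_ids = set(metadata.index)
    for sid in counts.samples:
        if sid not in meta_ids:
            issues.append({"stage": "metadata", "kind": "missing_sample",
                           "detail": f"sample {sid!r} absent from metadata"})
    arr = counts.counts
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        issues.append({"stage": "counts", "kind": "negative_count",
                       "detail": f"negative count at sample {counts.samples[i]!r}, "
                                 f"taxon {counts.taxa[j]!r}"})
    if enrichment is not None:
        for r in enrichment:
            for name in ("residue_e", "sab_e", "nh3_e"):
                v = getattr(r, name)
                if v is not None and v < 0:
                    issues.append({"stage": "enrichment", "kind": "negative_enrichment",
                                   "detail": f"{name} < 0 for vessel {r.vessel!r} "
                                             f"at {r.time_h} h"})
    if covariates is not None:
        missing = [s for s in covariates.index if s not in meta_ids
                   and s not in set(counts.samples)]
        if not covariates.map(np.isfinite).all().all():
            issues.append({"stage": "covariates", "kind": "non_finite",
                           "detail": "covariate table contains non-finite values"})
    if spectra is not None:
        diffs = np.diff(spectra.wavenumbers)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            issues.append({"stage": "spectra", "kind": "grid",
                           "detail": "wavenumber grid not monotone"})
    return issues


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict of artifact paths.

    Stages: simulate/load -> validation -> tracer profile -> rarefaction
    and diversity -> Bray-Curtis/UPGMA/PCoA -> PERMANOVA (full model +
    per-time forage and additive strata) -> CCA + variable tests ->
    networks per forage x time -> FTIR chain -> summary.  Any stage error
    raises :class:`PipelineError` naming the stage; nothing is silently
    skipped.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(cfg)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "config_hash": cfg.config_hash(), "artifacts": {}}

    def emit(name: str, path: Path):
        summary["artifacts"][name] = str(path.relative_to(out))

    # -- stage: inputs ---------------------------------------------------
    try:
        if cfg.simulate is not None:
            table, meta, truth = simulate_counts(cfg.simulate)
            enrichment = simulate_enrichment(cfg.simulate, noise_sd=0.01)
            covariates = simulate_covariates(cfg.simulate, truth)
            spectra, spec_meta = simulate_spectra(cfg.simulate, truth)
            table.to_tsv(out / "counts.tsv", hdr)
            with open(out / "metadata.tsv", "w") as fh:
                for line in hdr:
                    fh.write(f"# {line}\n")
                meta.to_csv(fh, sep="\t")
            with open(out / "truth.json", "w") as fh:
                json.dump({
                    "planted_edges": [[a, b, s] for (a, b), s
                                      in sorted(truth.planted_edges.items())],
                    "true_m": truth.true_m,
                    "true_effects": truth.true_effects,
                }, fh, sort_keys=True, indent=1)
            emit("counts", out / "counts.tsv")
            emit("metadata", out / "metadata.tsv")
            emit("truth", out / "truth.json")
        else:
            paths = cfg.inputs
            table = CountTable.from_tsv(paths["counts"])
            meta = pd.read_csv(paths["metadata"], sep="\t", comment="#", index_col=0)
            enrichment = (read_enrichment_tsv(paths["enrichment"])
                          if paths.get("enrichment") else None)
            covariates = (pd.read_csv(paths["covariates"], sep="\t",
                                      comment="#", index_col=0)
                          if paths.get("covariates") else None)
            spectra = (SpectrumSet.from_csv(paths["spectra"])
                       if paths.get("spectra") else None)
            spec_meta = meta
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("inputs", str(e)) from e

    issues = validate_inputs(table, meta, enrichment, covariates, spectra)
    if issues:
        raise PipelineError("validation", json.dumps(issues[:5]))

    # -- stage: tracer ---------------------------------------------------
    if enrichment is not None:
        try:
            profile = colonization_profile(enrichment)
            with open(out / "colonization_profile.tsv", "w") as fh:
                for line in hdr:
                    fh.write(f"# {line}\n")
                fh.write(f"# sab_source={json.dumps(profile.sab_source, sort_keys=True)}\n")
                merged = profile.fractions.merge(
                    profile.rates, how="left",
                    left_on=["vessel", "time_h"], right_on=["vessel", "t_end"])
                merged.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            emit("colonization_profile", out / "colonization_profile.tsv")
        except Exception as e:
            raise PipelineError("tracer", str(e)) from e

    # -- stage: rarefaction + diversity ----------------------------------
    try:
        depth = int(table.totals().min())
        rare = rarefy(table, depth, seed=cfg.seed)
        div = diversity(rare)
        with open(out / "diversity.tsv", "w") as fh:
            for line in hdr + [f"rarefaction_depth={depth}",
                               "shannon_log_base=e", "simpson=gini"]:
                fh.write(f"# {line}\n")
            div.to_csv(fh, sep="\t", float_format="%.10g")
        emit("diversity", out / "diversity.tsv")
    except Exception as e:
        raise PipelineError("diversity", str(e)) from e

    # -- stage: beta diversity -------------------------------------------
    try:
        d = bray_curtis(rare, normalize=True)
        d.to_tsv(out / "bray_curtis.tsv", hdr)
        with open(out / "upgma.nwk", "w") as fh:
            fh.write(upgma(d) + "\n")
        coords, eigvals = pcoa(d)
        with open(out / "pcoa.tsv", "w") as fh:
            for line in hdr + ["eigenvalues=" +
                               ",".join(f"{v:.6g}" for v in eigvals)]:
                fh.write(f"# {line}\n")
            coords.to_csv(fh, sep="\t", float_format="%.10g")
        emit("bray_curtis", out / "bray_curtis.tsv")
        emit("upgma", out / "upgma.nwk")
        emit("pcoa", out / "pcoa.tsv")
    except Exception as e:
        raise PipelineError("beta", str(e)) from e

    # -- stage: permanova -------------------------------------------------
    try:
        terms = [t for t in cfg.terms
                 if all(p in meta.columns for p in t.split(":"))]
        design = DesignMatrix(meta.loc[d.ids], terms=terms)
        res = permanova(d, design, n_perm=cfg.n_perm, seed=cfg.seed)
        res.to_tsv(out / "permanova.tsv", hdr)
        emit("permanova", out / "permanova.tsv")
        strata_rows = []
        for factor in ("forage", "vitamin_e"):
            if factor not in meta.columns:
                continue
            for t in sorted(meta["time_h"].unique()):
                sub = meta["time_h"] == t
                if meta.loc[sub, factor].nunique() < 2 or sub.sum() < 4:
                    continue
                r = stratum_effect(d, meta, factor, {"time_h": t},
                                   n_perm=cfg.n_perm, seed=cfg.seed)
                row = r.table.loc[factor]
                strata_rows.append({"factor": factor, "time_h": t,
                                    "pseudo_F": row["pseudo_F"],
                                    "p_perm": row["p_perm"],
                                    "p_mc": row["p_mc"]})
        if strata_rows:
            with open(out / "permanova_strata.tsv", "w") as fh:
                for line in hdr:
                    fh.write(f"# {line}\n")
                pd.DataFrame(strata_rows).to_csv(fh, sep="\t", index=False,
                                                 float_format="%.10g")
            emit("permanova_strata", out / "permanova_strata.tsv")
    except Exception as e:
        raise PipelineError("permanova", str(e)) from e

    # -- stage: cca -------------------------------------------------------
    if covariates is not None:
        try:
            env = covariates.loc[rare.samples]
            ccares = cca(rare, env)
            envp = env_significance(rare, env, n_perm=cfg.n_perm, seed=cfg.seed)
            with open(out / "cca.tsv", "w") as fh:
                for line in hdr + [
                        f"total_inertia={ccares.total_inertia:.10g}",
                        f"constrained_inertia={ccares.constrained_inertia:.10g}",
                        "env_p=" + ",".join(f"{k}:{v:.4g}"
                                            for k, v in envp.items())]:
                    fh.write(f"# {line}\n")
                ccares.site_scores.to_csv(fh, sep="\t", float_format="%.10g")
            emit("cca", out / "cca.tsv")
        except Exception as e:
            raise PipelineError("cca", str(e)) from e

    # -- stage: networks --------------------------------------------------
    try:
        net_meta = meta.loc[table.samples]
        if "fraction" in net_meta.columns and (net_meta["fraction"] == "SAB").any():
            net_ids = list(net_meta.index[net_meta["fraction"] == "SAB"])
        else:
            net_ids = list(net_meta.index)
        sub = table.subset(samples=net_ids)
        traj, networks = network_trajectory(
            sub, meta, group_by="forage" if "forage" in meta.columns
            else meta.columns[0],
            min_prevalence=cfg.prevalence,
            rho_threshold=cfg.rho_threshold, alpha=cfg.alpha)
        with open(out / "network_metrics.tsv", "w") as fh:
            for line in hdr:
                fh.write(f"# {line}\n")
            traj.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        emit("network_metrics", out / "network_metrics.tsv")
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for label, net in networks.items():
            safe = label.replace("@", "_")
            with open(netdir / f"{safe}_edges.tsv", "w") as fh:
                for line in hdr:
                    fh.write(f"# {line}\n")
                net.edges.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            export_graphml(net, netdir / f"{safe}.graphml")
    except Exception as e:
        raise PipelineError("network", str(e)) from e

    # -- stage: ftir -------------------------------------------------------
    if spectra is not None:
        try:
            deriv = savgol_first_derivative(spectra)
            proc = normalize(deriv)
            proc.to_csv(out / "spectra_processed.csv", hdr)
            emit("spectra_processed", out / "spectra_processed.csv")
            fterms = [t for t in ("forage", "vitamin_e", "time_h")
                      if t in spec_meta.columns]
            fres = spectra_permanova(proc, spec_meta, terms=tuple(fterms),
                                     n_perm=cfg.n_perm, seed=cfg.seed)
            fres.to_tsv(out / "ftir_permanova.tsv", hdr)
            emit("ftir_permanova", out / "ftir_permanova.tsv")
        except Exception as e:
            raise PipelineError("ftir", str(e)) from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    logger.info("pipeline complete: %d artifacts in %s",
                len(summary["artifacts"]), out)
    return summary
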