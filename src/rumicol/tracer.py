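"""Heavy-nitrogen tracer partitioning of plant-residue nitrogen.

Ratios of atom% excess enrichments split residue N into microbial and
feed fractions and quantify how much microbial N came from the ammonia
pool.  Enrichments are excess above background; natural abundance is
assumed already subtracted upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentRecord",
    "ColonizationProfile",
    "microbial_n_fraction",
    "ammonia_derived_fraction",
    "colonization_profile",
    "phase_label",
    "read_enrichment_tsv",
    "write_enrichment_tsv",
]

# Colonization phase boundaries in hours after feeding.
PRIMARY_END_H = 2.0
SECONDARY_END_H = 8.0


@dataclass(frozen=True)
class EnrichmentRecord:
    """Atom% excess enrichment triplet for one vessel at one time point.

    ``sab_e`` or ``nh3_e`` may be None when that pool was measured only
    once per vessel (pooling is resolved by :func:`colonization_profile`).
    """

    vessel: str
    time_h: float
    residue_e: float
    sab_e: float | None = None
    nh3_e: float | None = None

    def __post_init__(self):
        for name in ("residue_e", "sab_e", "nh3_e"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class ColonizationProfile:
    """Per-time microbial fractions and per-interval colonization rates.

    ``fractions`` columns: vessel, time_h, microbial_fraction, clamped.
    ``rates`` columns: vessel, t_start, t_end, rate_per_h, phase.
    ``sab_source`` records whether per-time or single pooled SAB
    enrichment was used per vessel.
    """

    fractions: pd.DataFrame
    rates: pd.DataFrame
    sab_source: dict[str, str]


def microbial_n_fraction(residue_e: float, sab_e: float,
                         clamp: bool = False) -> float:
    """Fraction of residue N that is microbial: residue_e / sab_e.

    Values above 1 (measurement noise) are returned as-is with a warning
    unless ``clamp=True``.
    """
    if sab_e is None or sab_e <= 0:
        raise ValueError(f"SAB enrichment must be > 0, got {sab_e}")
    if residue_e < 0:
        raise ValueError(f"residue enrichment must be >= 0, got {residue_e}")
    frac = residue_e / sab_e
    if frac > 1.0:
        if clamp:
            return 1.0
        warnings.warn(f"microbial fraction {frac:.4g} exceeds 1; "
                      "returned unclamped", stacklevel=2)
    return frac


def ammonia_derived_fraction(sab_e: float, nh3_e: float) -> float:
    """Fraction of microbial N derived from the ammonia pool: sab_e / nh3_e."""
    if nh3_e is None or nh3_e <= 0:
        raise ValueError(f"ammonia enrichment must be > 0, got {nh3_e}")
    if sab_e < 0:
        raise ValueError(f"SAB enrichment must be >= 0, got {sab_e}")
    return sab_e / nh3_e


def phase_label(t_end: float) -> str:
    """Phase of the interval ending at ``t_end`` hours."""
    if t_end <= PRIMARY_END_H:
        return "primary"
    if t_end <= SECONDARY_END_H:
        return "secondary"
    return "tertiary"


def colonization_profile(records: Iterable[EnrichmentRecord],
                         clamp: bool = False) -> ColonizationProfile:
    """Microbial fractions per time point and interval rates per vessel.

    Per-time SAB enrichments are used when available at every time point
    of a vessel; otherwise the vessel's single measured SAB enrichment is
    applied to all of its time points (and which route was taken is
    recorded).  Interval rate = delta fraction / delta hours between
    consecutive time points.
    """
    records = list(records)
    if not records:
        raise ValueError("no enrichment records supplied")
    by_vessel: dict[str, list[EnrichmentRecord]] = {}
    for r in records:
        by_vessel.setdefault(r.vessel, []).append(r)

    frac_rows, rate_rows = [], []
    sab_source: dict[str, str] = {}
    for vessel, recs in by_vessel.items():
        recs = sorted(recs, key=lambda r: r.time_h)
        if len(recs) < 2:
            raise ValueError(f"vessel {vessel!r} has fewer than 2 time points")
        sabs = [r.sab_e for r in recs if r.sab_e is not None and r.sab_e > 0]
        if not sabs:
            raise ValueError(f"vessel {vessel!r} has no usable SAB enrichment")
        if all(r.sab_e is not None and r.sab_e > 0 for r in recs):
            sab_source[vessel] = "per-time"
            get_sab = {r.time_h: r.sab_e for r in recs}.__getitem__
        else:
            # pooled: one measured pellet applied to every time point
            if len(set(sabs)) > 1:
                warnings.warn(
                    f"vessel {vessel!r}: multiple SAB enrichments with gaps; "
                    "using their mean for missing time points")
            pooled = float(np.mean(sabs))
            sab_source[vessel] = "single-pooled"

            def get_sab(t, _p=pooled, _m={r.time_h: r.sab_e for r in recs}):
                v = _m.get(t)
                return v if v is not None and v > 0 else _p

        fracs = []
        for r in recs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = microbial_n_fraction(r.residue_e, get_sab(r.time_h),
                                         clamp=clamp)
            fracs.append(f)
            frac_rows.append({"vessel": vessel, "time_h": r.time_h,
                              "microbial_fraction": min(f, 1.0) if clamp else f,
                              "exceeds_one": f > 1.0})
        for (r0, f0), (r1, f1) in zip(zip(recs, fracs), zip(recs[1:], fracs[1:])):
            dt = r1.time_h - r0.time_h
            rate_rows.append({
                "vessel": vessel,
                "t_start": r0.time_h,
                "t_end": r1.time_h,
                "rate_per_h": (f1 - f0) / dt,
                "phase": phase_label(r1.time_h),
            })

    return ColonizationProfile(
        fractions=pd.DataFrame(frac_rows),
        rates=pd.DataFrame(rate_rows),
        sab_source=sab_source,
    )


# -- interchange ----------------------------------------------------------

def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path,
                         header_lines: list[str] | None = None) -> None:
    rows = [{"vessel": r.vessel, "time_h": r.time_h, "residue_e": r.residue_e,
             "sab_e": r.sab_e, "nh3_e": r.nh3_e} for r in records]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_enrichment_tsv(path) -> list[EnrichmentRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(EnrichmentRecord(
            vessel=str(row["vessel"]), time_h=float(row["time_h"]),
            residue_e=float(row["residue_e"]),
            sab_e=None if pd.isna(row.get("sab_e")) else float(row["sab_e"]),
            nh3_e=None if pd.isna(row.get("nh3_e")) else float(row["nh3_e"])))
    return out
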