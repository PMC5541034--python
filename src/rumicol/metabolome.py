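"""Infrared fingerprint preprocessing and multivariate group testing.

The processing chain mirrors routine chemometric practice: replicate
averaging, a first Savitzky-Golay derivative (13-point window, quadratic
fit) to flatten baselines, then per-spectrum standardisation.  Group
differences are tested by PERMANOVA on Euclidean distances between
processed spectra (derivatives take negative values, so Bray-Curtis is
not applicable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .community import DistanceMatrix
from .multivariate import DesignMatrix, PermanovaResult, permanova

__all__ = [
    "SpectrumSet",
    "average_replicates",
    "savgol_first_derivative",
    "normalize",
    "spectra_permanova",
]

_PROVENANCE_ORDER = ("raw", "averaged", "derivative", "normalized")


@dataclass
class SpectrumSet:
    """Absorbance spectra on one shared wavenumber grid.

    ``values`` is (n_points x n_samples); ``provenance`` records the
    processing states applied so far, in order (transitions only move
    forward through raw -> averaged -> derivative -> normalized).
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    fraction: str = "plant_residue"
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != len(wn):
            raise ValueError("values do not match wavenumber grid")
        if v.shape[1] != len(self.sample_ids):
            raise ValueError("values do not match sample ids")
        diffs = np.diff(wn)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectra contain non-finite values")
        order = [_PROVENANCE_ORDER.index(p) for p in self.provenance]
        if order != sorted(order):
            raise ValueError(f"provenance out of order: {self.provenance}")
        self.wavenumbers = wn
        self.values = v

    def _advance(self, state: str) -> tuple[str, ...]:
        if _PROVENANCE_ORDER.index(state) < _PROVENANCE_ORDER.index(self.provenance[-1]):
            raise ValueError(
                f"cannot apply {state!r} after {self.provenance[-1]!r}")
        return self.provenance + (state,)

    def to_csv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            pd.DataFrame(self.values, index=self.wavenumbers,
                         columns=self.sample_ids) \
                .rename_axis("wavenumber_cm-1").to_csv(fh)

    @classmethod
    def from_csv(cls, path, fraction: str = "plant_residue",
                 provenance: tuple[str, ...] = ("raw",)) -> "SpectrumSet":
        df = pd.read_csv(path, comment="#", index_col=0)
        return cls(wavenumbers=df.index.values.astype(float),
                   values=df.values, sample_ids=list(df.columns),
                   fraction=fraction, provenance=provenance)


def average_replicates(spectra: SpectrumSet, groups) -> SpectrumSet:
    """Pointwise mean spectrum per group.

    ``groups`` maps sample id -> group label (dict or Series).  Output
    columns are the group labels in sorted order.
    """
    mapping = dict(groups) if not isinstance(groups, dict) else groups
    missing = [s for s in spectra.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"no group for samples: {missing[:5]}")
    labels = sorted(set(mapping[s] for s in spectra.sample_ids))
    cols = []
    for lab in labels:
        idx = [i for i, s in enumerate(spectra.sample_ids) if mapping[s] == lab]
        cols.append(spectra.values[:, idx].mean(axis=1))
    return replace(spectra, values=np.column_stack(cols),
                   sample_ids=[str(lab) for lab in labels],
                   provenance=spectra._advance("averaged"))


def savgol_first_derivative(spectra: SpectrumSet, window: int = 13,
                            polyorder: int = 2,
                            grid_rtol: float = 1e-6) -> SpectrumSet:
    """First derivative by Savitzky-Golay local polynomial fitting.

    The derivative is with respect to wavenumber (per cm^-1), so a
    descending grid flips its sign relative to the index derivative.
    Edges use polynomial extrapolation of the boundary fits.  The grid
    must be uniform to within ``grid_rtol``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    n = len(spectra.wavenumbers)
    if window >= n:
        raise ValueError(f"window {window} >= spectrum length {n}")
    steps = np.diff(spectra.wavenumbers)
    step = steps.mean()
    if np.any(np.abs(steps - step) > abs(step) * grid_rtol):
        raise ValueError("wavenumber grid is not uniform")
    deriv = savgol_filter(spectra.values, window_length=window,
                          polyorder=polyorder, deriv=1,
                          delta=abs(step), axis=0, mode="interp")
    deriv *= np.sign(step)
    return replace(spectra, values=deriv,
                   provenance=spectra._advance("derivative"))


def normalize(spectra: SpectrumSet, offset: float = 0.0) -> SpectrumSet:
    """Per-spectrum standardisation to sd 1, mean ``offset``.

    The default centres at 0 (autoscaling); ``offset=1.0`` reproduces a
    literal mean-1 convention.  Distance-based tests are translation
    invariant, so the choice does not affect downstream statistics.
    Requires the derivative step to have been applied; zero-variance
    spectra raise.
    """
    if "derivative" not in spectra.provenance:
        raise ValueError("normalize expects derivative-processed spectra")
    v = spectra.values
    sd = v.std(axis=0, ddof=0)
    tol = np.maximum(np.abs(v).max(axis=0), 1.0) * 1e-12
    degenerate = sd <= tol
    if np.any(degenerate):
        bad = spectra.sample_ids[int(np.argmax(degenerate))]
        raise ValueError(f"spectrum {bad!r} has zero variance")
    out = (v - v.mean(axis=0)) / sd + offset
    return replace(spectra, values=out,
                   provenance=spectra._advance("normalized"))


def spectra_permanova(spectra: SpectrumSet, metadata: pd.DataFrame,
                      terms=("forage", "vitamin_e", "time_h"),
                      n_perm: int = 999, seed: int | None = None
                      ) -> PermanovaResult:
    """PERMANOVA of Euclidean distances between processed spectra."""
    meta = metadata.loc[spectra.sample_ids]
    v = spectra.values.T  # samples x points
    sq = (v ** 2).sum(axis=1)
    gram = v @ v.T
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0)
    dmat = np.sqrt(d2)
    np.fill_diagonal(dmat, 0.0)
    dmat = (dmat + dmat.T) / 2.0
    d = DistanceMatrix(list(spectra.sample_ids), dmat, metric="euclidean",
                       transform="processed")
    design = DesignMatrix(meta, terms=terms)
    return permanova(d, design, n_perm=n_perm, seed=seed)
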