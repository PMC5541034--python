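"""Distance-based multivariate statistics for the factorial design.

PERMANOVA partitions a Gower-centred distance matrix across the model
terms (forage, additive, time, interactions, inoculum donor), with
significance by permutation of residuals under the reduced model and a
moment-matched continuous ("Monte Carlo") approximation to the
permutation null.  Canonical correspondence analysis relates the
chi-square-standardised community table to fermentation covariates, with
per-variable permutation tests.  Principal-coordinates analysis is
provided for visualisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import CountTable, DistanceMatrix

__all__ = [
    "DesignMatrix",
    "PermanovaResult",
    "CcaResult",
    "permanova",
    "stratum_effect",
    "cca",
    "env_significance",
    "pcoa",
    "gower_center",
]

DEFAULT_TERMS = ("forage", "vitamin_e", "time_h",
                 "forage:vitamin_e", "forage:time_h", "vitamin_e:time_h",
                 "forage:vitamin_e:time_h", "donor")


class DesignMatrix:
    """Per-term dummy-coded model matrix built from sample metadata.

    Terms are factor names or colon-joined interactions
    (``"forage:time_h"``).  Main effects use treatment coding (first
    level dropped); interaction columns are products of the parent
    main-effect codings, as in a classical ANOVA model matrix.
    """

    def __init__(self, metadata: pd.DataFrame, terms=DEFAULT_TERMS):
        self.ids = list(metadata.index)
        self.terms = list(terms)
        n = len(self.ids)
        self._blocks: dict[str, np.ndarray] = {}
        main: dict[str, np.ndarray] = {}
        for term in self.terms:
            parts = term.split(":")
            for p in parts:
                if p not in metadata.columns:
                    raise ValueError(f"factor {p!r} not in metadata")
                if p not in main:
                    main[p] = self._code(metadata[p])
            if len(parts) == 1:
                block = main[parts[0]]
            else:
                block = main[parts[0]]
                for p in parts[1:]:
                    block = np.einsum("ni,nj->nij", block, main[p]) \
                        .reshape(n, -1)
            self._blocks[term] = block

    @staticmethod
    def _code(col: pd.Series) -> np.ndarray:
        levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {col.name!r} has a single level")
        out = np.zeros((len(col), len(levels) - 1))
        vals = col.astype(str).values
        for j, lev in enumerate(levels[1:]):
            out[:, j] = vals == lev
        return out

    def block(self, term: str) -> np.ndarray:
        return self._blocks[term]

    def matrix(self, terms=None) -> np.ndarray:
        """Intercept plus the requested term blocks, in declared order."""
        terms = self.terms if terms is None else terms
        cols = [np.ones((len(self.ids), 1))]
        cols.extend(self._blocks[t] for t in terms)
        return np.hstack(cols)


@dataclass
class PermanovaResult:
    """Distance-based ANOVA table plus permutation diagnostics."""

    table: pd.DataFrame            # index: term; df, SS, pseudo_F, p_perm, p_mc
    n_permutations: int
    total_ss: float
    degenerate: bool = False       # SS_total == 0 (all samples identical)
    permuted_f: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tsv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.rename_axis("term").to_csv(fh, sep="\t")


def gower_center(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix G = J(-0.5 D^2)J."""
    m = d.matrix if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    a = -0.5 * m ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(x) and its rank (SVD-based, so aliased
    dummy columns are handled gracefully)."""
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    tol = (s[0] * max(x.shape) * np.finfo(float).eps) if s.size else 0.0
    rank = int((s > tol).sum())
    u = u[:, :rank]
    return u @ u.T, rank


def permanova(d: DistanceMatrix, design: DesignMatrix, n_perm: int = 999,
              seed: int | None = None, enumerate_all: bool = False,
              permute_within: pd.Series | None = None) -> PermanovaResult:
    """Multi-term PERMANOVA on a distance matrix.

    Sums of squares are sequential in the declared term order (in the
    balanced factorial they coincide with marginal SS).  The p-value for
    each term permutes the residuals of the reduced model that excludes
    that term, then recomputes the term's marginal pseudo-F.  ``p_mc`` is
    a Pearson-III tail probability moment-matched (mean/variance/skew) to
    the permutation null, giving a continuous analogue of the permutation
    p.  ``enumerate_all=True`` replaces random sampling by the full
    permutation group (only sensible for small n).  ``permute_within``
    restricts permutations to exchanges inside the given blocking factor
    (e.g. inoculum donor).
    """
    if list(design.ids) != list(d.ids):
        raise ValueError("distance matrix and design are not sample-aligned")
    if n_perm < 99 and not enumerate_all:
        raise ValueError("n_perm must be >= 99")
    n = d.n
    G = gower_center(d)
    ss_total = float(np.trace(G))
    if ss_total <= 1e-12:
        tbl = pd.DataFrame({"df": [], "SS": [], "pseudo_F": [],
                            "p_perm": [], "p_mc": []})
        return PermanovaResult(tbl, 0, ss_total, degenerate=True)

    terms = design.terms
    # sequential SS via nested hat matrices
    hats, ranks = [], []
    for k in range(len(terms) + 1):
        h, r = _hat(design.matrix(terms[:k]))
        hats.append(h)
        ranks.append(r)
    h_full, rank_full = hats[-1], ranks[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("residual degrees of freedom is zero; drop terms")
    seq_ss, dfs = {}, {}
    for k, term in enumerate(terms):
        dfk = ranks[k + 1] - ranks[k]
        if dfk == 0:
            raise ValueError(f"term {term!r} is aliased with earlier terms")
        seq_ss[term] = float(np.sum(hats[k + 1] * G) - np.sum(hats[k] * G))
        dfs[term] = dfk
    ss_res = ss_total - float(np.sum(h_full * G))
    ms_res = ss_res / df_res

    # permutations
    if enumerate_all:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        if permute_within is not None:
            blocks = [np.flatnonzero(permute_within.values == b)
                      for b in pd.unique(permute_within.values)]

            def draw():
                p = np.arange(n)
                for idx in blocks:
                    p[idx] = idx[rng.permutation(len(idx))]
                return p
        else:
            def draw():
                return rng.permutation(n)
        perms = [draw() for _ in range(n_perm)]
        n_used = n_perm

    rows = []
    permuted_f: dict[str, np.ndarray] = {}
    for term in terms:
        other = [t for t in terms if t != term]
        h_red, _ = _hat(design.matrix(other))
        df_t = dfs[term]
        # marginal F for the permutation comparison (== sequential F in
        # the balanced design)
        ss_t_marg = float(np.sum(h_full * G) - np.sum(h_red * G))
        f_obs = (ss_t_marg / df_t) / ms_res
        resid_op = np.eye(n) - h_red
        R = resid_op @ G @ resid_op
        fitted = h_red @ G @ h_red
        fs = np.empty(n_used)
        for i, p in enumerate(perms):
            Gp = fitted + R[np.ix_(p, p)]
            tot = float(np.trace(Gp))
            ss_t = float(np.sum(h_full * Gp) - np.sum(h_red * Gp))
            ss_r = tot - float(np.sum(h_full * Gp))
            fs[i] = (ss_t / df_t) / (ss_r / df_res) if ss_r > 0 else np.inf
        p_perm = (np.sum(fs >= f_obs - 1e-12) + 1.0) / (n_used + 1.0)
        p_mc = _pearson3_tail(fs, f_obs)
        permuted_f[term] = fs
        rows.append({"term": term, "df": df_t, "SS": seq_ss[term],
                     "pseudo_F": f_obs, "p_perm": p_perm, "p_mc": p_mc})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "pseudo_F": np.nan, "p_perm": np.nan, "p_mc": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "pseudo_F": np.nan, "p_perm": np.nan, "p_mc": np.nan})
    tbl = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(tbl, n_used, ss_total, permuted_f=permuted_f)


def _pearson3_tail(sample: np.ndarray, observed: float) -> float:
    """Upper-tail probability of ``observed`` under a Pearson type III
    law moment-matched to the permutation sample."""
    finite = sample[np.isfinite(sample)]
    if len(finite) < 10:
        return np.nan
    m, s = finite.mean(), finite.std(ddof=1)
    if s <= 0:
        return 1.0 if observed <= m else 0.0
    g = float(stats.skew(finite, bias=False))
    if abs(g) < 1e-8:
        p = stats.norm.sf(observed, loc=m, scale=s)
    else:
        p = stats.pearson3.sf(observed, skew=g, loc=m, scale=s)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def stratum_effect(d: DistanceMatrix, metadata: pd.DataFrame, factor: str,
                   stratum: pd.Series | dict | None = None,
                   n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA on a subset of samples.

    ``stratum`` selects the subset: a boolean mask aligned to metadata, a
    ``{column: value}`` dict, or None for the whole dataset.
    """
    meta = metadata.loc[d.ids]
    if stratum is None:
        mask = pd.Series(True, index=meta.index)
    elif isinstance(stratum, dict):
        mask = pd.Series(True, index=meta.index)
        for col, val in stratum.items():
            mask &= meta[col] == val
    else:
        mask = stratum.reindex(meta.index).fillna(False).astype(bool)
    ids = list(meta.index[mask])
    sub_meta = meta.loc[ids]
    if sub_meta[factor].nunique() < 2:
        raise ValueError(f"stratum has fewer than 2 levels of {factor!r}")
    sub_d = d.subset(ids)
    design = DesignMatrix(sub_meta, terms=[factor])
    return permanova(sub_d, design, n_perm=n_perm, seed=seed)


# -- correspondence analysis ---------------------------------------------

@dataclass
class CcaResult:
    """Constrained correspondence analysis output."""

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame       # weighted averages of taxon scores
    lc_scores: pd.DataFrame         # linear-combination (fitted) site scores
    taxon_scores: pd.DataFrame
    biplot_scores: pd.DataFrame     # env variable arrows
    total_inertia: float
    constrained_inertia: float
    env_pvalues: pd.Series | None = None

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(ev) > 1e-10) or np.any(ev < -1e-10):
            raise ValueError("eigenvalues must be nonincreasing and >= 0")
        if self.constrained_inertia > self.total_inertia + 1e-9:
            raise ValueError("constrained inertia exceeds total inertia")


def _chi_square_residuals(counts: np.ndarray):
    gt = counts.sum()
    if gt <= 0:
        raise ValueError("count table is empty")
    P = counts / gt
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0):
        raise ValueError("sample with zero total count")
    keep = c > 0
    c = c[keep]
    P = P[:, keep]
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    return Qbar, r, c, keep


def cca(table: CountTable, env: pd.DataFrame) -> CcaResult:
    """Canonical correspondence analysis of counts on environment.

    The chi-square-standardised table is regressed (row-weighted) on the
    environmental variables; the fitted part is eigen-decomposed.  Taxon
    scores span the constrained axes and site scores are the weighted
    averages of the taxon scores.
    """
    env = env.loc[table.samples]
    X = env.values.astype(float)
    n, q = X.shape
    if q > n - 1:
        raise ValueError(f"{q} environmental columns for {n} samples (max {n - 1})")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = env.columns[sds == 0][0]
        raise ValueError(f"environmental column {bad!r} is constant")

    counts = table.counts.astype(float)
    Qbar, r, c, keep = _chi_square_residuals(counts)
    taxa = [t for t, k in zip(table.taxa, keep) if k]
    total_inertia = float((Qbar ** 2).sum())

    w = np.sqrt(r)
    xbar = (r @ X) / r.sum()
    Xw = w[:, None] * (X - xbar)
    rank_x = np.linalg.matrix_rank(Xw)
    if rank_x < q:
        raise ValueError("environmental columns are collinear (aliased variable)")
    beta, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    Qhat = Xw @ beta
    u, s, vt = np.linalg.svd(Qhat, full_matrices=False)
    rank = min(rank_x, int((s > max(s[0], 1e-300) * 1e-10).sum()) if s.size else 0)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    eig = s ** 2
    constrained = float(eig.sum())

    # taxon scores on the constrained axes; site scores = weighted
    # averages of taxon scores over each sample's composition profile
    taxon_scores = vt.T / np.sqrt(c)[:, None]
    profiles = counts[:, keep] / counts[:, keep].sum(axis=1, keepdims=True)
    site_scores = profiles @ taxon_scores
    lc = (u * s) / w[:, None]

    axes = [f"CCA{i + 1}" for i in range(rank)]
    # env arrows: weighted correlation of each variable with the LC axes
    Xn = Xw / np.linalg.norm(Xw, axis=0)
    Un = u / np.linalg.norm(u, axis=0)
    biplot = Xn.T @ Un

    return CcaResult(
        eigenvalues=eig,
        site_scores=pd.DataFrame(site_scores, index=table.samples, columns=axes),
        lc_scores=pd.DataFrame(lc, index=table.samples, columns=axes),
        taxon_scores=pd.DataFrame(taxon_scores, index=taxa, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=env.columns, columns=axes),
        total_inertia=total_inertia,
        constrained_inertia=constrained,
    )


def _marginal_inertia(Qbar: np.ndarray, w: np.ndarray, x: np.ndarray,
                      r: np.ndarray) -> float:
    xbar = (r @ x[:, None]).item() / r.sum()
    xw = w * (x - xbar)
    nrm = xw @ xw
    if nrm <= 0:
        return 0.0
    proj = xw[:, None] * ((xw @ Qbar) / nrm)[None, :]
    return float((proj ** 2).sum())


def env_significance(table: CountTable, env: pd.DataFrame,
                     n_perm: int = 999, seed: int | None = None) -> pd.Series:
    """Permutation p-value of each environmental variable's marginal
    constrained inertia (variable fitted alone; values permuted across
    samples; p = (#exceedances + 1) / (n_perm + 1))."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    env = env.loc[table.samples]
    counts = table.counts.astype(float)
    Qbar, r, _c, _keep = _chi_square_residuals(counts)
    w = np.sqrt(r)
    rng = np.random.default_rng(seed)
    out = {}
    for col in env.columns:
        x = env[col].values.astype(float)
        if x.std() == 0:
            raise ValueError(f"environmental column {col!r} is constant")
        obs = _marginal_inertia(Qbar, w, x, r)
        b = 0
        for _ in range(n_perm):
            b += _marginal_inertia(Qbar, w, rng.permutation(x), r) >= obs - 1e-15
        out[col] = (b + 1.0) / (n_perm + 1.0)
    return pd.Series(out, name="p")


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinates analysis.

    Returns (coordinates on axes with positive eigenvalues, all
    eigenvalues sorted descending — negatives reported, not corrected).
    """
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    G = gower_center(d)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.ids, columns=axes), vals
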