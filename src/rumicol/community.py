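"""Count-table handling and community statistics.

Covers depth normalisation (rarefaction without replacement), alpha
diversity, Bray-Curtis dissimilarity, UPGMA dendrograms, and per-taxon
differential abundance with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CountTable",
    "DistanceMatrix",
    "rarefy",
    "diversity",
    "bray_curtis",
    "upgma",
    "differential_abundance",
    "adjust_bh",
]


@dataclass
class CountTable:
    """Integer abundance matrix, samples as rows and taxa as columns.

    ``data`` is a pandas DataFrame indexed by sample id with taxon lineage
    labels as columns.  ``rank`` tags the taxonomic level (e.g. ``genus``,
    ``otu``).
    """

    data: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("count table contains negative entries")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.data = self.data.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.values

    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances."""
        tot = self.data.sum(axis=1)
        if (tot == 0).any():
            bad = tot.index[tot == 0][0]
            raise ValueError(f"sample {bad!r} has zero total count")
        return self.data.div(tot, axis=0)

    def subset(self, samples=None, taxa=None) -> "CountTable":
        d = self.data
        if samples is not None:
            d = d.loc[list(samples)]
        if taxa is not None:
            d = d[list(taxa)]
        return CountTable(d.copy(), rank=self.rank)

    # interchange format: taxa as rows, samples as columns, first column
    # holds the lineage label
    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.data.T.rename_axis("taxon").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, rank: str = "genus") -> "CountTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        out = df.T
        out.index.name = None
        out.columns.name = None
        return cls(out, rank=rank)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    ids: list[str]
    matrix: np.ndarray
    metric: str = "braycurtis"
    transform: str = "raw"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if m.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(m < 0):
            raise ValueError("distance matrix has negative entries")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix([self.ids[i] for i in idx],
                              self.matrix[np.ix_(idx, idx)],
                              metric=self.metric, transform=self.transform)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            pd.DataFrame(self.matrix, index=self.ids, columns=self.ids) \
                .rename_axis("sample").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric: str = "braycurtis") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(list(df.index), df.values, metric=metric)


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; deterministic for a
    fixed seed.  Raises if any sample holds fewer than ``depth`` reads,
    naming the offending sample.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.totals()
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"sample {short.index[0]!r} has only {short.iloc[0]} reads, "
            f"cannot rarefy to {depth}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=table.data.index,
                                   columns=table.data.columns),
                      rank=table.rank)


def _chao1(row: np.ndarray) -> tuple[float, bool]:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2), False
    # bias-corrected form when no doubletons
    return s_obs + f1 * (f1 - 1) / 2.0, True


def diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Returns a DataFrame with columns ``richness``, ``chao1``,
    ``chao1_bias_corrected`` (flag), ``shannon`` (natural log),
    ``simpson`` (Gini-Simpson, 1 - sum p^2, larger = more diverse),
    ``simpson_dominance`` (sum p^2), and ``goods_coverage`` (1 - F1/N).
    """
    rows = []
    for sid, row in zip(table.samples, table.counts):
        n = int(row.sum())
        if n == 0:
            raise ValueError(f"sample {sid!r} is empty")
        p = row[row > 0] / n
        chao, corrected = _chao1(row)
        f1 = int((row == 1).sum())
        rows.append({
            "sample": sid,
            "richness": int((row > 0).sum()),
            "chao1": chao,
            "chao1_bias_corrected": corrected,
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p ** 2).sum()),
            "simpson_dominance": float((p ** 2).sum()),
            "goods_coverage": 1.0 - f1 / n,
        })
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis(table: CountTable, normalize: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d = sum|a-b| / sum(a+b).

    ``normalize=True`` converts samples to relative abundances first; the
    choice is recorded on the returned matrix.  A pair of all-zero samples
    makes the distance undefined and raises.
    """
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = table.counts.astype(float)
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.samples, zero) if z]
        raise ValueError(f"all-zero samples make Bray-Curtis undefined: {bad}")
    if normalize:
        x = x / x.sum(axis=1, keepdims=True)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = num / den
    d = d + d.T
    return DistanceMatrix(table.samples, d,
                          metric="braycurtis",
                          transform="relative" if normalize else "raw")


def upgma(d: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) dendrogram as a Newick string.

    Node height = merge distance / 2, so the cophenetic distance between
    two leaves equals their merge distance; an ultrametric input is
    reproduced exactly.
    """
    if d.n < 2:
        raise ValueError("need at least 2 samples for UPGMA")
    Z = hierarchy.linkage(d.condensed(), method="average")
    return linkage_to_newick(Z, d.ids)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    # height of each node (leaf = 0, internal = merge dist / 2)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        node = n + k
        heights[node] = h
        la = h - heights[a]
        lb = h - heights[b]
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
    return newick[n + len(Z) - 1] + ";"


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def differential_abundance(table: CountTable, metadata: pd.DataFrame,
                           factor: str, n_perm: int = 999,
                           seed: int | None = None,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-taxon permutation test of group differences with BH control.

    Counts get ``pseudocount`` added before the relative-abundance
    transform, then log10.  The statistic is the one-way ANOVA F on the
    log abundances (equivalent to the squared mean difference for two
    groups); p-values come from ``n_perm`` label permutations with the
    (b+1)/(m+1) convention, and q-values from :func:`adjust_bh`.
    Taxa constant across all samples get p = 1 and a ``constant`` flag.
    """
    meta = metadata.loc[table.samples]
    labels = meta[factor].astype(str).values
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = levels[counts < 2][0]
        raise ValueError(f"level {small!r} of {factor!r} has < 2 samples")

    x = table.counts.astype(float) + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    y = np.log10(x)  # samples x taxa

    const = np.ptp(y, axis=0) == 0

    def f_stat(yy: np.ndarray, codes_: np.ndarray) -> np.ndarray:
        grand = yy.mean(axis=0)
        ss_b = np.zeros(yy.shape[1])
        ss_w = np.zeros(yy.shape[1])
        for g in range(len(levels)):
            grp = yy[codes_ == g]
            gm = grp.mean(axis=0)
            ss_b += len(grp) * (gm - grand) ** 2
            ss_w += ((grp - gm) ** 2).sum(axis=0)
        df_b = len(levels) - 1
        df_w = yy.shape[0] - len(levels)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_b / df_b) / (ss_w / df_w)

    obs = f_stat(y, codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        exceed += f_stat(y, codes[perm]) >= obs - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)
    p[const] = 1.0
    if const.any():
        warnings.warn(f"{const.sum()} constant taxa set to p = 1")
    q = adjust_bh(p)
    return pd.DataFrame({"p": p, "q": q, "constant": const,
                         "statistic": np.where(const, np.nan, obs)},
                        index=table.taxa)
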