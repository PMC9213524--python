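"""Sample-level diagnostics: count-based ordination and growth rates.

Two sample dissimilarities are provided: the leading-logFC distance (per
pair of samples, root-mean-square of the largest absolute per-gene log2
differences, the top genes re-selected for every pair) and a Poisson
deviance distance on depth-normalised counts.  Classical (metric) MDS
embeds either.  A silhouette comparison quantifies whether samples group
by strain or by salinity.  The growth-rate estimator regresses the natural
log of relative fluorescence on time within each sequential transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExperimentDesign

__all__ = [
    "DistanceMatrix",
    "pairwise_logfc_distance",
    "classical_mds",
    "poisson_distance",
    "growth_rate",
    "cluster_concordance",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample dissimilarity with zero diagonal."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        M = self.matrix.to_numpy()
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(M), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (M < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def _log2_cpm(counts: CountMatrix, lib_sizes=None, prior: float = 2.0) -> np.ndarray:
    Y = counts.values.astype(float)
    if lib_sizes is None:
        lib = Y.sum(axis=0)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
    # prior count scaled by relative depth, as in the leading-logFC construction
    rel = lib / lib.mean()
    pc = prior * rel
    return np.log2((Y + pc[None, :]) / (lib + 2 * pc)[None, :] * 1e6)


def pairwise_logfc_distance(
    counts: CountMatrix,
    lib_sizes=None,
    top_n: int = 500,
) -> DistanceMatrix:
    """Leading-logFC distance between all sample pairs.

    For each pair, the distance is the root-mean-square of the ``top_n``
    largest absolute per-gene log2-CPM differences, with the top genes
    selected separately for that pair.  ``lib_sizes`` defaults to total
    counts; pass effective (TMM) library sizes for normalised distances.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > counts.n_genes:
        raise ValueError(
            f"top_n={top_n} exceeds the number of genes ({counts.n_genes})"
        )
    L = _log2_cpm(counts, lib_sizes)
    n = counts.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        diffs = np.abs(L[:, i][:, None] - L[:, i + 1 :])
        if diffs.size:
            part = np.partition(diffs, counts.n_genes - top_n, axis=0)[
                counts.n_genes - top_n :
            ]
            D[i, i + 1 :] = np.sqrt(np.mean(part**2, axis=0))
    D = D + D.T
    return DistanceMatrix(
        matrix=pd.DataFrame(D, index=counts.sample_ids, columns=counts.sample_ids)
    )


def classical_mds(dist: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns the
    first ``k`` coordinates ordered by descending eigenvalue.  Dimensions
    whose eigenvalues are not positive are dropped with a warning.  Sign
    convention: within each dimension, the largest-magnitude loading is
    made positive.
    """
    n = len(dist.sample_ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    D2 = dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    usable = eigval[:k] > 1e-10
    if not usable.all():
        warnings.warn(
            "distance matrix is not Euclidean in the requested dimension; "
            f"keeping {int(usable.sum())} of {k} axes",
            stacklevel=2,
        )
    kk = int(usable.sum())
    coords = eigvec[:, :kk] * np.sqrt(eigval[:kk])[None, :]
    for j in range(kk):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords,
        index=dist.sample_ids,
        columns=[f"MDS{j + 1}" for j in range(kk)],
    )


def poisson_distance(counts: CountMatrix) -> DistanceMatrix:
    """Poisson-deviance distance between depth-normalised samples.

    Samples are scaled by median-of-ratios size factors (total-count
    fallback when no gene is expressed everywhere); for each pair the
    distance is the square root of the summed per-gene Poisson deviance of
    the two scaled profiles against their pooled mean, with 0*log(0) = 0.
    """
    Y = counts.values.astype(float)
    totals = Y.sum(axis=0)
    if (totals == 0).any():
        bad = np.asarray(counts.sample_ids)[totals == 0]
        raise ValueError(f"sample(s) with zero total count: {list(bad)}")

    positive = (Y > 0).all(axis=1)
    if positive.any():
        logY = np.log(Y[positive])
        ref = logY.mean(axis=1)
        sf = np.exp(np.median(logY - ref[:, None], axis=0))
    else:
        sf = totals / np.exp(np.mean(np.log(totals)))
    Z = Y / sf[None, :]

    n = counts.n_samples
    D = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n):
            for j in range(i + 1, n):
                a, b = Z[:, i], Z[:, j]
                m = (a + b) / 2.0
                dev = np.zeros_like(a)
                for x in (a, b):
                    term = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / np.where(m > 0, m, 1.0)), 0.0)
                    dev += term - (x - m)
                D[i, j] = D[j, i] = np.sqrt(max(2.0 * dev.sum(), 0.0))
    return DistanceMatrix(
        matrix=pd.DataFrame(D, index=counts.sample_ids, columns=counts.sample_ids)
    )


def growth_rate(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential growth rates from fluorescence time series.

    ``series`` columns: strain, salinity, replicate, transfer, time_days,
    fluorescence (> 0).  Per transfer, the estimate is the ordinary
    least-squares slope of ln(fluorescence) against time (units 1/day).
    Transfers with fewer than two time points are skipped with a warning.
    Returns (per-transfer slopes, per-condition mean and SD over
    replicates x transfers).
    """
    required = {"strain", "salinity", "replicate", "transfer", "time_days", "fluorescence"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"growth series missing columns: {sorted(missing)}")
    if (series["fluorescence"] <= 0).any():
        raise ValueError("fluorescence values must be positive")

    rows = []
    keys = ["strain", "salinity", "replicate", "transfer"]
    for key, grp in series.groupby(keys, sort=False):
        if len(grp) < 2:
            warnings.warn(f"transfer {key} has fewer than 2 points; skipped", stacklevel=2)
            continue
        slope = np.polyfit(
            grp["time_days"].to_numpy(float),
            np.log(grp["fluorescence"].to_numpy(float)),
            deg=1,
        )[0]
        rows.append(dict(zip(keys, key), growth_rate=slope))
    slopes = pd.DataFrame(rows)
    if slopes.empty:
        return slopes, pd.DataFrame(columns=["strain", "salinity", "mean", "sd", "n"])
    summary = (
        slopes.groupby(["strain", "salinity"], sort=False)["growth_rate"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    return slopes, summary


def cluster_concordance(
    dist: DistanceMatrix, design: ExperimentDesign
) -> pd.Series:
    """Mean silhouette width by strain vs by salinity labels.

    Returns a Series with ``strain``, ``salinity`` and ``difference``
    (strain minus salinity).  Samples in singleton label classes get
    silhouette 0 with a warning.
    """
    from sklearn.metrics import silhouette_samples

    table = design.table.loc[dist.sample_ids]
    out = {}
    for factor in ("strain", "salinity"):
        labels = table[factor].astype(str).to_numpy()
        counts = pd.Series(labels).value_counts()
        if (counts == 1).any():
            warnings.warn(
                f"singleton {factor} class; its silhouette is set to 0",
                stacklevel=2,
            )
            sil = np.zeros(len(labels))
            mask = pd.Series(labels).map(counts).to_numpy() > 1
            if mask.any() and len(np.unique(labels[mask])) > 1:
                sub = silhouette_samples(
                    dist.values[np.ix_(mask, mask)], labels[mask], metric="precomputed"
                )
                sil[mask] = sub
        else:
            sil = silhouette_samples(dist.values, labels, metric="precomputed")
        out[factor] = float(np.mean(sil))
    out["difference"] = out["strain"] - out["salinity"]
    return pd.Series(out, name="mean_silhouette")
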