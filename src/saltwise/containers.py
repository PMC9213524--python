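"""Core data containers shared across the pipeline.

The pipeline is organised around a gene x sample integer count matrix, a
factorial experiment design (strain x salinity with replicates), and the
cell-means parameterisation of the negative-binomial GLM: one coefficient
per strain:salinity cell, on the log2 scale.  Contrasts are zero-sum weight
vectors over those cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExperimentDesign",
    "ContrastSet",
    "GeneFit",
    "ContrastResult",
    "cell_label",
]


def cell_label(strain: str, salinity) -> str:
    """Canonical label of a strain x salinity cell, e.g. ``"A:8"``."""
    return f"{strain}:{salinity}"


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Wraps a pandas DataFrame with gene identifiers as index and sample
    identifiers as columns.  Construction validates the type invariants.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("count matrix contains negative entries")
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])


@dataclass
class ExperimentDesign:
    """Per-sample strain, salinity and replicate labels for the factorial.

    ``table`` has one row per sample (index = sample_id) and columns
    ``strain``, ``salinity``, ``replicate``.  Salinity levels are kept in
    the order first seen unless ``salinity_order`` is given.
    """

    table: pd.DataFrame
    salinity_order: list = field(default=None)

    def __post_init__(self) -> None:
        required = {"strain", "salinity", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in design")
        if self.salinity_order is None:
            # numeric levels sort naturally; fall back to first-seen order
            levels = pd.unique(self.table["salinity"])
            try:
                self.salinity_order = sorted(levels)
            except TypeError:
                self.salinity_order = list(levels)
        # every strain must be observed at a consistent set of levels
        observed = self.table.groupby("strain", sort=False)["salinity"].apply(set)
        full = set(self.salinity_order)
        for strain, levels in observed.items():
            if levels != full:
                raise ValueError(
                    f"strain {strain!r} observed at salinities {sorted(levels)}, "
                    f"expected {sorted(full)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def strains(self) -> list[str]:
        return list(pd.unique(self.table["strain"]))

    @property
    def salinities(self) -> list:
        return list(self.salinity_order)

    @property
    def cell_labels(self) -> list[str]:
        """All strain:salinity cell labels, strains outer, salinities inner."""
        return [
            cell_label(st, sal) for st in self.strains for sal in self.salinities
        ]

    def sample_cells(self) -> pd.Series:
        """Cell label of each sample, aligned with ``sample_ids``."""
        return pd.Series(
            [
                cell_label(r["strain"], r["salinity"])
                for _, r in self.table.iterrows()
            ],
            index=self.table.index,
            name="cell",
        )

    def cell_means_matrix(self) -> pd.DataFrame:
        """Indicator design matrix: samples x cells, one 1 per row."""
        cells = self.sample_cells()
        X = pd.DataFrame(
            0.0, index=self.table.index, columns=self.cell_labels
        )
        for sample, cell in cells.items():
            X.loc[sample, cell] = 1.0
        return X

    def reorder(self, sample_ids) -> "ExperimentDesign":
        return ExperimentDesign(
            self.table.loc[list(sample_ids)], salinity_order=self.salinity_order
        )


@dataclass
class ContrastSet:
    """A named family of zero-sum weight vectors over design cells.

    ``weights`` is a DataFrame: one row per contrast (index = contrast
    name), one column per cell label.  ``family`` tags the set as
    ``"salinity-set"`` or ``"interaction-set"``.
    """

    family: str
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if self.weights.index.has_duplicates:
            raise ValueError("contrast names must be unique")
        sums = self.weights.sum(axis=1).to_numpy()
        if self.weights.shape[0] and not np.allclose(sums, 0.0, atol=1e-12):
            bad = self.weights.index[np.argmax(np.abs(sums))]
            raise ValueError(f"contrast {bad!r} weights do not sum to zero")

    @property
    def names(self) -> list[str]:
        return list(self.weights.index)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path) -> None:
        self.weights.to_csv(path, sep="\t", index_label="contrast")


@dataclass
class GeneFit:
    """Per-gene NB GLM fit under the cell-means parameterisation.

    coefficients : DataFrame, genes x cells, log2 scale.
    dispersions  : Series of NB dispersions phi_g >= 0.
    offsets      : Series of per-sample natural-log effective library sizes.
    deviance     : Series of residual deviances.
    converged    : boolean Series.
    design       : the ExperimentDesign used for the fit.
    counts       : the filtered CountMatrix the fit was computed from.
    """

    coefficients: pd.DataFrame
    dispersions: pd.Series
    offsets: pd.Series
    deviance: pd.Series
    converged: pd.Series
    design: ExperimentDesign
    counts: CountMatrix
    mean_log2cpm: pd.Series = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def cell_labels(self) -> list[str]:
        return list(self.coefficients.columns)

    def subset_genes(self, gene_ids) -> "GeneFit":
        genes = list(gene_ids)
        return GeneFit(
            coefficients=self.coefficients.loc[genes],
            dispersions=self.dispersions.loc[genes],
            offsets=self.offsets,
            deviance=self.deviance.loc[genes],
            converged=self.converged.loc[genes],
            design=self.design,
            counts=self.counts.subset_genes(genes),
            mean_log2cpm=(
                self.mean_log2cpm.loc[genes]
                if self.mean_log2cpm is not None
                else None
            ),
        )


@dataclass
class ContrastResult:
    """Raw per-gene x per-contrast test results.

    ``logfc``, ``stat`` and ``pvalue`` are DataFrames with genes as rows
    and contrast names as columns.  logFC is on the log2 scale and equals
    the contrast weights applied to the fitted coefficients.
    """

    family: str
    logfc: pd.DataFrame
    stat: pd.DataFrame
    pvalue: pd.DataFrame
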