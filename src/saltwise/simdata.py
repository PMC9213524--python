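"""Synthetic count experiments with known truth for the strain x salinity factorial.

Generates gene-wise negative-binomial counts under the same model class the
inference stage fits: log-link cell means on the log2 scale, per-sample
depth offsets, and gene-wise dispersion.  Genes are planted in one of five
effect classes:

``null``
    no effect of any kind (flat across all cells);
``strain_only``
    strain main effects, constant across salinities — null for both
    contrast families;
``salinity``
    a shared salinity response, identical in every strain;
``inter_magnitude``
    salinity responses of a single sign whose size differs between strains
    (including the one-strain-only case);
``inter_direction``
    salinity responses of opposite sign in two disjoint strain subsets.

The default configuration emulates an 8-strain x 3-salinity x 3-replicate
design (72 libraries) with strain-dominant expression structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExperimentDesign, ContrastSet, cell_label

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "SimConfigError",
    "simulate_experiment",
    "write_fixture",
]

DEFAULT_STRAINS = ["A", "B", "D", "F", "I", "J", "K", "P"]
DEFAULT_SALINITIES = [8, 16, 24]

CLASS_NULL = "null"
CLASS_SALINITY = "salinity"
CLASS_STRAIN = "strain_only"
CLASS_INTER_MAG = "inter_magnitude"
CLASS_INTER_DIR = "inter_direction"


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment generator.

    Fractions partition the gene set into effect classes; the remainder is
    null.  ``effect_size_logfc`` is the typical absolute log2 fold change
    between the extreme salinity levels for affected genes.
    ``strain_effect_sd`` controls the spread of strain main effects (log2);
    its default is four times ``salinity_effect_sd`` so that strain
    structure dominates sample-level ordination, as in the experiment this
    design emulates.
    """

    n_genes: int = 2000
    strains: list = field(default_factory=lambda: list(DEFAULT_STRAINS))
    salinities: list = field(default_factory=lambda: list(DEFAULT_SALINITIES))
    n_replicates: int = 3
    baseline_logmean_loc: float = 6.0
    baseline_logmean_scale: float = 2.0
    dispersion_logmean: float = float(np.log(0.1))
    dispersion_logsd: float = 0.5
    library_size_logsd: float = 0.2
    frac_salinity: float = 0.10
    frac_strain: float = 0.30
    frac_inter_magnitude: float = 0.05
    frac_inter_direction: float = 0.05
    effect_size_logfc: float = 2.0
    strain_effect_sd: float = 2.0
    salinity_effect_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise SimConfigError("n_genes must be non-negative")
        if len(set(self.strains)) != len(self.strains):
            raise SimConfigError("strains contains duplicate labels")
        if len(set(self.salinities)) != len(self.salinities):
            raise SimConfigError("salinities contains duplicate levels")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        for name in (
            "frac_salinity",
            "frac_strain",
            "frac_inter_magnitude",
            "frac_inter_direction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        effect_total = (
            self.frac_salinity
            + self.frac_inter_magnitude
            + self.frac_inter_direction
        )
        if effect_total > 1.0 + 1e-12:
            raise SimConfigError(
                "frac_salinity + frac_inter_magnitude + frac_inter_direction "
                "must not exceed 1"
            )
        if (
            effect_total + self.frac_strain > 1.0 + 1e-12
        ):
            raise SimConfigError("effect-class fractions sum to more than 1")
        for name in ("baseline_logmean_scale", "dispersion_logsd",
                     "library_size_logsd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        for name in ("effect_size_logfc", "strain_effect_sd",
                     "salinity_effect_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.strains) * len(self.salinities) * self.n_replicates


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment.

    beta_true     : genes x cells true log2 group means.
    class_label   : per-gene effect class.
    dispersions   : per-gene true NB dispersion.
    library_sizes : per-sample depth multipliers.
    """

    beta_true: pd.DataFrame
    class_label: pd.Series
    dispersions: pd.Series
    library_sizes: pd.Series

    def true_logfc(self, contrasts: ContrastSet) -> pd.DataFrame:
        """True log2 fold change for every gene x contrast."""
        W = contrasts.weights[self.beta_true.columns].to_numpy()
        values = self.beta_true.to_numpy() @ W.T
        return pd.DataFrame(
            values, index=self.beta_true.index, columns=contrasts.names
        )

    def null_genes(self, contrasts: ContrastSet) -> pd.Index:
        """Genes whose true contrast values are all zero for this family."""
        lfc = self.true_logfc(contrasts)
        return lfc.index[(lfc.abs() < 1e-12).all(axis=1)]


def _salinity_ramp(n_levels: int) -> np.ndarray:
    """Response shape over ordered salinity levels: 1 at the lowest level,
    0 at the highest, linear in between."""
    idx = np.arange(n_levels)
    return (n_levels - 1 - idx) / (n_levels - 1)


def simulate_experiment(
    config: SimConfig | None = None,
) -> tuple[CountMatrix, ExperimentDesign, SimulationTruth]:
    """Draw one synthetic experiment.

    Counts are NB distributed with mean ``library_size * 2**beta[g, cell]``
    and gene-wise dispersion phi_g (gamma-Poisson mixture; phi = 0 gives
    Poisson).  The same seed yields bit-identical output.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    S, L, R = len(config.strains), len(config.salinities), config.n_replicates
    G = config.n_genes
    cells = [
        cell_label(st, sal) for st in config.strains for sal in config.salinities
    ]
    gene_ids = [f"g{i:05d}" for i in range(G)]

    # class assignment: fixed counts per class, positions shuffled
    n_sal = int(np.floor(config.frac_salinity * G))
    n_mag = int(np.floor(config.frac_inter_magnitude * G))
    n_dir = int(np.floor(config.frac_inter_direction * G))
    n_str = int(np.floor(config.frac_strain * G))
    labels = np.array(
        [CLASS_SALINITY] * n_sal
        + [CLASS_INTER_MAG] * n_mag
        + [CLASS_INTER_DIR] * n_dir
        + [CLASS_STRAIN] * n_str
        + [CLASS_NULL] * (G - n_sal - n_mag - n_dir - n_str),
        dtype=object,
    )
    rng.shuffle(labels)

    baseline = rng.normal(
        config.baseline_logmean_loc, config.baseline_logmean_scale, size=G
    )
    beta = np.tile(baseline[:, None], (1, S * L))
    ramp = _salinity_ramp(L)

    for g in range(G):
        cls = labels[g]
        if cls == CLASS_STRAIN:
            strain_fx = rng.normal(0.0, config.strain_effect_sd, size=S)
            beta[g] += np.repeat(strain_fx, L)
        elif cls == CLASS_SALINITY:
            sign = rng.choice([-1.0, 1.0])
            size = abs(
                rng.normal(config.effect_size_logfc, config.salinity_effect_sd)
            )
            beta[g] += np.tile(sign * size * ramp, S)
        elif cls == CLASS_INTER_MAG:
            sign = rng.choice([-1.0, 1.0])
            n_affected = int(rng.integers(1, S))
            affected = rng.choice(S, size=n_affected, replace=False)
            per_strain = np.zeros(S)
            per_strain[affected] = sign * np.abs(
                rng.normal(
                    config.effect_size_logfc,
                    config.salinity_effect_sd,
                    size=n_affected,
                )
            )
            beta[g] += np.outer(per_strain, ramp).ravel()
        elif cls == CLASS_INTER_DIR:
            split = int(rng.integers(1, S))
            order = rng.permutation(S)
            per_strain = np.empty(S)
            sizes = np.abs(
                rng.normal(
                    config.effect_size_logfc, config.salinity_effect_sd, size=S
                )
            )
            # strictly opposite-sign responses in two disjoint subsets
            per_strain[order[:split]] = np.maximum(sizes[:split], 1e-6)
            per_strain[order[split:]] = -np.maximum(sizes[split:], 1e-6)
            beta[g] += np.outer(per_strain, ramp).ravel()

    dispersions = rng.lognormal(
        config.dispersion_logmean, config.dispersion_logsd, size=G
    )
    lib_sizes = rng.lognormal(0.0, config.library_size_logsd, size=S * L * R)

    sample_ids, strain_col, sal_col, rep_col = [], [], [], []
    for st in config.strains:
        for sal in config.salinities:
            for rep in range(1, R + 1):
                sample_ids.append(f"{st}_{sal}_r{rep}")
                strain_col.append(st)
                sal_col.append(sal)
                rep_col.append(rep)
    cell_of_sample = np.repeat(np.arange(S * L), R)

    mu = lib_sizes[None, :] * np.exp2(beta[:, cell_of_sample])
    # gamma-Poisson mixture; dispersion -> 0 handled by the Poisson branch
    phi = dispersions[:, None]
    small = dispersions < 1e-8
    lam = np.empty_like(mu)
    if (~small).any():
        shape = 1.0 / phi[~small]
        lam[~small] = rng.gamma(shape, mu[~small] * phi[~small])
    if small.any():
        lam[small] = mu[small]
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    design_df = pd.DataFrame(
        {"strain": strain_col, "salinity": sal_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimulationTruth(
        beta_true=pd.DataFrame(beta, index=gene_ids, columns=cells),
        class_label=pd.Series(labels, index=gene_ids, name="class_label"),
        dispersions=pd.Series(dispersions, index=gene_ids, name="dispersion"),
        library_sizes=pd.Series(lib_sizes, index=sample_ids, name="library_size"),
    )
    return (
        CountMatrix(counts_df),
        ExperimentDesign(design_df, salinity_order=list(config.salinities)),
        truth,
    )


def write_fixture(
    counts: CountMatrix,
    design: ExperimentDesign,
    truth: SimulationTruth | None,
    directory,
) -> dict:
    """Write a simulated experiment to plain-text files.

    Counts go out both as TSV and MatrixMarket (with row/column index
    files); design and truth as TSV.  Returns a dict of written paths.
    """
    import os
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(directory, exist_ok=True)
    paths = {}

    counts_tsv = os.path.join(directory, "counts.tsv")
    counts.counts.to_csv(counts_tsv, sep="\t", index_label="gene_id")
    paths["counts_tsv"] = counts_tsv

    mtx = os.path.join(directory, "counts.mtx")
    mmwrite(mtx, csr_matrix(counts.values))
    paths["counts_mtx"] = mtx
    rows = os.path.join(directory, "counts.mtx.rows")
    with open(rows, "w") as fh:
        fh.write("\n".join(counts.gene_ids) + ("\n" if counts.gene_ids else ""))
    paths["counts_mtx_rows"] = rows
    cols = os.path.join(directory, "counts.mtx.cols")
    with open(cols, "w") as fh:
        fh.write("\n".join(counts.sample_ids) + ("\n" if counts.sample_ids else ""))
    paths["counts_mtx_cols"] = cols

    design_tsv = os.path.join(directory, "design.tsv")
    design.table.to_csv(design_tsv, sep="\t", index_label="sample_id")
    paths["design_tsv"] = design_tsv

    if truth is not None:
        truth_tsv = os.path.join(directory, "truth.tsv")
        out = truth.beta_true.copy()
        out.insert(0, "class_label", truth.class_label)
        out.insert(1, "dispersion", truth.dispersions)
        out.to_csv(truth_tsv, sep="\t", index_label="gene_id")
        paths["truth_tsv"] = truth_tsv
    return paths
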