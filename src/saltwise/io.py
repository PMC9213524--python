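"""File readers/writers and the end-to-end pipeline driver.

Counts are accepted as TSV (gene_id column + one column per sample) or
MatrixMarket (``.mtx`` plus ``.mtx.rows`` / ``.mtx.cols`` index files);
designs and annotations as TSV; the GO DAG as OBO or a parent-child TSV.
``run_pipeline`` chains filtering, normalisation, dispersion estimation,
GLM fitting, both contrast families, stage-wise testing, interaction
classification, response partitions, top-gene rankings, enrichment and
sample ordination, writing TSV results plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, ExperimentDesign
from .contrasts import build_interaction_contrasts, build_salinity_contrasts
from .enrichment import (
    competitive_gsea,
    elim_ora,
    read_annotations,
    read_obo,
    read_parent_child_tsv,
    residual_correlation,
)
from .glm import (
    estimate_dispersions,
    filter_genes,
    fit_glm,
    normalization_factors,
    offsets_from_library_sizes,
    test_contrasts,
)
from .response_sets import (
    classify_interactions,
    core_response,
    top_genes,
    unique_de_partition,
)
from .stagewise import stagewise_test
from .structure import (
    classical_mds,
    cluster_concordance,
    pairwise_logfc_distance,
    poisson_distance,
)

logger = logging.getLogger("saltwise")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_counts",
    "read_design",
    "read_stagewise_tsv",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are serialised with results."""

    counts_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    dag_path: str | None = None
    output_dir: str | None = None
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 3
    dispersion_prior_df: float = 10.0
    elim_cutoff: float = 0.01
    top_n_ranking: int = 100
    top_n_mds: int = 500
    statistic: str = "lrt"
    confirmation_method: str = "holm"
    partition_mode: str = "pooled"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.min_cpm < 0:
            raise ValueError("min_cpm must be non-negative")
        if self.top_n_ranking < 1 or self.top_n_mds < 1:
            raise ValueError("top_n values must be >= 1")
        for path_attr in ("counts_path", "design_path", "annotations_path", "dag_path"):
            path = getattr(self, path_attr)
            if path is not None and not os.path.exists(path):
                raise ValueError(f"{path_attr} does not exist: {path}")


def read_counts(path) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense())
        with open(path + ".rows") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        with open(path + ".cols") as fh:
            samples = [line.strip() for line in fh if line.strip()]
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MatrixMarket shape {values.shape} does not match "
                f"{len(genes)} row and {len(samples)} column labels"
            )
        df = pd.DataFrame(values, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")
    frac = df.to_numpy()
    if not np.allclose(frac, np.round(frac)):
        raise ValueError("count matrix contains non-integer values")
    return CountMatrix(df.round().astype(np.int64))


def read_design(path, salinity_order=None) -> ExperimentDesign:
    """Read a sample metadata table (sample_id, strain, salinity, replicate)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExperimentDesign(df, salinity_order=salinity_order)


def read_stagewise_tsv(path, family: str, alpha: float = 0.05):
    """Re-load a stage-wise results TSV written by the pipeline."""
    from .stagewise import StagewiseResult

    df = pd.read_csv(path, sep="\t", index_col=0)
    blocks = {}
    for prefix in ("logfc", "raw_p", "padj", "call"):
        cols = [c for c in df.columns if c.startswith(prefix + ":")]
        block = df[cols]
        block.columns = [c.split(":", 1)[1] for c in cols]
        blocks[prefix] = block
    return StagewiseResult(
        family=family,
        alpha=alpha,
        screen_p=df["screen_p"],
        padj_screen=df["padj_screen"],
        logfc=blocks["logfc"],
        raw_p=blocks["raw_p"],
        padj=blocks["padj"],
        calls=blocks["call"].astype(bool),
    )


def _check_consistency(counts: CountMatrix, design: ExperimentDesign) -> None:
    missing = [s for s in counts.sample_ids if s not in design.table.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    extra = [s for s in design.table.index if s not in counts.sample_ids]
    if extra:
        raise ValueError(f"design samples missing from counts: {extra}")


def read_dag(path):
    path = str(path)
    if path.endswith(".obo"):
        return read_obo(path)
    return read_parent_child_tsv(path)


def _signed_z(result) -> pd.DataFrame:
    """Signed z-scores per gene x contrast from raw p-values and logFC sign."""
    from scipy import stats as sps

    p = np.clip(result.raw_p.to_numpy(), 1e-300, 1.0)
    z = sps.norm.isf(p / 2.0)
    return pd.DataFrame(
        np.sign(result.logfc.to_numpy()) * z,
        index=result.raw_p.index,
        columns=result.raw_p.columns,
    )


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    design: ExperimentDesign | None = None,
) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    When ``config.output_dir`` is set, results are also written as TSV
    plus a JSON manifest.  On failure the stage name is reported and
    partial outputs are removed.
    """
    config.validate()
    out = config.output_dir
    wrote_dir = False
    if out is not None:
        wrote_dir = not os.path.isdir(out)
        os.makedirs(out, exist_ok=True)

    stage = "input"
    try:
        if counts is None:
            if config.counts_path is None:
                raise ValueError("no counts supplied")
            counts = read_counts(config.counts_path)
        if design is None:
            if config.design_path is None:
                raise ValueError("no design supplied")
            design = read_design(config.design_path)
        _check_consistency(counts, design)
        design = design.reorder(counts.sample_ids)

        stage = "filter"
        filtered = filter_genes(
            counts, design, min_cpm=config.min_cpm, min_samples=config.min_samples
        )
        logger.info(
            "stage=filter genes_in=%d genes_out=%d", counts.n_genes, filtered.n_genes
        )

        stage = "normalize"
        lib_sizes = normalization_factors(filtered)
        offsets = offsets_from_library_sizes(lib_sizes)

        stage = "dispersions"
        dispersions = estimate_dispersions(
            filtered, design, offsets, prior_df=config.dispersion_prior_df
        )

        stage = "fit"
        fit = fit_glm(filtered, design, offsets, dispersions)

        stage = "contrasts"
        sal_set = build_salinity_contrasts(design.strains, design.salinities)
        int_set = build_interaction_contrasts(design.strains, design.salinities)

        stage = "stagewise"
        sal_result = stagewise_test(
            fit,
            sal_set,
            alpha=config.alpha,
            method=config.confirmation_method,
            statistic=config.statistic,
        )
        int_result = stagewise_test(
            fit, int_set, alpha=config.alpha, statistic=config.statistic
        )
        logger.info(
            "stage=stagewise family=salinity screened=%d de=%d",
            sal_result.n_screened, len(sal_result.de_genes()),
        )
        logger.info(
            "stage=stagewise family=interaction screened=%d de=%d",
            int_result.n_screened, len(int_result.de_genes()),
        )

        stage = "classification"
        classification = classify_interactions(int_result, sal_result)
        core = core_response(sal_result, design.strains)
        partition = unique_de_partition(sal_result)
        logger.info(
            "stage=classification interaction_de=%d core=%d",
            len(classification.table), len(core),
        )

        stage = "ranking"
        n_rank = min(config.top_n_ranking, len(fit.gene_ids))
        top_screen, top_screen_dir = top_genes(
            sal_result, n=n_rank, ranking="padjscreen"
        )
        top_confect, _ = top_genes(sal_result, n=n_rank, ranking="confect")

        stage = "enrichment"
        enrichment = {}
        if config.annotations_path and config.dag_path:
            dag = read_dag(config.dag_path)
            dag.annotate(read_annotations(config.annotations_path))
            universe = set(fit.gene_ids)
            up = set(
                sal_result.calls.index[
                    ((sal_result.calls) & (sal_result.logfc > 0)).any(axis=1)
                ]
            )
            down = set(
                sal_result.calls.index[
                    ((sal_result.calls) & (sal_result.logfc < 0)).any(axis=1)
                ]
            )
            enrichment["ora_up"] = elim_ora(
                up & universe, universe, dag, elim_cutoff=config.elim_cutoff
            )
            enrichment["ora_down"] = elim_ora(
                down & universe, universe, dag, elim_cutoff=config.elim_cutoff
            )
            term_sets = {
                t: set(dag.genes_of(t)) & universe
                for t in dag.terms
                if len(set(dag.genes_of(t)) & universe) >= 2
            }
            log2cpm = pd.DataFrame(
                np.log2(
                    (filtered.values + 0.5)
                    / (lib_sizes.to_numpy()[None, :] + 1.0)
                    * 1e6
                ),
                index=fit.gene_ids,
                columns=filtered.sample_ids,
            )
            cor = residual_correlation(log2cpm, design)
            z = _signed_z(sal_result)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for contrast in z.columns:
                    enrichment[f"gsea:{contrast}"] = competitive_gsea(
                        z[contrast], term_sets, inter_gene_cor=cor, dag=dag
                    )

        stage = "ordination"
        top_n_mds = min(config.top_n_mds, filtered.n_genes)
        logfc_dist = pairwise_logfc_distance(
            filtered, lib_sizes=lib_sizes.to_numpy(), top_n=top_n_mds
        )
        mds = classical_mds(logfc_dist, k=2)
        pois = poisson_distance(filtered)
        concordance = cluster_concordance(logfc_dist, design)

        results = {
            "counts": counts,
            "filtered": filtered,
            "fit": fit,
            "salinity_result": sal_result,
            "interaction_result": int_result,
            "classification": classification,
            "core_response": core,
            "partition": partition,
            "top_padjscreen": top_screen,
            "top_confect": top_confect,
            "enrichment": enrichment,
            "logfc_distance": logfc_dist,
            "mds": mds,
            "poisson_distance": pois,
            "concordance": concordance,
        }

        if out is not None:
            stage = "write"
            _write_results(config, results, out)
        return results
    except Exception as exc:
        if out is not None:
            # remove partial outputs; keep a pre-existing directory itself
            if wrote_dir:
                shutil.rmtree(out, ignore_errors=True)
            else:
                for name in os.listdir(out):
                    if name.startswith("saltwise_"):
                        os.remove(os.path.join(out, name))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_results(config: PipelineConfig, results: dict, out: str) -> None:
    def path(name):
        return os.path.join(out, f"saltwise_{name}")

    sal, inter = results["salinity_result"], results["interaction_result"]
    for tag, res in (("salinity", sal), ("interaction", inter)):
        frame = pd.concat(
            {
                "logfc": res.logfc,
                "raw_p": res.raw_p,
                "padj": res.padj,
                "call": res.calls.astype(int),
            },
            axis=1,
        )
        frame.columns = [f"{a}:{b}" for a, b in frame.columns]
        frame.insert(0, "padj_screen", res.padj_screen)
        frame.insert(0, "screen_p", res.screen_p)
        frame.to_csv(path(f"{tag}_results.tsv"), sep="\t", index_label="gene_id")
    results["classification"].table.to_csv(
        path("interaction_classes.tsv"), sep="\t"
    )
    pd.Series(results["core_response"], name="gene_id").to_csv(
        path("core_response.tsv"), sep="\t", index=False
    )
    results["mds"].to_csv(path("mds.tsv"), sep="\t", index_label="sample_id")
    results["poisson_distance"].matrix.to_csv(
        path("poisson_distance.tsv"), sep="\t", index_label="sample_id"
    )
    for key, enr in results["enrichment"].items():
        safe = key.replace(":", "_").replace("-", "_")
        enr.table.to_csv(path(f"enrichment_{safe}.tsv"), sep="\t", index=False)

    manifest = {
        "package": "saltwise",
        "version": __version__,
        "config": asdict(config),
        "n_genes_input": results["counts"].n_genes,
        "n_genes_filtered": results["filtered"].n_genes,
        "n_samples": results["counts"].n_samples,
        "de_per_contrast": {
            "salinity": sal.summary()["n_de"].to_dict(),
            "interaction": inter.summary()["n_de"].to_dict(),
        },
        "n_core_response": int(len(results["core_response"])),
        "partition_sizes": results["partition"].sizes(),
        "silhouette": results["concordance"].to_dict(),
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
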