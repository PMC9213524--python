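"""Simulation-based validation recipes.

End-to-end checks that exercise the whole pipeline against the generator's
ground truth: empirical FDR of the stage-wise procedure, recovery of the
planted interaction categories, and the strain-dominance ordination check
(with the gene-blocklist robustness variant).  These are the routines the
acceptance machinery and long-running validation tests share.
"""

from __future__ import annotations

import warnings

import numpy as np

from .contrasts import build_interaction_contrasts, build_salinity_contrasts
from .glm import (
    estimate_dispersions,
    filter_genes,
    fit_glm,
    normalization_factors,
    offsets_from_library_sizes,
)
from .response_sets import classify_interactions
from .simdata import SimConfig, simulate_experiment
from .stagewise import stagewise_test
from .structure import cluster_concordance, pairwise_logfc_distance

__all__ = [
    "fit_simulated",
    "salinity_fdp",
    "interaction_null_fdp",
    "classification_recovery",
    "strain_dominance",
]


def fit_simulated(config: SimConfig):
    """Simulate one experiment and run the standard fitting chain."""
    counts, design, truth = simulate_experiment(config)
    filtered = filter_genes(counts, design)
    lib = normalization_factors(filtered)
    offsets = offsets_from_library_sizes(lib)
    disp = estimate_dispersions(filtered, design, offsets)
    fit = fit_glm(filtered, design, offsets, disp)
    return fit, design, truth


def salinity_fdp(seed: int, n_genes: int = 2000, alpha: float = 0.05) -> float:
    """False discovery proportion of the salinity-set procedure, one seed.

    Uses the generator defaults (10% of genes with a shared salinity
    effect of |log2FC| = 2, strain-dominant nuisance effects).  A false
    discovery is a DE-called gene whose true salinity-set contrast values
    are all zero.
    """
    config = SimConfig(n_genes=n_genes, seed=seed)
    fit, design, truth = fit_simulated(config)
    family = build_salinity_contrasts(design.strains, design.salinities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stagewise_test(fit, family, alpha=alpha)
    null_genes = set(truth.null_genes(family))
    de = result.de_genes()
    if len(de) == 0:
        return 0.0
    return len(set(de) & null_genes) / len(de)


def interaction_null_fdp(seed: int, n_genes: int = 2000, alpha: float = 0.05) -> float:
    """FDP of the interaction-set procedure when no interactions exist.

    All genes carry equal salinity slopes across strains (shared salinity
    effects and strain main effects remain), so every interaction call is
    a false discovery.
    """
    config = SimConfig(
        n_genes=n_genes, seed=seed,
        frac_inter_magnitude=0.0, frac_inter_direction=0.0,
    )
    fit, design, truth = fit_simulated(config)
    family = build_interaction_contrasts(design.strains, design.salinities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = stagewise_test(fit, family, alpha=alpha)
    null_genes = set(truth.null_genes(family))
    de = result.de_genes()
    if len(de) == 0:
        return 0.0
    return len(set(de) & null_genes) / len(de)


def classification_recovery(
    seed: int, n_genes: int = 600, alpha: float = 0.05
) -> dict:
    """Recovery of the planted interaction categories for one seed.

    Uses enriched interaction fractions (15% magnitude, 15% direction) so
    each run detects enough interaction genes to score.  Returns counts of
    detected planted direction/magnitude genes and how they were
    classified, plus a flag for the partition property (every
    interaction-DE gene in exactly one category).
    """
    config = SimConfig(
        n_genes=n_genes, seed=seed,
        frac_inter_magnitude=0.15, frac_inter_direction=0.15,
    )
    fit, design, truth = fit_simulated(config)
    sal_family = build_salinity_contrasts(design.strains, design.salinities)
    int_family = build_interaction_contrasts(design.strains, design.salinities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sal_res = stagewise_test(fit, sal_family, alpha=alpha)
        int_res = stagewise_test(fit, int_family, alpha=alpha)
    classification = classify_interactions(int_res, sal_res)

    table = classification.table
    de = set(int_res.de_genes())
    labels = truth.class_label
    out = {
        "n_interaction_de": len(de),
        "partition_ok": set(table.index) == de
        and (table["category"].isin(["magnitude", "direction"])).all(),
    }
    for cls in ("inter_direction", "inter_magnitude"):
        planted = set(labels[labels == cls].index)
        detected = planted & de
        as_direction = sum(
            table.loc[g, "category"] == "direction" for g in detected
        )
        out[cls] = {
            "detected": len(detected),
            "classified_direction": as_direction,
        }
    return out


def strain_dominance(seed: int, n_genes: int = 2000, blocklist_size: int = 100):
    """Silhouette comparison by strain vs salinity, one simulated run.

    Returns (full-data silhouettes, silhouettes after dropping a planted
    blocklist).  The blocklist stands in for a set of genes with strong
    strain-linked expression (the robustness recipe: recompute the
    ordination after removing a supplied gene list and re-evaluate which
    factor the samples cluster by); here it is the first
    ``blocklist_size`` genes planted with strain main effects.
    """
    config = SimConfig(n_genes=n_genes, seed=seed)
    counts, design, truth = simulate_experiment(config)
    top_n = min(500, counts.n_genes)

    dist = pairwise_logfc_distance(counts, top_n=top_n)
    sil_full = cluster_concordance(dist, design)

    strain_genes = truth.class_label[truth.class_label == "strain_only"].index
    blocklist = set(strain_genes[:blocklist_size])
    kept = [g for g in counts.gene_ids if g not in blocklist]
    reduced = counts.subset_genes(kept)
    dist_reduced = pairwise_logfc_distance(
        reduced, top_n=min(top_n, reduced.n_genes)
    )
    sil_reduced = cluster_concordance(dist_reduced, design)
    return sil_full, sil_reduced
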