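"""Post-testing set logic over stage-wise results.

Four analyses downstream of the two contrast families:

* **interaction classification** — every interaction-DE gene is assigned to
  exactly one of two categories.  ``direction``: some salinity contrast has
  at least one strain significantly up- and another significantly
  down-regulated.  ``magnitude``: everything else (DE in a subset of
  strains only, or significant same-sign differences in response size).
* **core response** — genes DE in at least one per-strain salinity
  contrast of *every* strain (average contrasts excluded from the
  criterion).
* **uniquely-DE partition** — DE genes split into: exactly one strain and
  not the average; exactly one strain and the average; average only;
  multi-strain remainder.
* **top-gene rankings** — by screening Padjscreen, by a confident-effect
  (lower confidence bound on |logFC|) ordering, or by contrast-specific
  Padj, with up/down direction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import AVERAGE_LABEL, strain_of_contrast, salinity_pair_of_contrast
from .stagewise import StagewiseResult

__all__ = [
    "InteractionClassification",
    "ResponsePartition",
    "classify_interactions",
    "core_response",
    "unique_de_partition",
    "top_genes",
]


@dataclass
class InteractionClassification:
    """Category and supporting evidence per interaction-DE gene.

    ``table`` has one row per interaction-DE gene with columns
    ``category`` ("magnitude" or "direction"), ``evidence_contrast`` (the
    salinity pair showing opposite signs, empty for magnitude genes),
    ``strains_up``, ``strains_down`` (comma-joined strain lists) and
    ``flagged`` (True when no per-strain salinity information existed and
    the gene defaulted to magnitude).
    """

    table: pd.DataFrame

    @property
    def direction_genes(self) -> pd.Index:
        return self.table.index[self.table["category"] == "direction"]

    @property
    def magnitude_genes(self) -> pd.Index:
        return self.table.index[self.table["category"] == "magnitude"]


@dataclass
class ResponsePartition:
    """Disjoint buckets of salinity-DE genes plus their cardinalities."""

    unique_strain: dict  # strain -> Index of genes DE only in that strain
    unique_strain_and_average: dict
    average_only: pd.Index
    multi_strain: pd.Index

    def sizes(self) -> dict:
        return {
            "unique_strain": int(sum(len(v) for v in self.unique_strain.values())),
            "unique_strain_and_average": int(
                sum(len(v) for v in self.unique_strain_and_average.values())
            ),
            "average_only": int(len(self.average_only)),
            "multi_strain": int(len(self.multi_strain)),
        }


def _per_strain_calls(result: StagewiseResult) -> dict[str, pd.DataFrame]:
    """Split salinity-set calls into per-strain (and average) blocks."""
    blocks: dict[str, list[str]] = {}
    for name in result.contrast_names:
        blocks.setdefault(strain_of_contrast(name), []).append(name)
    return {strain: result.calls[names] for strain, names in blocks.items()}


def classify_interactions(
    interaction_result: StagewiseResult,
    salinity_result: StagewiseResult,
) -> InteractionClassification:
    """Assign each interaction-DE gene to "magnitude" or "direction".

    A gene is "direction" when, for some salinity pair, at least one strain
    has a confirmed positive per-strain salinity call and another strain a
    confirmed negative call for that same pair; otherwise "magnitude".
    Interaction-DE genes absent from the salinity result (or with no
    per-strain contrasts) default to magnitude and are flagged.
    """
    inter_de = interaction_result.de_genes()
    rows = []
    sal_calls = salinity_result.calls
    sal_logfc = salinity_result.logfc
    per_strain_names = [
        n
        for n in salinity_result.contrast_names
        if strain_of_contrast(n) != AVERAGE_LABEL
    ]
    pairs = sorted({salinity_pair_of_contrast(n) for n in per_strain_names})

    for gene in inter_de:
        if gene not in sal_calls.index or not per_strain_names:
            rows.append((gene, "magnitude", "", "", "", True))
            continue
        category, ev_pair, ups, downs = "magnitude", "", [], []
        for pair in pairs:
            names = [
                n for n in per_strain_names if salinity_pair_of_contrast(n) == pair
            ]
            called = [n for n in names if bool(sal_calls.loc[gene, n])]
            up = [strain_of_contrast(n) for n in called if sal_logfc.loc[gene, n] > 0]
            down = [strain_of_contrast(n) for n in called if sal_logfc.loc[gene, n] < 0]
            if up and down:
                category, ev_pair, ups, downs = "direction", pair, up, down
                break
        rows.append(
            (gene, category, ev_pair, ",".join(ups), ",".join(downs), False)
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "category",
            "evidence_contrast",
            "strains_up",
            "strains_down",
            "flagged",
        ],
    ).set_index("gene_id")
    return InteractionClassification(table=table)


def core_response(salinity_result: StagewiseResult, strains) -> pd.Index:
    """Genes DE in >= 1 per-strain salinity contrast of every strain.

    Average-response calls do not count toward the criterion.  As the
    intersection of per-strain DE sets the result inherits each strain's
    FDR control only marginally; callers wanting descriptive evidence can
    take the max over strains of the per-strain minimum Padj.
    """
    blocks = _per_strain_calls(salinity_result)
    sets = []
    for strain in strains:
        if strain not in blocks:
            return pd.Index([])
        calls = blocks[strain]
        sets.append(set(calls.index[calls.any(axis=1)]))
    core = set.intersection(*sets) if sets else set()
    return pd.Index(
        [g for g in salinity_result.gene_ids if g in core]
    )  # stable gene order


def unique_de_partition(
    salinity_result: StagewiseResult, salinity_pair: str | None = None
) -> ResponsePartition:
    """Partition salinity-DE genes by which strains (and the average)
    called them.

    By default calls are pooled over the salinity contrasts of each
    strain block; pass ``salinity_pair`` (e.g. ``"8-24"``) to restrict
    the partition to a single contrast per block.
    """
    blocks = _per_strain_calls(salinity_result)
    if salinity_pair is not None:
        blocks = {
            strain: calls[
                [c for c in calls.columns
                 if salinity_pair_of_contrast(c) == salinity_pair]
            ]
            for strain, calls in blocks.items()
        }
        if any(c.shape[1] == 0 for c in blocks.values()):
            raise ValueError(f"no contrasts match salinity pair {salinity_pair!r}")
    avg_calls = blocks.pop(AVERAGE_LABEL, None)
    strain_de = {
        strain: set(calls.index[calls.any(axis=1)])
        for strain, calls in blocks.items()
    }
    avg_de = (
        set(avg_calls.index[avg_calls.any(axis=1)])
        if avg_calls is not None
        else set()
    )

    unique_strain: dict = {s: [] for s in strain_de}
    unique_strain_avg: dict = {s: [] for s in strain_de}
    average_only, multi = [], []
    de_union = set().union(*strain_de.values(), avg_de) if strain_de else avg_de
    all_de = [g for g in salinity_result.gene_ids if g in de_union]
    for gene in all_de:
        in_strains = [s for s, genes in strain_de.items() if gene in genes]
        in_avg = gene in avg_de
        if len(in_strains) == 1 and not in_avg:
            unique_strain[in_strains[0]].append(gene)
        elif len(in_strains) == 1 and in_avg:
            unique_strain_avg[in_strains[0]].append(gene)
        elif len(in_strains) == 0 and in_avg:
            average_only.append(gene)
        else:
            multi.append(gene)

    return ResponsePartition(
        unique_strain={s: pd.Index(v) for s, v in unique_strain.items()},
        unique_strain_and_average={
            s: pd.Index(v) for s, v in unique_strain_avg.items()
        },
        average_only=pd.Index(average_only),
        multi_strain=pd.Index(multi),
    )


def _confect_bounds(result: StagewiseResult, alpha: float) -> pd.Series:
    """Confident lower bound on max |logFC| per gene.

    Simplified confident-effect ranking: per gene, take the contrast with
    the largest |logFC| among confirmed contrasts (all contrasts when none
    confirmed), form its Wald-style lower confidence bound at a step-down
    FDR-adjusted level, and enforce monotonicity down the ranking.
    """
    logfc = result.logfc.to_numpy()
    raw_p = result.raw_p.to_numpy()
    # implied SE of each logFC from the two-sided p of the LRT statistic
    z = stats.norm.isf(np.clip(raw_p, 1e-300, 1.0) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(z > 0, np.abs(logfc) / z, np.inf)
    best = np.argmax(np.abs(logfc), axis=1)
    rows = np.arange(logfc.shape[0])
    abs_fc = np.abs(logfc[rows, best])
    se_best = se[rows, best]

    order = np.argsort(-abs_fc, kind="stable")
    n = len(order)
    bounds = np.empty(n)
    for rank, gi in enumerate(order, start=1):
        level = alpha * rank / n  # step-down FDR-adjusted confidence level
        zcrit = stats.norm.isf(level / 2.0)
        bounds[rank - 1] = abs_fc[gi] - zcrit * se_best[gi]
    bounds = np.minimum.accumulate(np.maximum(bounds, 0.0))
    out = np.empty(n)
    out[order] = bounds
    return pd.Series(out, index=result.logfc.index, name="confect")


def top_genes(
    result: StagewiseResult,
    n: int = 100,
    ranking: str = "padjscreen",
    contrast: str | None = None,
) -> tuple[pd.Index, pd.DataFrame]:
    """Top-n genes under one of three rankings, with direction summaries.

    ``padjscreen``    ascending screening-stage adjusted p;
    ``confect``       descending confident lower bound on |logFC|;
    ``contrast_padj`` ascending confirmation Padj of ``contrast``.
    Ties break on stable gene order.  Returns the ranked gene index and a
    per-contrast up/down count table restricted to the top set (counting
    only confirmed contrasts).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranking == "padjscreen":
        key = result.padj_screen
        order = key.sort_values(kind="stable").index
    elif ranking == "confect":
        key = _confect_bounds(result, result.alpha)
        order = key.sort_values(ascending=False, kind="stable").index
    elif ranking == "contrast_padj":
        if contrast is None:
            raise ValueError("ranking 'contrast_padj' requires a contrast name")
        key = result.padj[contrast]
        order = key.sort_values(kind="stable", na_position="last").index
    else:
        raise ValueError(f"unknown ranking {ranking!r}")

    if n > len(order):
        import warnings

        warnings.warn(
            f"requested top {n} of {len(order)} genes; truncating", stacklevel=2
        )
        n = len(order)
    top = order[:n]
    calls = result.calls.loc[top]
    logfc = result.logfc.loc[top]
    summary = pd.DataFrame(
        {
            "n_up": (calls & (logfc > 0)).sum(axis=0),
            "n_down": (calls & (logfc < 0)).sum(axis=0),
        }
    )
    return top, summary
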