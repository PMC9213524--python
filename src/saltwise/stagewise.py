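"""Two-stage testing of a contrast family with gene-level FDR control.

Stage I (screening) tests, per gene, the global null that *all* contrasts
in the family are simultaneously zero, via a likelihood-ratio test of the
cell-means model against the model constrained by the family's span.  The
screening p-values are Benjamini-Hochberg adjusted (Padjscreen) and genes
with Padjscreen <= alpha pass to stage II.

Stage II (confirmation) tests each contrast only for screened genes.
Within each gene the family of per-contrast p-values is corrected by a
step-down familywise procedure (Holm by default; a Shaffer variant exploits
the logical constraints among the three pairwise salinity comparisons) and
compared against the stage-II level alpha * R / m, where R of m screened
genes passed stage I.  Reported Padj values are rescaled by m / R so that
"call iff Padj <= alpha" reproduces the procedure's decisions; the whole
two-stage procedure then controls the gene-level FDR at alpha.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContrastResult, ContrastSet, GeneFit
from .glm import constrained_deviance, test_contrasts

__all__ = [
    "StagewiseResult",
    "screening_pvalues",
    "benjamini_hochberg",
    "confirm_stage",
    "stagewise_test",
]


@dataclass
class StagewiseResult:
    """Full output of the two-stage procedure for one contrast family."""

    family: str
    alpha: float
    screen_p: pd.Series
    padj_screen: pd.Series
    logfc: pd.DataFrame
    raw_p: pd.DataFrame
    padj: pd.DataFrame
    calls: pd.DataFrame  # boolean genes x contrasts

    @property
    def gene_ids(self) -> list[str]:
        return list(self.screen_p.index)

    @property
    def contrast_names(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_screened(self) -> int:
        return int((self.padj_screen <= self.alpha).sum())

    def de_genes(self) -> pd.Index:
        """Genes with at least one confirmed contrast."""
        return self.calls.index[self.calls.any(axis=1)]

    def summary(self) -> pd.DataFrame:
        """Per-contrast confirmed / up / down counts."""
        up = (self.calls & (self.logfc > 0)).sum(axis=0)
        down = (self.calls & (self.logfc < 0)).sum(axis=0)
        return pd.DataFrame(
            {"n_de": self.calls.sum(axis=0), "n_up": up, "n_down": down}
        )


def screening_pvalues(fit: GeneFit, contrasts: ContrastSet) -> pd.Series:
    """Per-gene p-value of the global null over the whole family.

    Likelihood-ratio test of the full cell-means model against the model
    constrained to the family's span; degrees of freedom = rank of the
    family's weight matrix (linearly dependent contrasts are absorbed).
    """
    if len(contrasts) == 0:
        raise ValueError("contrast family is empty")
    W = contrasts.weights[fit.cell_labels].to_numpy()
    rank = int(np.linalg.matrix_rank(W))
    if rank < W.shape[0]:
        warnings.warn(
            f"family {contrasts.family!r}: {W.shape[0]} contrasts span only "
            f"{rank} dimensions; testing the span",
            stacklevel=2,
        )
    dev0, rank = constrained_deviance(fit, W)
    lr = np.maximum(dev0 - fit.deviance.to_numpy(), 0.0)
    p = stats.chi2.sf(lr, df=rank)
    return pd.Series(p, index=fit.gene_ids, name="screen_p")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment with monotonicity, order-preserving.

    NaN entries propagate and are excluded from the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[ok] = unsorted
    return out


_PAIR_RE = re.compile(r"^(?P<block>.+):(?P<pair>[^:]+-[^:]+)$")


def _shaffer_blocks(names: list[str]) -> list[list[int]] | None:
    """Group contrast names into per-strain blocks of 3 pairwise salinity
    comparisons.  Returns None when the family lacks that structure."""
    blocks: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        m = _PAIR_RE.match(name)
        if not m:
            return None
        blocks.setdefault(m.group("block"), []).append(i)
    if any(len(v) != 3 for v in blocks.values()):
        return None
    return list(blocks.values())


def _within_gene_adjust(p: np.ndarray, method: str, blocks) -> np.ndarray:
    """Step-down familywise adjustment of one gene's contrast p-values."""
    k = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(k)
    if method == "holm" or blocks is None:
        mult = np.arange(k, 0, -1)
    else:
        # Shaffer-style multipliers: three pairwise differences of three
        # means admit at most one true null once any of them is false, so
        # after the first rejection within a block only one hypothesis of
        # that block can still be null.
        block_of = np.empty(k, dtype=int)
        for bi, idxs in enumerate(blocks):
            for i in idxs:
                block_of[i] = bi
        remaining = np.array([len(b) for b in blocks])
        rejected = np.zeros(len(blocks), dtype=int)
        mult = np.empty(k, dtype=float)
        for step, i in enumerate(order):
            possible = np.where(rejected > 0, np.minimum(remaining, 1), remaining)
            mult[step] = possible.sum()
            b = block_of[i]
            remaining[b] -= 1
            rejected[b] += 1
        # note: mult already in step order below
        adj_sorted = np.maximum.accumulate(np.minimum(mult * p[order], 1.0))
        adj[order] = adj_sorted
        return adj
    adj_sorted = np.maximum.accumulate(np.minimum(mult * p[order], 1.0))
    adj[order] = adj_sorted
    return adj


def confirm_stage(
    fit: GeneFit,
    contrasts: ContrastSet,
    screened_genes,
    alpha: float,
    R: int,
    m: int,
    contrast_result: ContrastResult | None = None,
    method: str = "holm",
    statistic: str = "lrt",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Confirmation stage: per-contrast adjusted p-values for screened genes.

    Returns (logfc, raw_p, padj, calls) DataFrames over *all* genes of the
    fit; rows not in ``screened_genes`` carry NaN adjusted p-values and no
    calls.  Padj = within-gene step-down adjusted p * m / R (clipped at 1),
    so that Padj <= alpha reproduces the stage-II decision at level
    alpha * R / m.
    """
    if method not in ("holm", "shaffer"):
        raise ValueError(f"unknown confirmation method {method!r}")
    genes = list(fit.gene_ids)
    cols = contrasts.names
    W = contrasts.weights[fit.cell_labels]
    logfc = pd.DataFrame(
        fit.coefficients.to_numpy() @ W.to_numpy().T, index=genes, columns=cols
    )
    if contrast_result is None:
        # per-contrast refits are only needed for genes that passed
        # screening; everything else keeps NaN raw p-values
        screened_list = [g for g in genes if g in set(screened_genes)]
        raw_p = pd.DataFrame(np.nan, index=genes, columns=cols)
        if screened_list:
            sub = test_contrasts(
                fit.subset_genes(screened_list), contrasts, statistic=statistic
            )
            raw_p.loc[screened_list] = sub.pvalue.to_numpy()
    else:
        logfc = contrast_result.logfc
        raw_p = contrast_result.pvalue
    padj = pd.DataFrame(np.nan, index=genes, columns=logfc.columns)
    calls = pd.DataFrame(False, index=genes, columns=logfc.columns)
    if R == 0:
        return logfc, raw_p, padj, calls

    blocks = _shaffer_blocks(list(logfc.columns)) if method == "shaffer" else None
    scale = m / R
    screened = set(screened_genes)
    raw_np = raw_p.to_numpy()
    padj_np = padj.to_numpy()
    for gi, gene in enumerate(genes):
        if gene not in screened:
            continue
        adj = _within_gene_adjust(raw_np[gi], method, blocks)
        padj_np[gi] = np.minimum(adj * scale, 1.0)
    padj = pd.DataFrame(padj_np, index=genes, columns=logfc.columns)
    calls = padj <= alpha
    calls = calls.fillna(False).astype(bool)
    return logfc, raw_p, padj, calls


def stagewise_test(
    fit: GeneFit,
    contrasts: ContrastSet,
    alpha: float = 0.05,
    method: str = "holm",
    statistic: str = "lrt",
) -> StagewiseResult:
    """Run both stages for one contrast family.

    A gene is differentially expressed when it has at least one confirmed
    contrast.  Families are always tested separately; never pool the
    salinity and interaction sets.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    screen_p = screening_pvalues(fit, contrasts)
    padj_screen = pd.Series(
        benjamini_hochberg(screen_p.to_numpy()),
        index=screen_p.index,
        name="padj_screen",
    )
    screened = padj_screen.index[padj_screen <= alpha]
    m = int(screen_p.notna().sum())
    R = len(screened)
    logfc, raw_p, padj, calls = confirm_stage(
        fit,
        contrasts,
        screened,
        alpha,
        R,
        m,
        method=method,
        statistic=statistic,
    )
    return StagewiseResult(
        family=contrasts.family,
        alpha=alpha,
        screen_p=screen_p,
        padj_screen=padj_screen,
        logfc=logfc,
        raw_p=raw_p,
        padj=padj,
        calls=calls,
    )
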