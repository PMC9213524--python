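"""GO overrepresentation and competitive gene-set testing.

Overrepresentation analysis (ORA) uses the one-sided hypergeometric test on
the 2x2 table of term membership vs study membership, optionally with the
*elim* decorrelation: terms are visited children-before-parents and, when a
term's p-value falls below the elim cutoff, its annotated genes are removed
from all of its ancestors before those are tested.  This prevents a strong
specific term from dragging its general ancestors into significance.

The competitive gene-set test asks whether the per-gene statistics of a
term's members are shifted relative to all other genes, inflating the
variance of the set mean by 1 + (m - 1) * rho_bar to account for residual
inter-gene correlation (rho_bar floored at zero), in the spirit of CAMERA.

The DAG is held as a networkx DiGraph with child -> parent (is_a) edges;
annotations are propagated to ancestors before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GoDag",
    "EnrichmentResult",
    "read_obo",
    "read_parent_child_tsv",
    "read_annotations",
    "fisher_ora",
    "elim_ora",
    "competitive_gsea",
    "residual_correlation",
    "collapse_duplicate_sets",
]


@dataclass
class GoDag:
    """A GO-style DAG plus gene annotations propagated to ancestors.

    graph        : DiGraph with child -> parent edges (is_a).
    names        : term id -> human-readable name.
    namespaces   : term id -> namespace (BP / MF / CC).
    annotations  : term id -> frozenset of directly+ancestrally annotated genes.
    """

    graph: nx.DiGraph
    names: dict = field(default_factory=dict)
    namespaces: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def ancestors(self, term: str) -> set:
        """All terms reachable via is_a edges (term itself excluded)."""
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def annotate(self, gene_to_terms: dict) -> None:
        """Attach gene -> direct-term annotations and propagate upward."""
        ann: dict[str, set] = {t: set() for t in self.graph.nodes}
        for gene, terms in gene_to_terms.items():
            for term in terms:
                if term not in ann:
                    continue
                ann[term].add(gene)
                for anc in self.ancestors(term):
                    ann[anc].add(gene)
        self.annotations = {t: frozenset(g) for t, g in ann.items()}

    def genes_of(self, term: str) -> frozenset:
        return self.annotations.get(term, frozenset())


@dataclass
class EnrichmentResult:
    """Per-term enrichment statistics.

    ``table`` columns: term, name, namespace, study_count, universe_count,
    pvalue, enrichment_ratio (study_count / universe_count), direction
    ("up"/"down" for the competitive test, "" for ORA).
    """

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["pvalue"] <= alpha]


# ---------------------------------------------------------------------------
# readers


def read_obo(path) -> GoDag:
    """Minimal OBO reading: term ids, names, namespaces and is_a edges."""
    import obonet

    multi = obonet.read_obo(path)
    graph = nx.DiGraph()
    names, namespaces = {}, {}
    graph.add_nodes_from(multi.nodes)
    for term, data in multi.nodes(data=True):
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "")
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return GoDag(graph=graph, names=names, namespaces=namespaces)


def read_parent_child_tsv(path) -> GoDag:
    """Two-column child<TAB>parent table as a DAG fallback."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("parent-child table needs two columns: child, parent")
    graph = nx.DiGraph()
    children, parents = df.iloc[:, 0], df.iloc[:, 1]
    graph.add_nodes_from(pd.unique(pd.concat([children, parents])))
    graph.add_edges_from(zip(children, parents))
    return GoDag(graph=graph, names={t: t for t in graph.nodes})


def read_annotations(path) -> dict:
    """Gene -> set of term ids, from two-column TSV or GAF 2.x.

    GAF lines (comment lines starting with '!') use columns 2 (gene) and
    5 (term); plain TSVs use the first two columns.
    """
    gene_to_terms: dict[str, set] = {}
    with open(path) as fh:
        first = fh.readline()
        is_gaf = first.startswith("!")
        fh.seek(0)
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if is_gaf:
                if len(fields) < 5:
                    continue
                gene, term = fields[1], fields[4]
            else:
                if len(fields) < 2:
                    continue
                gene, term = fields[0], fields[1]
            if gene == "gene_id" or term == "term_id":  # header row
                continue
            gene_to_terms.setdefault(gene, set()).add(term)
    return gene_to_terms


# ---------------------------------------------------------------------------
# overrepresentation


def _hypergeom_upper(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe M, term K, study N)."""
    return float(stats.hypergeom.sf(k - 1, M, K, N))


def _ora_table(dag: GoDag, study: set, universe: set, term_genes: dict) -> pd.DataFrame:
    rows = []
    M, N = len(universe), len(study)
    for term in dag.terms:
        genes = term_genes[term] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study)
        p = _hypergeom_upper(k, M, K, N)
        rows.append(
            (
                term,
                dag.names.get(term, term),
                dag.namespaces.get(term, ""),
                k,
                K,
                p,
                k / K,
                "",
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term",
            "name",
            "namespace",
            "study_count",
            "universe_count",
            "pvalue",
            "enrichment_ratio",
            "direction",
        ],
    )
    return df.sort_values("pvalue", kind="stable").reset_index(drop=True)


def fisher_ora(study, universe, dag: GoDag) -> EnrichmentResult:
    """Classic one-sided Fisher/hypergeometric ORA per term."""
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    if not study:
        return EnrichmentResult(
            table=pd.DataFrame(
                columns=[
                    "term",
                    "name",
                    "namespace",
                    "study_count",
                    "universe_count",
                    "pvalue",
                    "enrichment_ratio",
                    "direction",
                ]
            )
        )
    term_genes = {t: set(dag.genes_of(t)) for t in dag.terms}
    return EnrichmentResult(table=_ora_table(dag, study, universe, term_genes))


def elim_ora(study, universe, dag: GoDag, elim_cutoff: float = 0.01) -> EnrichmentResult:
    """ORA with the elim decorrelation.

    Terms are processed leaves-first (reverse topological order on the
    child -> parent graph).  When a term's p-value is below
    ``elim_cutoff``, its annotated genes are removed from every ancestor
    before the ancestor is tested.  With a cutoff no term reaches, the
    output equals :func:`fisher_ora`.
    """
    if not 0.0 < elim_cutoff <= 1.0:
        raise ValueError("elim_cutoff must lie in (0, 1]")
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    if not study:
        return fisher_ora(study, universe, dag)

    term_genes = {t: set(dag.genes_of(t)) for t in dag.terms}
    M, N = len(universe), len(study)
    pvals: dict[str, float] = {}
    # topological order of child -> parent edges yields children first
    for term in nx.topological_sort(dag.graph):
        if not set(dag.genes_of(term)) & universe:
            continue  # never annotated in this universe
        genes = term_genes[term] & universe
        k, K = len(genes & study), len(genes)
        # a term fully depleted by its children scores the trivial p = 1
        p = _hypergeom_upper(k, M, K, N) if K else 1.0
        pvals[term] = p
        if p < elim_cutoff:
            removed = set(dag.genes_of(term))
            for anc in dag.ancestors(term):
                term_genes[anc] -= removed

    rows = []
    for term, p in pvals.items():
        genes = term_genes[term] & universe
        # counts reported on the (possibly depleted) table actually tested
        K = len(genes) if term in pvals else 0
        k = len(genes & study)
        rows.append(
            (
                term,
                dag.names.get(term, term),
                dag.namespaces.get(term, ""),
                k,
                K,
                p,
                k / K if K else 0.0,
                "",
            )
        )
    df = (
        pd.DataFrame(
            rows,
            columns=[
                "term",
                "name",
                "namespace",
                "study_count",
                "universe_count",
                "pvalue",
                "enrichment_ratio",
                "direction",
            ],
        )
        .sort_values("pvalue", kind="stable")
        .reset_index(drop=True)
    )
    return EnrichmentResult(table=df)


def collapse_duplicate_sets(term_sets: dict) -> tuple[dict, dict]:
    """Collapse terms with byte-identical gene sets.

    Returns (representative term -> gene set, representative -> list of
    absorbed terms).  Terms carrying exactly the same genes are redundant
    for any set-based test; the first term in iteration order represents
    each group.  This is deliberately minimal — no semantic-similarity
    pruning.
    """
    seen: dict[frozenset, str] = {}
    collapsed: dict = {}
    absorbed: dict = {}
    for term, genes in term_sets.items():
        key = frozenset(genes)
        if key in seen:
            absorbed[seen[key]].append(term)
        else:
            seen[key] = term
            collapsed[term] = set(genes)
            absorbed[term] = []
    return collapsed, absorbed


# ---------------------------------------------------------------------------
# competitive gene-set test


def residual_correlation(log_expr: pd.DataFrame, design) -> pd.DataFrame:
    """Residual inter-gene correlation after removing cell means.

    ``log_expr`` is genes x samples on a variance-stabilised (log) scale;
    ``design`` supplies the strain x salinity cell of each sample.
    Returns the gene x gene correlation matrix of the residuals.
    """
    cells = design.sample_cells().loc[log_expr.columns]
    resid = log_expr.copy()
    for _, samples in cells.groupby(cells):
        cols = samples.index
        resid[cols] = resid[cols].sub(resid[cols].mean(axis=1), axis=0)
    R = np.corrcoef(resid.to_numpy())
    return pd.DataFrame(R, index=log_expr.index, columns=log_expr.index)


def competitive_gsea(
    gene_stats: pd.Series,
    term_sets: dict,
    inter_gene_cor: float | pd.DataFrame = 0.01,
    dag: GoDag | None = None,
) -> EnrichmentResult:
    """Correlation-adjusted competitive test of each term's gene set.

    For a set of m genes with mean statistic different from the remaining
    genes, the two-sample t statistic is computed with the set variance
    inflated by VIF = 1 + (m - 1) * rho_bar.  ``inter_gene_cor`` is either
    a scalar rho_bar applied to every set or a gene x gene correlation
    matrix from which each set's mean pairwise correlation is taken
    (floored at 0).  Sets smaller than 2 genes are skipped with a warning.
    """
    universe = list(gene_stats.index)
    values = gene_stats.to_numpy(dtype=float)
    G = len(universe)
    pos = {g: i for i, g in enumerate(universe)}
    overall_var = float(np.var(values, ddof=1)) if G > 1 else 0.0

    rows = []
    for term, genes in term_sets.items():
        idx = [pos[g] for g in genes if g in pos]
        m = len(idx)
        if m < 2:
            warnings.warn(f"term {term!r} has fewer than 2 genes; skipped", stacklevel=2)
            continue
        m2 = G - m
        if m2 < 1:
            continue
        in_mask = np.zeros(G, dtype=bool)
        in_mask[idx] = True
        mean_in = values[in_mask].mean()
        mean_out = values[~in_mask].mean()
        if isinstance(inter_gene_cor, pd.DataFrame):
            sub = inter_gene_cor.to_numpy()[np.ix_(idx, idx)]
            rho = (sub.sum() - m) / (m * (m - 1))
        else:
            rho = float(inter_gene_cor)
        rho = max(rho, 0.0)
        vif = 1.0 + (m - 1) * rho
        if overall_var <= 0:
            rows.append((term, m, mean_in - mean_out, 0.0, 1.0))
            continue
        se = np.sqrt(overall_var * (vif / m + 1.0 / m2))
        t = (mean_in - mean_out) / se
        p = 2.0 * stats.t.sf(abs(t), df=G - 2)
        rows.append((term, m, mean_in - mean_out, t, min(p, 1.0)))

    df = pd.DataFrame(
        rows, columns=["term", "set_size", "mean_diff", "stat", "pvalue"]
    )
    df["direction"] = np.where(df["mean_diff"] >= 0, "up", "down")
    if dag is not None:
        df["name"] = [dag.names.get(t, t) for t in df["term"]]
        df["namespace"] = [dag.namespaces.get(t, "") for t in df["term"]]
    df = df.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=df)
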