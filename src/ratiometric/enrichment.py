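"""Scoring gene graphs against pathway, gene-pair and ontology annotations.

Given the nested graphs of a stringency sweep, this module measures how
much of the accepted edge set is biologically annotated:

* :func:`annotated_edge_fraction` — percent of edges whose endpoints are
  both pathway-annotated genes (optionally both in the *same* set).
* :func:`within_pathway_recovery` — per-pathway edge-recovery curves as a
  function of graph vertex size.
* :func:`annotated_pair_fraction` — percent of edges present in a curated
  gene-pair database.
* :func:`permuted_pathway_null` — an expression-matched permutation null
  for the recovery curve (random same-size gene sets drawn to match the
  pathway's mean-expression profile), yielding a false-discovery envelope.
* :func:`aggregate_ontology` + :func:`category_enrichment` — merge small
  ontology terms upward into categories with at least ``min_size``
  detected genes, then score selections by one-sided hypergeometric tests
  with Bonferroni correction.
* :func:`pathway_cv_profiles` — per-pathway distributions of each gene's
  CV(FPKM), with Welch t-tests between pathway groups.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix
from .pairscan import GeneGraph, StringencySweep, select_graph_at_size

__all__ = [
    "GeneSetCollection",
    "PairAnnotation",
    "OntologyDag",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "read_pair_annotation",
    "read_ontology",
    "annotated_edge_fraction",
    "within_pathway_recovery",
    "annotated_pair_fraction",
    "permuted_pathway_null",
    "aggregate_ontology",
    "category_enrichment",
    "pathway_cv_profiles",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (KEGG-pathway style)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def all_members(self) -> frozenset[str]:
        return frozenset().union(*self.sets.values())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class PairAnnotation:
    """Unordered annotated gene pairs (IntPath style)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            if a > b:
                raise ValueError("pairs must be stored in sorted order")

    @classmethod
    def from_iterable(cls, pairs: Iterable[tuple[str, str]]) -> "PairAnnotation":
        canon = frozenset(
            tuple(sorted((a, b))) for a, b in pairs if a != b
        )
        return cls(pairs=canon)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class OntologyDag:
    """Acyclic child -> parent term graph with gene annotations."""

    parents: dict[str, frozenset[str]]
    annotations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def terms(self) -> list[str]:
        known = set(self.parents)
        for ps in self.parents.values():
            known.update(ps)
        return sorted(known)


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's hypergeometric enrichment record."""

    category: str
    overlap: int
    category_size: int
    selection_size: int
    background_size: int
    p_raw: float
    p_bonferroni: float
    enriched: bool


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs >= 3 fields: {line[:80]!r}")
        name, desc, *genes = fields
        if name in sets:
            raise ValueError(f"duplicate gene set id {name!r}")
        members = frozenset(g for g in genes if g)
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pair_annotation(path: str | Path, delimiter: str = "\t") -> PairAnnotation:
    """Read a 2-column annotated gene-pair table."""
    frame = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    return PairAnnotation.from_iterable(
        zip(frame.iloc[:, 0], frame.iloc[:, 1])
    )


def read_ontology(
    edges_path: str | Path,
    annotations_path: str | Path,
    delimiter: str = "\t",
) -> OntologyDag:
    """Read a DAG from (child, parent) edges and (gene, term) annotations.

    For OBO files, parse with :mod:`obonet` and pass the resulting
    ``is_a`` edges; this reader handles the plain 2-column form.
    """
    edge_frame = pd.read_csv(edges_path, sep=delimiter, header=None, dtype=str, comment="#")
    parents: dict[str, set[str]] = {}
    for child, parent in zip(edge_frame.iloc[:, 0], edge_frame.iloc[:, 1]):
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    ann_frame = pd.read_csv(annotations_path, sep=delimiter, header=None, dtype=str, comment="#")
    annotations: dict[str, set[str]] = {}
    for gene, term in zip(ann_frame.iloc[:, 0], ann_frame.iloc[:, 1]):
        annotations.setdefault(term, set()).add(gene)
    return OntologyDag(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        annotations={t: frozenset(gs) for t, gs in annotations.items()},
    )


# ---------------------------------------------------------------------------
# Edge-level annotation scores
# ---------------------------------------------------------------------------

def annotated_edge_fraction(
    graph: GeneGraph,
    sets: GeneSetCollection,
    same_set: bool = False,
) -> float:
    """Percent of graph edges whose both endpoints are annotated genes.

    With ``same_set=True`` both endpoints must belong to one common set
    (the stricter within-pathway reading); otherwise membership anywhere
    in the collection counts.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    if same_set:
        hits = sum(
            1
            for a, b in graph.edges
            if any(a in members and b in members for members in sets.sets.values())
        )
    else:
        universe = sets.all_members()
        hits = sum(1 for a, b in graph.edges if a in universe and b in universe)
    return 100.0 * hits / graph.n_edges


def annotated_pair_fraction(graph: GeneGraph, pairs: PairAnnotation) -> float:
    """Percent of graph edges present in the annotated pair database."""
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    hits = len(set(graph.edges) & pairs.pairs)
    return 100.0 * hits / graph.n_edges


def within_pathway_recovery(
    sweep: StringencySweep,
    sets: GeneSetCollection,
    pathway: str,
    vertex_sizes: Sequence[int],
) -> pd.DataFrame:
    """Within-pathway edge counts at a series of graph vertex sizes.

    At each requested |V(G)| (nearest sweep step at-or-above that size),
    counts edges with both endpoints in the pathway, and reports the
    percent of pathway genes present in the graph.  Counts are
    non-decreasing because the sweep's graphs are nested.
    """
    members = sets[pathway]
    if len(members) < 2:
        raise ValueError(f"pathway {pathway!r} has fewer than 2 genes")
    rows = []
    for size in vertex_sizes:
        graph = select_graph_at_size(sweep, size, match_on="genes")
        within = sum(1 for a, b in graph.edges if a in members and b in members)
        present = len(graph.vertices & members)
        rows.append(
            {
                "target_vertex_size": size,
                "step": graph.stringency_index,
                "n_vertices": graph.n_vertices,
                "within_pathway_edges": within,
                "pathway_genes_present_pct": 100.0 * present / len(members),
            }
        )
    return pd.DataFrame(rows)


def permuted_pathway_null(
    matrix: ExpressionMatrix,
    sweep: StringencySweep,
    sets: GeneSetCollection,
    pathway: str,
    vertex_sizes: Sequence[int],
    n_perm: int = 20,
    seed: int = 0,
    match_bins: int = 10,
) -> pd.DataFrame:
    """Expression-matched permutation null for a pathway recovery curve.

    Each permutation draws a random gene set of the same size as the
    pathway, matched on mean expression: genes are binned into
    ``match_bins`` equal-frequency mean-expression bins and draws respect
    the pathway's bin composition.  Returns per-size mean and min–max
    envelope of the within-set edge counts, to compare against the
    observed curve (a real pathway should sit above the envelope).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    members = sets[pathway] & set(matrix.gene_ids)
    if len(members) < 2:
        raise ValueError(f"pathway {pathway!r} has fewer than 2 detected genes")
    means = matrix.values.mean(axis=1)
    bins = pd.qcut(means, q=match_bins, labels=False, duplicates="drop")
    gene_bin = dict(zip(matrix.gene_ids, bins))
    by_bin: dict[int, list[str]] = {}
    for g in sorted(matrix.gene_ids):
        by_bin.setdefault(int(gene_bin[g]), []).append(g)
    composition: dict[int, int] = {}
    for g in members:
        composition[int(gene_bin[g])] = composition.get(int(gene_bin[g]), 0) + 1
    for b, need in composition.items():
        if len(by_bin.get(b, [])) < need:
            raise ValueError(
                f"mean-expression bin {b} has {len(by_bin.get(b, []))} genes, "
                f"needs {need} for the pathway composition"
            )

    # Pre-materialise graphs once per requested size.
    graphs = [select_graph_at_size(sweep, s, match_on="genes") for s in vertex_sizes]
    curves = np.zeros((n_perm, len(vertex_sizes)), dtype=int)
    for p in range(n_perm):
        drawn: set[str] = set()
        for b, need in sorted(composition.items()):
            drawn.update(rng.choice(by_bin[b], size=need, replace=False))
        for s_idx, graph in enumerate(graphs):
            curves[p, s_idx] = sum(
                1 for a, b2 in graph.edges if a in drawn and b2 in drawn
            )
    return pd.DataFrame(
        {
            "target_vertex_size": list(vertex_sizes),
            "null_mean": curves.mean(axis=0),
            "null_min": curves.min(axis=0),
            "null_max": curves.max(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# Ontology aggregation and enrichment
# ---------------------------------------------------------------------------

def aggregate_ontology(
    dag: OntologyDag,
    detected_genes: Iterable[str],
    min_size: int = 200,
) -> tuple[dict[str, frozenset[str]], dict[str, tuple[str, ...]], list[str]]:
    """Merge small ontology terms upward into large categories.

    A term is *large* when its own detected-gene count is at least
    ``min_size``; every small term is merged into its closest large
    ancestor (minimum edge distance; ties broken by fewest detected
    genes, then lexicographic id).  A small term with no large ancestor
    is merged into its root and that root is flagged.

    Returns ``(categories, member_terms, flagged_roots)`` where
    ``categories`` maps each output category id to its merged detected
    gene set and ``member_terms`` records which terms merged into it.
    """
    detected = set(detected_genes)
    terms = dag.terms()
    det_count = {
        t: len(dag.annotations.get(t, frozenset()) & detected) for t in terms
    }
    large = {t for t in terms if det_count[t] >= min_size}

    def ancestors_by_distance(term: str) -> list[tuple[int, str]]:
        seen = {term: 0}
        queue = deque([term])
        out = []
        while queue:
            node = queue.popleft()
            for parent in sorted(dag.parents.get(node, frozenset())):
                if parent not in seen:
                    seen[parent] = seen[node] + 1
                    out.append((seen[parent], parent))
                    queue.append(parent)
        return out

    target: dict[str, str] = {}
    flagged: list[str] = []
    for term in terms:
        if term in large:
            target[term] = term
            continue
        candidates = [
            (dist, det_count[anc], anc)
            for dist, anc in ancestors_by_distance(term)
            if anc in large
        ]
        if candidates:
            target[term] = min(candidates)[2]
        else:
            # No large ancestor: roll up into the term's root.
            roots = [
                anc
                for _, anc in ancestors_by_distance(term)
                if not dag.parents.get(anc)
            ]
            root = min(roots) if roots else term
            target[term] = root
            if root not in flagged:
                flagged.append(root)

    categories: dict[str, set[str]] = {}
    members: dict[str, list[str]] = {}
    for term in terms:
        cat = target[term]
        categories.setdefault(cat, set()).update(
            dag.annotations.get(term, frozenset()) & detected
        )
        members.setdefault(cat, []).append(term)
    return (
        {c: frozenset(gs) for c, gs in categories.items()},
        {c: tuple(sorted(ts)) for c, ts in members.items()},
        sorted(flagged),
    )


def category_enrichment(
    selection: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 1e-4,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment with Bonferroni correction.

    ``selection`` must be a subset of ``background``; each category is
    intersected with the background before testing.  A category is called
    enriched when its Bonferroni-corrected p-value is at or below
    ``alpha`` (default 1e-4).
    """
    background = set(background)
    selection = set(selection)
    if not selection <= background:
        raise ValueError("selection must be a subset of the background")
    n_tests = len(categories)
    results = []
    for name in sorted(categories):
        cat = set(categories[name]) & background
        k = len(cat & selection)
        p = float(
            stats.hypergeom.sf(
                k - 1, len(background), len(cat), len(selection)
            )
        )
        p_corr = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                category=name,
                overlap=k,
                category_size=len(cat),
                selection_size=len(selection),
                background_size=len(background),
                p_raw=p,
                p_bonferroni=p_corr,
                enriched=p_corr <= alpha,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Pathway expression-variability profiles
# ---------------------------------------------------------------------------

def pathway_cv_profiles(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    group_assignment: Mapping[str, int],
    cv_ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway CV(FPKM) samples and pairwise group comparisons.

    For every detected gene in every pathway, computes the CV of that
    gene's expression across samples.  Pathways carry a group label
    (e.g. 1 = recovered far better by RA ... 4 = better by PE/MI); group
    means are compared pairwise with Welch's two-sample t-test.

    Returns ``(per_gene_frame, group_comparison_frame)``.
    """
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=cv_ddof)
    rows = []
    for pathway, group in sorted(group_assignment.items()):
        for g in sorted(sets[pathway]):
            if g not in gene_index:
                continue
            i = gene_index[g]
            cv = sds[i] / means[i] if means[i] > 0 else np.nan
            rows.append({"pathway": pathway, "group": group, "gene": g, "cv_fpkm": cv})
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        raise ValueError("no detected genes in the assigned pathways")
    comparisons = []
    groups = sorted(per_gene["group"].unique())
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            x = per_gene.loc[per_gene["group"] == g1, "cv_fpkm"].dropna()
            y = per_gene.loc[per_gene["group"] == g2, "cv_fpkm"].dropna()
            t = stats.ttest_ind(x, y, equal_var=False)
            comparisons.append(
                {
                    "group_1": g1,
                    "group_2": g2,
                    "mean_1": float(x.mean()),
                    "mean_2": float(y.mean()),
                    "t_statistic": float(t.statistic),
                    "p_value": float(t.pvalue),
                }
            )
    return per_gene, pd.DataFrame(comparisons)
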