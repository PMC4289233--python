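"""All-pairs screening, rankings, stringency sweeps and graph diagnostics.

:func:`all_pairs` computes every pairwise statistic over a filtered
expression matrix in vectorised blocks (one block per anchor gene), so a
10k-gene panel (~48M pairs) stays within workstation memory.  The result, a
:class:`PairTable`, feeds:

* :func:`rank_pairs` — per-method orderings (RA ranks only gate-passing
  pairs, ascending by stability; PE/SP/MI rank all pairs descending).
* :func:`stringency_sweep` — 100 nested gene graphs per method, built by
  dividing each statistic's range into equal-width thresholds (PE: R² from
  1 to 0; MI: I from 2 to 0; RA: delta_cv from 0 to 1, or the gated
  stability range).  Degree-0 genes are excluded from every graph.
* overlap, correlation-between-measures, invariance and 2-regime
  diagnostics, and cross-batch ranking consistency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix
from .measures import (
    DegenerateInputError,
    MeasureConfig,
    equal_frequency_bins,
    pearson_association,
)

__all__ = [
    "PairTable",
    "GeneGraph",
    "StringencySweep",
    "all_pairs",
    "rank_pairs",
    "stringency_sweep",
    "inclusion_profile",
    "select_graph_at_size",
    "method_overlap",
    "measure_correlation_matrix",
    "invariance_diagnostic",
    "two_regime_flag",
    "ranking_consistency",
]

Method = Literal["RA", "PE", "MI", "SP"]

PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "cv_ab",
    "cv_ba",
    "delta_cv",
    "mean_ab",
    "mean_ba",
    "pearson_r",
    "pearson_r2",
    "spearman_r2",
    "mi",
    "n_used",
    "ra_evaluable",
    "stability",
]


@dataclass(frozen=True)
class PairTable:
    """All pairwise statistics over a matrix, one row per unordered pair."""

    frame: pd.DataFrame = field(repr=False)
    config: MeasureConfig
    n_genes: int
    n_samples: int

    def __post_init__(self) -> None:
        expected = self.n_genes * (self.n_genes - 1) // 2
        if len(self.frame) != expected:
            raise ValueError(
                f"expected {expected} pair records for {self.n_genes} genes, "
                f"got {len(self.frame)}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def pair_ids(self) -> list[tuple[str, str]]:
        return list(zip(self.frame["gene_a"], self.frame["gene_b"]))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneGraph:
    """One stringency step's graph: accepted edges, degree>=1 vertices."""

    stringency_index: int
    threshold: float
    edges: frozenset[tuple[str, str]]
    method: str = ""

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self.edges))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def write_edge_list(self, path) -> None:
        frame = pd.DataFrame(sorted(self.edges), columns=["gene_a", "gene_b"])
        frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StringencySweep:
    """A nested series of gene graphs from most to least stringent.

    The sweep stores, per pair, the first (most stringent) step at which
    the pair is accepted; individual graphs are materialised on demand and
    per-step vertex/edge counts are computed once.
    """

    method: str
    mode: str
    thresholds: np.ndarray = field(repr=False)  # length n_steps
    pair_ids: tuple[tuple[str, str], ...] = field(repr=False)
    first_step: np.ndarray = field(repr=False)  # per pair; > n_steps = never

    @property
    def n_steps(self) -> int:
        return len(self.thresholds)

    def step(self, i: int) -> GeneGraph:
        """Materialise the graph at step ``i`` (1-based; 1 = most stringent)."""
        if not 1 <= i <= self.n_steps:
            raise IndexError(f"step must be in [1, {self.n_steps}]")
        mask = self.first_step <= i
        edges = frozenset(
            tuple(sorted(self.pair_ids[j])) for j in np.flatnonzero(mask)
        )
        return GeneGraph(
            stringency_index=i,
            threshold=float(self.thresholds[i - 1]),
            edges=edges,
            method=self.method,
        )

    def edge_counts(self) -> np.ndarray:
        """|E(G_i)| for every step, i = 1..n_steps."""
        cached = getattr(self, "_edge_counts", None)
        if cached is None:
            clipped = np.clip(self.first_step, 1, self.n_steps + 1)
            per_step = np.bincount(clipped, minlength=self.n_steps + 2)
            cached = np.cumsum(per_step[1 : self.n_steps + 1])
            object.__setattr__(self, "_edge_counts", cached)
        return cached

    def vertex_counts(self) -> np.ndarray:
        """|V(G_i)| (degree-0 genes excluded) for every step."""
        cached = getattr(self, "_vertex_counts", None)
        if cached is not None:
            return cached
        if self.pair_ids:
            genes_a = np.array([p[0] for p in self.pair_ids], dtype=object)
            genes_b = np.array([p[1] for p in self.pair_ids], dtype=object)
            codes, uniques = pd.factorize(np.concatenate([genes_a, genes_b]))
            first = np.full(len(uniques), self.n_steps + 1, dtype=int)
            steps = np.concatenate([self.first_step, self.first_step])
            np.minimum.at(first, codes, steps)
            per_step = np.bincount(
                np.clip(first, 1, self.n_steps + 1), minlength=self.n_steps + 2
            )
        else:
            per_step = np.zeros(self.n_steps + 2, dtype=int)
        cached = np.cumsum(per_step[1 : self.n_steps + 1])
        object.__setattr__(self, "_vertex_counts", cached)
        return cached

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, self.n_steps + 1),
                "threshold": self.thresholds,
                "n_vertices": self.vertex_counts(),
                "n_edges": self.edge_counts(),
            }
        )


# ---------------------------------------------------------------------------
# All-pairs scan
# ---------------------------------------------------------------------------

def all_pairs(matrix: ExpressionMatrix, config: MeasureConfig = MeasureConfig()) -> PairTable:
    """Compute every pairwise statistic over the matrix.

    Genes are processed in lexicographic id order and pairs are emitted in
    lexicographic (gene_a < gene_b) order, so the output is deterministic.
    Ratio statistics exclude samples where either gene is zero; a pair
    with too few usable samples is flagged ``ra_evaluable=False`` (NaN
    ratio fields) rather than dropped.

    Raises
    ------
    ValueError
        For a matrix with fewer than two genes.
    DegenerateInputError
        If any gene is constant across samples (correlation and MI are
        undefined; filter such genes out first).
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least two genes for a pair scan")
    order = sorted(range(matrix.n_genes), key=lambda i: matrix.gene_ids[i])
    genes = [matrix.gene_ids[i] for i in order]
    x = matrix.values[order]
    n_genes, n_samples = x.shape

    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        bad = [g for g, c in zip(genes, constant) if c]
        raise DegenerateInputError(
            f"constant gene(s) make correlation/MI undefined: {bad[:5]}"
        )

    ddof = config.cv_ddof
    k = config.mi_bins
    min_used = max(3, int(np.ceil(config.min_used_fraction * n_samples)))

    # Pearson on raw values, Spearman as Pearson on average ranks.
    with np.errstate(invalid="ignore"):
        pearson = np.corrcoef(x)
        ranks = stats.rankdata(x, axis=1, method="average")
        spearman = np.corrcoef(ranks)

    # Equal-frequency bin labels and marginal entropies for MI.
    bins = np.vstack([equal_frequency_bins(row, k) for row in x])
    marg = np.zeros((n_genes, k))
    np.add.at(marg, (np.repeat(np.arange(n_genes), n_samples), bins.ravel()), 1.0)
    pm = marg / n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        h_marg = -np.nansum(np.where(pm > 0, pm * np.log2(pm), 0.0), axis=1)

    positive = x > 0
    n_pairs = n_genes * (n_genes - 1) // 2
    out = {
        name: np.empty(n_pairs)
        for name in ("cv_ab", "cv_ba", "delta_cv", "mean_ab", "mean_ba", "mi")
    }
    n_used_arr = np.empty(n_pairs, dtype=int)
    evaluable = np.empty(n_pairs, dtype=bool)
    gene_a_idx = np.empty(n_pairs, dtype=int)
    gene_b_idx = np.empty(n_pairs, dtype=int)

    pos = 0
    for i in range(n_genes - 1):
        j = slice(i + 1, n_genes)
        m = n_genes - i - 1
        block = slice(pos, pos + m)
        gene_a_idx[block] = i
        gene_b_idx[block] = np.arange(i + 1, n_genes)

        a = x[i]
        b = x[j]  # (m, n_samples)
        mask = positive[i] & positive[j]
        n_used = mask.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_ab = np.where(mask, a[None, :] / b, 0.0)
            r_ba = np.where(mask, b / np.where(a > 0, a, 1.0)[None, :], 0.0)
        safe_n = np.maximum(n_used, 1)
        mean_ab = r_ab.sum(axis=1) / safe_n
        mean_ba = r_ba.sum(axis=1) / safe_n
        denom = np.maximum(n_used - ddof, 1)
        var_ab = np.maximum(
            (np.square(r_ab).sum(axis=1) - safe_n * mean_ab**2) / denom, 0.0
        )
        var_ba = np.maximum(
            (np.square(r_ba).sum(axis=1) - safe_n * mean_ba**2) / denom, 0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_ab = np.sqrt(var_ab) / mean_ab
            cv_ba = np.sqrt(var_ba) / mean_ba
        ok = n_used >= min_used
        cv_ab = np.where(ok, cv_ab, np.nan)
        cv_ba = np.where(ok, cv_ba, np.nan)

        # Joint histograms against gene i, via combined bin codes.
        codes = bins[i][None, :] * k + bins[j]
        idx = (np.arange(m)[:, None] * (k * k) + codes).ravel()
        joint = np.bincount(idx, minlength=m * k * k).reshape(m, k * k)
        pj = joint / n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            h_joint = -np.where(pj > 0, pj * np.log2(pj), 0.0).sum(axis=1)
        mi = np.maximum(h_marg[i] + h_marg[i + 1 :] - h_joint, 0.0)

        out["cv_ab"][block] = cv_ab
        out["cv_ba"][block] = cv_ba
        out["delta_cv"][block] = np.abs(cv_ab - cv_ba)
        out["mean_ab"][block] = np.where(ok, mean_ab, np.nan)
        out["mean_ba"][block] = np.where(ok, mean_ba, np.nan)
        out["mi"][block] = mi
        n_used_arr[block] = n_used
        evaluable[block] = ok
        pos += m

    gene_names = np.asarray(genes, dtype=object)
    r = pearson[gene_a_idx, gene_b_idx]
    sp = spearman[gene_a_idx, gene_b_idx]
    if config.stability_rule == "max":
        stab = np.fmax(out["cv_ab"], out["cv_ba"])
    else:
        stab = 0.5 * (out["cv_ab"] + out["cv_ba"])
    frame = pd.DataFrame(
        {
            "gene_a": gene_names[gene_a_idx],
            "gene_b": gene_names[gene_b_idx],
            "cv_ab": out["cv_ab"],
            "cv_ba": out["cv_ba"],
            "delta_cv": out["delta_cv"],
            "mean_ab": out["mean_ab"],
            "mean_ba": out["mean_ba"],
            "pearson_r": r,
            "pearson_r2": r * r,
            "spearman_r2": sp * sp,
            "mi": out["mi"],
            "n_used": n_used_arr,
            "ra_evaluable": evaluable,
            "stability": stab,
        }
    )
    return PairTable(frame=frame, config=config, n_genes=n_genes, n_samples=n_samples)


# ---------------------------------------------------------------------------
# Rankings and sweeps
# ---------------------------------------------------------------------------

def _gated(table: PairTable) -> pd.DataFrame:
    """Pairs passing the delta_cv gate (and stability bound, if set)."""
    cfg = table.config
    f = table.frame
    mask = f["ra_evaluable"] & (f["delta_cv"] < cfg.delta_cv_threshold)
    if cfg.stability_bound is not None:
        mask &= f["stability"] <= cfg.stability_bound
    return f[mask]


def rank_pairs(table: PairTable, method: Method) -> pd.DataFrame:
    """Order the pair table by one method's association strength.

    RA ranks only gate-passing pairs, ascending by stability (smaller =
    stronger), ties broken by delta_cv then gene ids.  PE/SP rank all
    pairs descending by R² (ties: |r|, then ids); MI descending by I
    (ties: R², then ids).
    """
    if method == "RA":
        f = _gated(table)
        keys = [f["gene_b"], f["gene_a"], f["delta_cv"], f["stability"]]
    elif method == "PE":
        f = table.frame
        keys = [f["gene_b"], f["gene_a"], -f["pearson_r"].abs(), -f["pearson_r2"]]
    elif method == "MI":
        f = table.frame
        keys = [f["gene_b"], f["gene_a"], -f["pearson_r2"], -f["mi"]]
    elif method == "SP":
        f = table.frame
        keys = [f["gene_b"], f["gene_a"], -f["pearson_r2"], -f["spearman_r2"]]
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.lexsort([np.asarray(k) for k in keys])
    return f.iloc[order].reset_index(drop=True)


def stringency_sweep(
    table: PairTable,
    method: Method,
    n_steps: int = 100,
    ra_sweep_mode: Literal["delta_cv", "gated_cv"] = "delta_cv",
) -> StringencySweep:
    """Divide a method's statistic range into ``n_steps`` nested graphs.

    Ranges: PE/SP R² swept 1 -> 0, MI swept log2(mi_bins) -> 0, RA swept
    delta_cv 0 -> 1 (``delta_cv`` mode) or stability over the gated
    pairs' observed range (``gated_cv`` mode).  Step ``i`` accepts every
    pair meeting threshold ``i``; graphs are nested by construction.
    """
    f = table.frame
    mode = "statistic"
    if method == "RA":
        mode = ra_sweep_mode
        if ra_sweep_mode == "delta_cv":
            stat = f["delta_cv"].to_numpy()
            ids = list(zip(f["gene_a"], f["gene_b"]))
            span = 1.0
            thresholds = span * np.arange(1, n_steps + 1) / n_steps
            with np.errstate(invalid="ignore"):
                first = np.where(
                    np.isnan(stat),
                    n_steps + 1,
                    np.maximum(1, np.ceil(stat / (span / n_steps))),
                )
            first = np.where(stat > span, n_steps + 1, first)
        elif ra_sweep_mode == "gated_cv":
            g = _gated(table)
            stat = g["stability"].to_numpy()
            ids = list(zip(g["gene_a"], g["gene_b"]))
            span = float(stat.max()) if len(stat) else 1.0
            span = span if span > 0 else 1.0
            thresholds = span * np.arange(1, n_steps + 1) / n_steps
            first = np.maximum(1, np.ceil(stat / (span / n_steps)))
        else:
            raise ValueError(f"unknown ra_sweep_mode {ra_sweep_mode!r}")
    elif method in ("PE", "SP", "MI"):
        col = {"PE": "pearson_r2", "SP": "spearman_r2", "MI": "mi"}[method]
        stat = f[col].to_numpy()
        ids = list(zip(f["gene_a"], f["gene_b"]))
        span = float(np.log2(table.config.mi_bins)) if method == "MI" else 1.0
        thresholds = span * (1.0 - np.arange(1, n_steps + 1) / n_steps)
        first = np.where(
            np.isnan(stat),
            n_steps + 1,
            np.maximum(1, np.ceil(n_steps * (span - stat) / span)),
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return StringencySweep(
        method=method,
        mode=mode,
        thresholds=np.asarray(thresholds, dtype=float),
        pair_ids=tuple(ids),
        first_step=np.asarray(first, dtype=int),
    )


def inclusion_profile(
    sweep: StringencySweep,
    total_genes: int,
    target_coverage: float = 0.95,
) -> tuple[pd.DataFrame, int | None]:
    """Per-step percent of genes included and edge count.

    Returns the profile table and the first step at which the fraction of
    included genes reaches ``target_coverage`` (None if never reached).
    """
    v = sweep.vertex_counts()
    e = sweep.edge_counts()
    percent = 100.0 * v / total_genes
    frame = pd.DataFrame(
        {
            "step": np.arange(1, sweep.n_steps + 1),
            "threshold": sweep.thresholds,
            "n_vertices": v,
            "percent_genes": percent,
            "n_edges": e,
        }
    )
    reached = np.flatnonzero(v >= target_coverage * total_genes)
    target_step = int(reached[0]) + 1 if len(reached) else None
    return frame, target_step


def select_graph_at_size(
    sweep: StringencySweep,
    target_size: int,
    match_on: Literal["genes", "pairs"] = "genes",
) -> GeneGraph:
    """Most stringent step whose size first reaches ``target_size``."""
    counts = sweep.vertex_counts() if match_on == "genes" else sweep.edge_counts()
    reached = np.flatnonzero(counts >= target_size)
    if not len(reached):
        raise ValueError(
            f"no step reaches {match_on} size {target_size} "
            f"(max {counts[-1] if len(counts) else 0})"
        )
    return sweep.step(int(reached[0]) + 1)


def method_overlap(
    graphs: dict[str, GeneGraph],
    match_on: Literal["genes", "pairs"] = "genes",
) -> pd.DataFrame:
    """Exclusive-region counts for the Venn partition of 2–3 method graphs.

    Each row is one region (e.g. ``RA``, ``RA&PE``, ``RA&PE&MI``) with its
    exclusive element count and its fraction of the union.
    """
    if not 2 <= len(graphs) <= 3:
        raise ValueError("method_overlap expects two or three graphs")
    sets: dict[str, set] = {}
    for name, graph in graphs.items():
        sets[name] = set(graph.vertices if match_on == "genes" else graph.edges)
    names = list(sets)
    union = set().union(*sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            exclusive = inside - outside
            rows.append(
                {
                    "region": "&".join(combo),
                    "count": len(exclusive),
                    "union_fraction": len(exclusive) / len(union) if union else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

MEASURE_LABELS = {
    "mi": "I",
    "pearson_r2": "R2",
    "pearson_r": "r",
    "delta_cv": "delta_CV",
    "cv_ab": "CV(A/B)",
    "cv_ba": "CV(B/A)",
}


def measure_correlation_matrix(table: PairTable) -> pd.DataFrame:
    """Pearson correlations between the per-pair statistics.

    Rows/columns: I, R², r, delta_CV, CV(A/B), CV(B/A).  Pairs with
    unevaluable ratio statistics are excluded pairwise (NaN-aware).
    """
    cols = list(MEASURE_LABELS)
    sub = table.frame[cols].rename(columns=MEASURE_LABELS)
    return sub.corr(method="pearson")


def invariance_diagnostic(
    matrix: ExpressionMatrix,
    table: PairTable,
    top_k: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Does per-gene expression invariance alone explain RA rank?

    For every gene appearing in a gate-passing pair: its own CV(FPKM)
    across samples and the minimum stability over its gated pairs.  The
    returned R² is the squared Pearson correlation between the two across
    the ``top_k`` best-ranked genes (all genes if None); a low value means
    RA rank is not mere expression invariance.
    """
    gated = _gated(table)
    best: dict[str, float] = {}
    for _, row in gated.iterrows():
        for g in (row["gene_a"], row["gene_b"]):
            s = row["stability"]
            if g not in best or s < best[g]:
                best[g] = s
    if not best:
        raise ValueError("no gate-passing pairs; nothing to diagnose")
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=table.config.cv_ddof)
    rows = []
    for g, s in best.items():
        i = gene_index[g]
        gene_cv = sds[i] / means[i] if means[i] > 0 else np.nan
        rows.append({"gene": g, "gene_cv": gene_cv, "best_stability": s})
    frame = (
        pd.DataFrame(rows)
        .sort_values(["best_stability", "gene"])
        .reset_index(drop=True)
    )
    top = frame.head(top_k) if top_k is not None else frame
    if top["gene_cv"].nunique() < 2 or top["best_stability"].nunique() < 2:
        r2 = 0.0
    else:
        _, r2 = pearson_association(
            top["gene_cv"].to_numpy(), top["best_stability"].to_numpy()
        )
    return frame, float(r2)


def two_regime_flag(
    a: np.ndarray,
    b: np.ndarray,
    high_fraction: float = 0.1,
    r2_drop: float = 0.5,
) -> bool:
    """Heuristic for association driven by a small highly-expressed subgroup.

    Flags the pair when removing the top ``high_fraction`` of samples
    (ranked by a+b) drops the pairwise R² by more than ``r2_drop``.
    Symmetric in gene order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    n_drop = max(1, int(np.ceil(high_fraction * n)))
    order = np.argsort(a + b, kind="stable")
    keep = order[: n - n_drop]
    try:
        _, r2_full = pearson_association(a, b)
    except DegenerateInputError:
        return False
    try:
        _, r2_reduced = pearson_association(a[keep], b[keep])
    except DegenerateInputError:
        r2_reduced = 0.0
    return (r2_full - r2_reduced) > r2_drop


def ranking_consistency(
    ranking_1: Sequence,
    ranking_2: Sequence,
    depths: Iterable[int],
) -> pd.DataFrame:
    """Top-k overlap between two rankings over a shared pair universe.

    At each depth k the overlap fraction is
    ``|top-k(r1) ∩ top-k(r2)| / k``; identical rankings give 1 at every
    depth, unrelated rankings give about k / N.
    """
    r1 = [_canonical(p) for p in ranking_1]
    r2 = [_canonical(p) for p in ranking_2]
    rows = []
    for k in depths:
        top1 = set(r1[:k])
        top2 = set(r2[:k])
        rows.append({"depth": k, "overlap_fraction": len(top1 & top2) / k})
    return pd.DataFrame(rows)


def _canonical(pair) -> tuple:
    a, b = pair
    return (a, b) if a <= b else (b, a)
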