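"""Longitudinal microbiome dynamics and interaction-network inference.

Two complementary views of how the community moves between time points:

* :func:`rank_trends` collapses the log table at a coarse rank (phylum or
  class) and tracks per-time-point means, flagging taxa with a monotone
  trend over the surgical course (Spearman of value against time index).
* :func:`infer_network` fits, for every taxon *i*, an ordinary least-squares
  regression of its within-subject change ``y_i = x_i(t+1) − x_i(t)`` on the
  levels of all taxa at *t* (self included).  Coefficients surviving a
  Bonferroni correction over all taxa² tests at level alpha become directed
  signed edges j → i; the published picture keeps only the largest weakly
  connected component.

Pairs are formed between *consecutive sampled* time points within a subject
(A<B<C<D<E); a missing intermediate visit simply lengthens the step.  Lean
controls have a single time point and contribute no pairs by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .normalize import collapse_to_rank
from .tables import TIMEPOINT_ORDER, FeatureTable


@dataclass
class DeltaPair:
    """One within-subject step: levels at t and the change to the next visit."""

    subject_id: str
    t_from: str
    t_to: str
    x_from: np.ndarray
    delta: np.ndarray


@dataclass
class InteractionNetwork:
    """Directed signed graph of Bonferroni-significant delta regressions."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, beta, p_raw, sign
    alpha: float
    n_tests: int
    coef_matrix: np.ndarray | None = None  # full beta matrix, target x source
    pval_matrix: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, beta=row.beta,
                       p_raw=row.p_raw, sign=row.sign)
        return g

    def write_edge_list(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def summary(self) -> str:
        pos = int((self.edges["sign"] > 0).sum())
        neg = int((self.edges["sign"] < 0).sum())
        return (
            "Interaction network from delta regressions\n"
            f"  taxa: {len(self.nodes)}\n"
            f"  significant edges: {self.n_edges} ({pos} positive, {neg} negative)\n"
            f"  alpha: {self.alpha} with Bonferroni over {self.n_tests} tests"
        )


def rank_trends(table: FeatureTable, meta: pd.DataFrame,
                rank: str = "phylum") -> pd.DataFrame:
    """Per-taxon, per-time-point means with a monotone-trend flag.

    Expects a log-stage table.  For each taxon collapsed at ``rank``,
    reports mean ± SD at every time point present (A..E and H) and a
    Spearman trend of sample values against the A..E time index: flag +1
    for a significant increase, −1 for a decrease, 0 otherwise, NaN when
    fewer than two obese time points are sampled.
    """
    if table.stage != "logged":
        raise ValueError("rank_trends expects a log-stage table")
    collapsed = collapse_to_rank(table, rank)
    meta = meta.loc[collapsed.sample_ids]
    tp = meta["timepoint"]
    records = []
    obese_mask = tp.isin(list(TIMEPOINT_ORDER)).to_numpy()
    time_index = tp.map(TIMEPOINT_ORDER).to_numpy(dtype=float)
    for taxon in collapsed.feature_ids:
        values = collapsed.data[taxon].to_numpy()
        rec = {"taxon": taxon}
        for code in sorted(tp.unique()):
            sel = (tp == code).to_numpy()
            rec[f"mean_{code}"] = float(values[sel].mean())
            rec[f"sd_{code}"] = float(values[sel].std())
        x = time_index[obese_mask]
        y = values[obese_mask]
        if len(np.unique(x)) < 2:
            rec["trend_rho"], rec["trend_p"], rec["trend"] = np.nan, np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
            rec["trend_rho"] = float(rho)
            rec["trend_p"] = float(p)
            rec["trend"] = float(np.sign(rho)) if p < 0.05 else 0.0
        records.append(rec)
    return pd.DataFrame(records).set_index("taxon")


def build_delta_pairs(table: FeatureTable, meta: pd.DataFrame) -> list[DeltaPair]:
    """Within-subject steps between consecutive sampled time points.

    One pair per adjacent sampled pair (ordering A<B<C<D<E); lean (H) and
    single-visit subjects contribute none.  A subject sampled twice at one
    time point is an error.
    """
    if table.stage != "logged":
        raise ValueError("delta pairs are defined on the log-stage table")
    meta = meta.loc[table.sample_ids]
    pairs: list[DeltaPair] = []
    obese = meta[meta["timepoint"].isin(list(TIMEPOINT_ORDER))]
    for subject, sub in obese.groupby("subject_id", sort=True):
        if sub["timepoint"].duplicated().any():
            code = sub.loc[sub["timepoint"].duplicated(), "timepoint"].iloc[0]
            raise ValueError(f"subject {subject!r} sampled twice at {code!r}")
        ordered = sub.sort_values("timepoint", key=lambda s: s.map(TIMEPOINT_ORDER))
        sample_ids = list(ordered.index)
        for a, b in zip(sample_ids[:-1], sample_ids[1:]):
            x_from = table.data.loc[a].to_numpy()
            x_to = table.data.loc[b].to_numpy()
            pairs.append(DeltaPair(
                subject_id=str(subject),
                t_from=str(ordered.loc[a, "timepoint"]),
                t_to=str(ordered.loc[b, "timepoint"]),
                x_from=x_from,
                delta=x_to - x_from,
            ))
    return pairs


def infer_network(pairs: list[DeltaPair], taxa: list[str],
                  alpha: float = 0.05, include_self: bool = True,
                  max_condition: float = 1e8) -> InteractionNetwork:
    """OLS of each taxon's delta on all taxa's levels, Bonferroni-thresholded.

    ``taxa`` names the coordinates of the pair vectors.  The design pools
    every pair across subjects and transitions; an intercept is included.
    The Bonferroni denominator is the number of tested coefficients
    (taxa², or taxa×(taxa−1) without self terms).
    """
    if not pairs:
        raise ValueError("no delta pairs supplied")
    n_taxa = len(taxa)
    X = np.stack([p.x_from for p in pairs])
    Y = np.stack([p.delta for p in pairs])
    if X.shape[0] <= n_taxa:
        raise ValueError(
            f"only {X.shape[0]} pairs for {n_taxa} taxa; OLS is not "
            "identifiable — collapse to a coarser rank")
    cond = np.linalg.cond(X - X.mean(axis=0))
    if cond > max_condition:
        raise ValueError(f"rank-deficient design (condition number {cond:.3g})")

    n_tests = n_taxa * n_taxa if include_self else n_taxa * (n_taxa - 1)
    threshold = alpha / n_tests
    coef = np.full((n_taxa, n_taxa), np.nan)   # [target, source]
    pval = np.full((n_taxa, n_taxa), np.nan)
    rows = []
    for i in range(n_taxa):
        sources = list(range(n_taxa)) if include_self else \
            [j for j in range(n_taxa) if j != i]
        design = sm.add_constant(X[:, sources])
        fit = sm.OLS(Y[:, i], design).fit()
        # degenerate exact fit (noiseless dynamics): the t-test is 0/0, so
        # fall back to a numerical-zero threshold on the coefficients
        exact = fit.mse_resid < 1e-20
        for k, j in enumerate(sources):
            beta = fit.params[k + 1]
            if exact:
                p = 0.0 if abs(beta) > 1e-10 else 1.0
            else:
                p = fit.pvalues[k + 1]
            coef[i, j] = beta
            pval[i, j] = p
            if p <= threshold:
                rows.append({"source": taxa[j], "target": taxa[i],
                             "beta": float(beta), "p_raw": float(p),
                             "sign": int(np.sign(beta))})
    edges = pd.DataFrame(rows, columns=["source", "target", "beta", "p_raw", "sign"])
    return InteractionNetwork(nodes=list(taxa), edges=edges, alpha=alpha,
                              n_tests=n_tests, coef_matrix=coef, pval_matrix=pval)


def main_component(network: InteractionNetwork) -> InteractionNetwork:
    """Restrict to the largest weakly connected component of the edge graph.

    Nodes without any significant edge are not part of any component.  Size
    ties are broken toward the component containing the lexicographically
    smallest member.  An empty network stays empty.
    """
    if network.n_edges == 0:
        return InteractionNetwork(nodes=[], edges=network.edges.iloc[0:0].copy(),
                                  alpha=network.alpha, n_tests=network.n_tests)
    g = nx.DiGraph()
    for row in network.edges.itertuples(index=False):
        g.add_edge(row.source, row.target)
    components = list(nx.weakly_connected_components(g))
    components.sort(key=lambda c: (-len(c), min(c)))
    keep = components[0]
    edges = network.edges[
        network.edges["source"].isin(keep) & network.edges["target"].isin(keep)
    ].copy()
    return InteractionNetwork(nodes=sorted(keep), edges=edges,
                              alpha=network.alpha, n_tests=network.n_tests)


class InteractionModel:
    """Model object: delta-regression network over a logged table + metadata."""

    def __init__(self, pairs: list[DeltaPair], taxa: list[str]):
        self.pairs = pairs
        self.taxa = taxa

    @classmethod
    def from_table(cls, table: FeatureTable, meta: pd.DataFrame,
                   rank: str | None = "class") -> "InteractionModel":
        """Collapse the logged table at ``rank`` (None = as-is) and build pairs."""
        work = collapse_to_rank(table, rank) if rank is not None else table
        pairs = build_delta_pairs(work, meta)
        return cls(pairs, work.feature_ids)

    def fit(self, alpha: float = 0.05, include_self: bool = True,
            restrict_to_main_component: bool = False) -> InteractionNetwork:
        net = infer_network(self.pairs, self.taxa, alpha=alpha,
                            include_self=include_self)
        if restrict_to_main_component:
            net = main_component(net)
        return net
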