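"""Weighted coexpression modules, top-hub eigen-proteins, and ORA screening.

The pipeline follows the weighted-correlation-network recipe: pairwise
Pearson correlation of protein expression profiles, soft-thresholded
adjacency a_ij = ((1 + r_ij)/2)^power (signed convention; the unsigned
|r|^power and the literal (1 - r)/2 similarity are selectable),
topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu,

average-linkage hierarchical clustering of the dissimilarity 1 - TOM,
and a simplified dynamic-hybrid tree cut (static cut at a
deepSplit-mapped fraction of the dendrogram height; branches below
``min_module_size`` stay unassigned). Each module is summarized by its
top hub — the member with the highest intramodular connectivity —
called the eigen-protein, whose expression profile is correlated with
0/1 clinical-trait indicators.

Modules are screened against externally defined protein groups (e.g.
trait-unique or Rsc-upregulated sets) by one-sided hypergeometric
over-representation tests with Benjamini-Hochberg q-values computed
over all module x group cells as a single family; a module passes the
screen when its *maximum* q across the groups is below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from saavkit.core_io import SaavkitError

log = logging.getLogger("saavkit.netmod")

UNASSIGNED = "unassigned"

SIMILARITY_CONVENTIONS = ("signed", "unsigned", "literal_paper")

#: deepSplit sensitivity ladder -> fraction of the maximum merge height at
#: which the tree is cut. Higher sensitivity cuts nearer the top, so
#: branches separated only by the final merges still come apart into
#: modules; lower values demand tighter branches and leave more proteins
#: unassigned.
DEEP_SPLIT_CUT_FRACTION = {0: 0.90, 1: 0.93, 2: 0.95, 3: 0.97, 4: 0.99}


@dataclass(frozen=True)
class NetworkConfig:
    soft_power: float = 15.0
    similarity_convention: str = "signed"
    min_module_size: int = 30
    deep_split: int = 4
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.deep_split not in DEEP_SPLIT_CUT_FRACTION:
            raise ValueError("deep_split must be an integer in 0..4")
        if self.similarity_convention not in SIMILARITY_CONVENTIONS:
            raise ValueError(f"similarity_convention must be one of {SIMILARITY_CONVENTIONS}")


@dataclass
class ModuleAssignment:
    """Protein -> module labels plus per-module hubs and connectivities."""

    labels: dict[str, str]
    modules: dict[str, list[str]] = field(default_factory=dict)
    eigen_proteins: dict[str, str] = field(default_factory=dict)
    connectivity: dict[str, float] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return sorted(self.modules, key=lambda m: int(m.lstrip("WM")))


def correlation_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between protein rows.

    Zero-variance rows are excluded with a warning; fewer than three
    samples is an error (a correlation needs df > 0).
    """
    if expression.shape[1] < 3:
        raise SaavkitError("correlation requires at least 3 samples")
    variances = expression.var(axis=1, ddof=0)
    flat = variances[variances == 0].index
    if len(flat):
        log.warning("excluding %d zero-variance protein(s): %s", len(flat), list(flat)[:5])
        expression = expression.drop(index=flat)
    values = np.corrcoef(expression.to_numpy(dtype=float))
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return pd.DataFrame(values, index=expression.index, columns=expression.index)


def adjacency(corr: pd.DataFrame, config: NetworkConfig) -> pd.DataFrame:
    """Soft-thresholded adjacency with zeroed diagonal."""
    r = corr.to_numpy(dtype=float)
    if config.similarity_convention == "signed":
        sim = (1.0 + r) / 2.0
    elif config.similarity_convention == "unsigned":
        sim = np.abs(r)
    else:  # literal_paper: (1 - r)/2, a dissimilarity used as similarity
        sim = (1.0 - r) / 2.0
    a = sim**config.soft_power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix; unit diagonal, entries in [0, 1]."""
    is_frame = isinstance(adj, pd.DataFrame)
    a = adj.to_numpy(dtype=float) if is_frame else np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (l + a) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    if is_frame:
        return pd.DataFrame(t, index=adj.index, columns=adj.columns)
    return t


def cluster_modules(tom_matrix: pd.DataFrame, config: NetworkConfig) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a simplified dynamic cut.

    The dendrogram is cut at ``DEEP_SPLIT_CUT_FRACTION[deep_split]``
    times its maximum merge height; resulting clusters smaller than
    ``min_module_size`` are unassigned. Modules are labelled WM1, WM2,
    ... in decreasing size order (ties broken by smallest member name),
    which makes the output deterministic and permutation-equivariant.
    """
    proteins = list(tom_matrix.index)
    n = len(proteins)
    assignment = ModuleAssignment(labels={p: UNASSIGNED for p in proteins})
    if n < config.min_module_size:
        log.warning("only %d proteins (< min_module_size %d): all unassigned", n, config.min_module_size)
        return assignment
    diss = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method=config.linkage_method)
    cut_height = DEEP_SPLIT_CUT_FRACTION[config.deep_split] * z[:, 2].max()
    flat = fcluster(z, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for protein, c in zip(proteins, flat):
        clusters.setdefault(int(c), []).append(protein)
    qualifying = [m for m in clusters.values() if len(m) >= config.min_module_size]
    qualifying.sort(key=lambda m: (-len(m), min(m)))
    for i, members in enumerate(qualifying, start=1):
        label = f"WM{i}"
        assignment.modules[label] = sorted(members)
        for p in members:
            assignment.labels[p] = label
    return assignment


def eigen_protein(members: Sequence[str], adj: pd.DataFrame) -> str:
    """The module's top hub: member with the highest intramodular connectivity.

    Connectivity of member i is the sum of adjacency to the other
    members; ties break lexicographically by name.
    """
    if not members:
        raise ValueError("empty module")
    sub = adj.loc[list(members), list(members)]
    k_in = sub.sum(axis=1)
    best = min(k_in.index[k_in == k_in.max()])
    return best


def fill_eigen_proteins(assignment: ModuleAssignment, adj: pd.DataFrame) -> None:
    """Populate per-module eigen-proteins and member intramodular connectivities."""
    for label, members in assignment.modules.items():
        sub = adj.loc[members, members]
        k_in = sub.sum(axis=1)
        for p in members:
            assignment.connectivity[p] = float(k_in[p])
        assignment.eigen_proteins[label] = eigen_protein(members, adj)


def module_trait_correlation(
    eigen_profile: Sequence[float], trait_indicator: Sequence[int]
) -> tuple[float, float]:
    """Point-biserial Pearson r of an eigen-protein profile with a 0/1 trait.

    Two-sided p comes from the t-transform t = r sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(eigen_profile, dtype=float)
    y = np.asarray(trait_indicator, dtype=float)
    if len(x) < 3:
        raise SaavkitError("correlation requires at least 3 samples")
    if np.all(y == y[0]):
        raise SaavkitError("trait indicator is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class OraResult:
    """Module x group over-representation table with BH q-values."""

    table: pd.DataFrame  # columns: module, group, module_size, group_size, overlap, p, q
    max_q: pd.Series  # per module, max q across groups
    screened: pd.Series  # per module, max_q < threshold
    q_threshold: float

    @property
    def ranked_modules(self) -> list[str]:
        return list(self.max_q.sort_values(kind="stable").index)


def ora_screen(
    assignment: ModuleAssignment,
    groups: Mapping[str, set[str]],
    universe: set[str],
    q_threshold: float = 0.05,
) -> OraResult:
    """Hypergeometric over-representation of each module in each protein group.

    For a module of size n drawn from a universe of size N containing a
    group of size K, the upper-tail p is P(X >= overlap) under the
    hypergeometric law. BH q-values are computed across all
    module x group cells as one family. A module is screened in when its
    maximum q across the groups is below ``q_threshold``; modules are
    ranked by that maximum q ascending.
    """
    for gname, gset in groups.items():
        if not gset <= universe:
            raise SaavkitError(f"group {gname!r} is not a subset of the universe")
    rows = []
    n_universe = len(universe)
    for label, members in sorted(assignment.modules.items()):
        module_set = set(members) & universe
        for gname in sorted(groups):
            gset = groups[gname]
            overlap = len(module_set & gset)
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(gset), len(module_set)))
            rows.append(
                {
                    "module": label,
                    "group": gname,
                    "module_size": len(module_set),
                    "group_size": len(gset),
                    "overlap": overlap,
                    "p": min(p, 1.0),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        max_q = table.groupby("module")["q"].max()
    else:
        table["q"] = pd.Series(dtype=float)
        max_q = pd.Series(dtype=float)
    screened = max_q < q_threshold
    return OraResult(table=table, max_q=max_q, screened=screened, q_threshold=q_threshold)


def fit_network(
    expression: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[ModuleAssignment, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience chain: correlation -> adjacency -> TOM -> modules -> hubs.

    Returns (assignment, correlation, adjacency, TOM).
    """
    config = config or NetworkConfig()
    corr = correlation_matrix(expression)
    adj = adjacency(corr, config)
    t = tom(adj)
    assignment = cluster_modules(t, config)
    fill_eigen_proteins(assignment, adj)
    return assignment, corr, adj, t
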