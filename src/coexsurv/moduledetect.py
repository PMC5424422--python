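"""Module detection on the TOM dissimilarity.

Average-linkage (UPGMA) hierarchical clustering of 1 − TOM, a hybrid
tree cut (static cut at a height threshold, minimum branch size, then a
PAM-like adoption stage for leftover genes), module eigengenes as the first
principal component of each module's standardized expression, and the
eigengene dendrogram.

Module labels follow the conventional colour sequence by decreasing module
size ("turquoise" is always the largest); "grey" collects unassigned genes
and is not itself a module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Conventional module colour sequence, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge tree: a scipy linkage matrix plus the leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Render the merge tree as a Newick string with branch lengths
        derived from merge heights (iterative; safe for large trees)."""
        z = self.linkage
        n = len(self.labels)
        height = np.concatenate([np.zeros(n), z[:, 2]])
        children = {n + k: (int(z[k, 0]), int(z[k, 1]))
                    for k in range(len(z))}
        rendered: dict[int, str] = {}
        root = n + len(z) - 1
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < n:
                rendered[node] = self.labels[node]
                continue
            a, b = children[node]
            if not expanded:
                stack.extend([(node, True), (a, False), (b, False)])
            else:
                la = height[node] - height[a]
                lb = height[node] - height[b]
                rendered[node] = (f"({rendered[a]}:{la:.10g},"
                                  f"{rendered[b]}:{lb:.10g})")
        return rendered[root] + ";"


def _check_dissimilarity(diss: pd.DataFrame) -> np.ndarray:
    d = diss.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not diss.index.equals(diss.columns):
        raise ValueError("dissimilarity must be square with matching labels")
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity diagonal must be zero")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(diss: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a square symmetric dissimilarity matrix."""
    d = _check_dissimilarity(diss)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, [str(g) for g in diss.index])


# ---------------------------------------------------------------------------
# hybrid tree cut
# ---------------------------------------------------------------------------

def cut_tree_hybrid(dendro: Dendrogram, diss: pd.DataFrame,
                    cut_height: float = 0.95,
                    min_size: int = 30) -> pd.Series:
    """Cut the dendrogram into modules.

    Stage 1: a static cut at ``cut_height`` yields candidate branches.
    Stage 2: branches with ≥ ``min_size`` leaves become modules.
    Stage 3 (PAM-like adoption): every remaining gene is assigned to the
    module with the smallest mean dissimilarity to its members, provided
    (a) that mean is smaller than the gene's mean dissimilarity to all
    non-module genes and (b) that mean is within the clustering radius
    ``cut_height``; otherwise the gene stays grey.

    Returns a Series gene → colour label, colours assigned by decreasing
    module size; all-grey (with a warning) when no branch reaches
    ``min_size``.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must be in (0, 1]")
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    d = _check_dissimilarity(diss)
    genes = list(diss.index)
    if dendro.labels != [str(g) for g in genes]:
        raise ValueError("dendrogram labels do not match dissimilarity")

    flat = hierarchy.fcluster(dendro.linkage, t=cut_height,
                              criterion="distance")
    branches: dict[int, np.ndarray] = {}
    for cl in np.unique(flat):
        members = np.where(flat == cl)[0]
        if members.size >= min_size:
            branches[cl] = members
    if not branches:
        warnings.warn("no branch reached min_size; all genes grey")
        return pd.Series(GREY, index=diss.index, name="module")

    assign = np.full(len(genes), -1, dtype=int)
    mods = sorted(branches, key=lambda c: (-branches[c].size, branches[c][0]))
    for mi, cl in enumerate(mods):
        assign[branches[cl]] = mi

    # stage 3: adoption of leftover genes
    member_mask = assign >= 0
    mean_to_mod = np.column_stack([
        d[:, assign == mi].mean(axis=1) for mi in range(len(mods))])
    for g in np.where(~member_mask)[0]:
        mi = int(np.argmin(mean_to_mod[g]))
        inside = assign == mi
        outside = ~inside
        outside[g] = False
        if not outside.any():
            continue
        avg_in = mean_to_mod[g, mi]
        avg_out = d[g, outside].mean()
        if avg_in < avg_out and avg_in <= cut_height:
            assign[g] = mi

    # colour labels by decreasing final size (stable on the stage-2 order)
    sizes = np.bincount(assign[assign >= 0], minlength=len(mods))
    order = sorted(range(len(mods)), key=lambda mi: (-sizes[mi], mi))
    names = {}
    for rank, mi in enumerate(order):
        names[mi] = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                     else f"module{rank + 1}")
    labels = [names[a] if a >= 0 else GREY for a in assign]
    part = pd.Series(labels, index=diss.index, name="module")
    logger.info("detected %d modules (sizes %s); %d genes grey",
                len(mods), sorted(sizes, reverse=True),
                int((part == GREY).sum()))
    return part


# ---------------------------------------------------------------------------
# module eigengenes
# ---------------------------------------------------------------------------

@dataclass
class EigengeneResult:
    """Module eigengenes and memberships.

    ``eigengenes``: modules × samples, each row the first principal
    component of the module's standardized expression (zero mean, unit
    norm, sign oriented so the mean member kME is positive).
    ``kme``: per-gene Pearson correlation with its own module's eigengene
    (NaN for grey genes).  ``var_explained``: fraction of the module's
    standardized variance carried by the eigengene.
    """

    eigengenes: pd.DataFrame
    kme: pd.Series
    var_explained: pd.Series


def module_eigengene(expr: pd.DataFrame,
                     partition: pd.Series) -> EigengeneResult:
    """First-principal-component eigengene of every (non-grey) module."""
    partition = partition.reindex(expr.index)
    if partition.isna().any():
        raise ValueError("partition does not cover all genes")
    modules = [m for m in partition.unique() if m != GREY]
    if not modules:
        raise ValueError("partition contains no modules")
    mes, varex = {}, {}
    kme = pd.Series(np.nan, index=expr.index, name="kme")
    for mod in modules:
        members = partition.index[partition == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        x = expr.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        if (sd == 0).any():
            gene = members[int(np.argmax(sd == 0))]
            raise ValueError(f"constant gene {gene!r} in module {mod!r}")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        me = vt[0]
        member_kme = _rowwise_pearson(xs, me)
        if member_kme.mean() < 0:
            me = -me
            member_kme = -member_kme
        mes[mod] = me
        kme.loc[members] = member_kme
        varex[mod] = float(s[0] ** 2 / (s ** 2).sum())
    eig = pd.DataFrame(mes, index=expr.columns).T
    eig.index.name = "module"
    return EigengeneResult(eig, kme, pd.Series(varex, name="var_explained"))


def _rowwise_pearson(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    num = rc @ vc
    den = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    return num / den


def eigengene_dendrogram(eigengenes: pd.DataFrame) -> Dendrogram:
    """Average-linkage tree of modules on dissimilarity 1 − cor(ME_i, ME_j)."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 modules to cluster eigengenes; "
                         "a single module makes this a no-op")
    r = np.corrcoef(eigengenes.to_numpy(dtype=float))
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return average_linkage(pd.DataFrame(d, index=eigengenes.index,
                                        columns=eigengenes.index))


def project_partition(expr_val: pd.DataFrame,
                      partition: pd.Series) -> EigengeneResult:
    """Recompute module eigengenes in an independent validation matrix.

    Modules are taken as defined on the discovery data; gene memberships
    are intersected with the validation matrix's gene symbols and each
    module's eigengene is recomputed as the first principal component of
    the intersected member expression.  Modules reduced below 2 shared
    genes are dropped (logged).
    """
    shared = expr_val.index.intersection(partition.index)
    sub = partition.loc[shared].copy()
    for mod in [m for m in sub.unique() if m != GREY]:
        if (sub == mod).sum() < 2:
            logger.warning("module %s has <2 genes in validation data; "
                           "dropped", mod)
            sub[sub == mod] = GREY
    return module_eigengene(expr_val.loc[shared], sub)
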