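"""Gene-set over-representation analysis and ward.D2 hierarchical clustering.

ORA scores a query gene list against each gene set with the one-sided
upper-tail hypergeometric test, followed by Benjamini-Hochberg adjustment
across the tested terms.  The multiple-testing strategy is BH throughout
(recorded in the result metadata), chosen over service-specific schemes
for transparency and reproducibility.

Clustering implements Ward's minimum-variance agglomeration in the
ward.D2 convention: the Lance-Williams recurrence runs on squared
Euclidean dissimilarities and merge heights are reported on the unsquared
(square-root) scale.  Ties are broken deterministically by the smallest
pair of cluster indices.  Rows are typically scaled to mean 0 / SD 1
before clustering, mirroring standard heatmap preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import pdist, squareform

from .diffstats import adjust_bh
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of detected genes."""

    sets: dict[str, tuple[str, frozenset[str]]]  # term id -> (name, members)
    universe: frozenset[str]

    @classmethod
    def from_gmt(cls, path, universe: set[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file (term, description, members...) and restrict
        members to the universe; empty post-restriction sets are dropped."""
        raw: dict[str, tuple[str, frozenset[str]]] = {}
        members_all: set[str] = set()
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"GMT line {i}: expected >= 3 tab-separated fields")
                term, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                raw[term] = (name, frozenset(genes))
                members_all.update(genes)
        uni = frozenset(universe if universe is not None else members_all)
        sets = {}
        for term, (name, genes) in raw.items():
            restricted = genes & uni
            if restricted:
                sets[term] = (name, restricted)
        return cls(sets, uni)


ORA_COLUMNS = ["term", "name", "k", "K", "n", "N", "p_value", "p_adj", "genes"]


def hypergeometric_ora(
    query: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query gene list.

    Query genes outside the universe are dropped with a warning.  Results
    carry BH-adjusted p-values, are filtered at p_adj <= alpha, and sorted
    by p.  The frame's ``attrs["adjustment"]`` records the BH choice.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    outside = set(query) - collection.universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
    q = set(query) & collection.universe
    out = pd.DataFrame(columns=ORA_COLUMNS)
    out.attrs["adjustment"] = "benjamini-hochberg"
    if not q:
        logger.warning("empty query after universe restriction")
        return out
    N = len(collection.universe)
    n = len(q)
    rows = []
    for term, (name, members) in collection.sets.items():
        K = len(members)
        overlap = q & members
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append([term, name, k, K, n, N, p, np.nan, ";".join(sorted(overlap))])
    res = pd.DataFrame(rows, columns=ORA_COLUMNS)
    res["p_adj"] = adjust_bh(res["p_value"].to_numpy())
    res = res[res["p_adj"] <= alpha].sort_values("p_value").reset_index(drop=True)
    res.attrs["adjustment"] = "benjamini-hochberg"
    return res


# ---------------------------------------------------------------------------
# row scaling


def scale_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Scale each row to mean 0 and SD 1 (n-1 denominator).

    Constant rows (zero variance) are emitted as zeros and returned in the
    flagged list.
    """
    X = matrix.to_numpy(dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    flagged = list(matrix.index[(sd == 0).ravel() | ~np.isfinite(sd).ravel()])
    if flagged:
        logger.warning("%d constant rows scaled to zeros", len(flagged))
    safe_sd = np.where((sd > 0) & np.isfinite(sd), sd, 1.0)
    Z = (X - mean) / safe_sd
    Z[((sd == 0) | ~np.isfinite(sd)).ravel(), :] = 0.0
    return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns), flagged


# ---------------------------------------------------------------------------
# ward.D2 clustering


@dataclass
class ClusterResult:
    """Agglomeration in scipy linkage layout plus the ordered matrix."""

    merges: np.ndarray  # (n-1, 4): idx_a, idx_b, height, cluster size
    leaf_order: list
    scaled: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def write(self, merge_path, order_path) -> None:
        pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        ).to_csv(merge_path, sep="\t", index=False)
        pd.Series(self.leaf_order, name="leaf").to_csv(order_path, sep="\t", index=False)


def ward_d2_cluster(matrix: pd.DataFrame, axis: str = "rows") -> ClusterResult:
    """Ward minimum-variance agglomeration in the ward.D2 convention.

    The Lance-Williams recurrence updates squared Euclidean
    dissimilarities with Ward coefficients,

        D2(m, k) = [(n_i + n_k) D2(i,k) + (n_j + n_k) D2(j,k)
                    - n_k D2(i,j)] / (n_i + n_j + n_k),

    and heights are the square roots of the merged squared
    dissimilarities.  The minimum pair is chosen with a deterministic
    tie-break on the smallest (i, j) cluster-index pair.
    """
    if axis not in ("rows", "columns"):
        raise ConfigError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix if axis == "rows" else matrix.T
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ConfigError("clustering requires >= 2 items")
    if not np.all(np.isfinite(X)):
        raise ConfigError("clustering input contains non-finite values")

    n = X.shape[0]
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    np.fill_diagonal(D2, np.inf)
    active = list(range(n))  # positions into D2; ids map clusters scipy-style
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        sub = D2[np.ix_(active, active)]
        flat = np.argmin(sub)
        best = sub.flat[flat]
        # deterministic tie-break: smallest (id_i, id_j) pair among minima
        cand = np.argwhere(np.isclose(sub, best, rtol=0.0, atol=0.0))
        pairs = sorted(
            (min(ids[a], ids[b]), max(ids[a], ids[b]), a, b)
            for a, b in cand
            if a < b
        )
        _, _, ai, bj = pairs[0]
        pi, pj = active[ai], active[bj]
        id_i, id_j = ids[ai], ids[bj]
        d2_ij = D2[pi, pj]
        new_id = n + step
        new_size = sizes[id_i] + sizes[id_j]
        merges[step] = [min(id_i, id_j), max(id_i, id_j), np.sqrt(d2_ij), new_size]

        # Lance-Williams Ward update written into row/col pi
        for ak, pk in zip(range(len(active)), [active[k] for k in range(len(active))]):
            if pk in (pi, pj):
                continue
            nk = sizes[ids[ak]]
            ni, nj = sizes[id_i], sizes[id_j]
            d2_new = (
                (ni + nk) * D2[pi, pk] + (nj + nk) * D2[pj, pk] - nk * d2_ij
            ) / (ni + nj + nk)
            D2[pi, pk] = D2[pk, pi] = d2_new
        sizes[new_id] = new_size
        ids[ai] = new_id
        del active[bj], ids[bj]

    leaf_idx = leaves_list(merges)
    labels = list(data.index)
    leaf_order = [labels[i] for i in leaf_idx]
    ordered = data.iloc[leaf_idx] if axis == "rows" else matrix[ [labels[i] for i in leaf_idx] ]
    return ClusterResult(merges=merges, leaf_order=leaf_order, scaled=ordered)
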