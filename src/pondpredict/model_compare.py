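"""Comparison of predictability estimates across models.

Pipeline: Pearson correlations over ponds -> chord distance sqrt(2 - 2r) ->
UPGMA (average linkage) dendrogram -> bootstrap clade support -> threshold
cut into model clusters.

Conventions (documented because they vary between tools):

* merge heights are recorded as the full average-linkage distance, not half;
* ties in the minimum linkage distance are broken by the lexicographically
  smallest pair of sorted leaf-label tuples;
* bootstrap support is the plain bootstrap proportion (BP) of replicate trees
  containing the same leaf bipartition; replicates with degenerate
  (zero-variance) columns are skipped but stay in the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class EstimateMatrix:
    """ponds x models grid of predictability estimates, no missing cells.

    Rows and columns are sorted on construction so every downstream result is
    independent of input ordering.  Ponds with any missing estimate are
    dropped listwise (with a warning).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.sort_index(axis=0).sort_index(axis=1)
        incomplete = df.index[df.isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "dropping ponds with missing estimates (listwise): %s", list(incomplete)
            )
            df = df.drop(index=incomplete)
        self.values = df.astype(float)

    @property
    def pond_ids(self) -> list:
        return list(self.values.index)

    @property
    def model_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def without_ponds(self, exclude) -> "EstimateMatrix":
        keep = [p for p in self.values.index if p not in set(exclude)]
        return EstimateMatrix(self.values.loc[keep])


def estimate_matrix_from_records(records) -> EstimateMatrix:
    """Build an EstimateMatrix from PredictabilityEstimate-like records."""
    rows = [(r.pond_id, r.model, r.predictability) for r in records]
    df = pd.DataFrame(rows, columns=["pond_id", "model", "predictability"])
    wide = df.pivot(index="pond_id", columns="model", values="predictability")
    return EstimateMatrix(wide)


def correlation_matrix(est: EstimateMatrix, exclude_ponds=()) -> pd.DataFrame:
    """Pairwise Pearson correlation of model columns over ponds."""
    sub = est.without_ponds(exclude_ponds)
    data = sub.values
    if len(data) < 3:
        raise InputError("need at least 3 ponds to correlate models")
    stds = data.std(axis=0, ddof=1)
    dead = stds.index[stds == 0]
    if len(dead):
        raise EstimationError(
            f"zero-variance model column(s) {list(dead)}: correlation undefined"
        )
    corr = np.corrcoef(data.to_numpy(), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def chord_distance(r):
    """sqrt(2 - 2r); maps correlation 1 -> 0, 0 -> sqrt(2), -1 -> 2."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise InputError("correlation must lie in [-1, 1]")
    out = np.sqrt(np.maximum(2.0 - 2.0 * np.clip(arr, -1.0, 1.0), 0.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class Dendrogram:
    """UPGMA merge history over labeled leaves.

    ``merges`` lists (cluster_a, cluster_b, height, new_id) with leaves
    numbered 0..n-1 and internal nodes n, n+1, ...; heights never decrease.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def members(self) -> dict[int, frozenset]:
        """Leaf-label set of every node id."""
        out = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        for a, b, _, new in self.merges:
            out[new] = out[a] | out[b]
        return out

    def clades(self) -> set[frozenset]:
        """Leaf bipartitions of all internal nodes below the root."""
        members = self.members()
        all_leaves = frozenset(self.labels)
        return {
            members[new]
            for *_, new in self.merges
            if members[new] != all_leaves
        }

    def to_newick(self) -> str:
        members = self.members()
        texts = {i: _quote(lab) for i, lab in enumerate(self.labels)}
        node_height = {i: 0.0 for i in range(len(self.labels))}
        root = len(self.labels) - 1
        for a, b, h, new in self.merges:
            la = max(h - node_height[a], 0.0)
            lb = max(h - node_height[b], 0.0)
            sup = self.support.get(members[new])
            tag = "" if sup is None else f"{sup:.3f}"
            texts[new] = f"({texts[a]}:{la:g},{texts[b]}:{lb:g}){tag}"
            node_height[new] = h
            root = new
        return texts[root] + ";"


def _quote(label: str) -> str:
    return label if label.replace("_", "").isalnum() else f"'{label}'"


def _validate_distance(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=np.float64)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise InputError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise InputError("distances must be non-negative")
    return dist


def upgma(dist, labels=None) -> Dendrogram:
    """Average-linkage agglomeration with deterministic lexicographic ties."""
    dist = _validate_distance(dist)
    n = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = [str(l) for l in labels]
    if len(labels) != n:
        raise InputError("label count must match matrix size")

    # Active clusters: id -> (sorted leaf-label tuple, size).
    leaf_sets = {i: (tuple([labels[i]]), 1) for i in range(n)}
    d = {
        (i, j): dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best_pair, best_dist = None, np.inf
        for (i, j), val in d.items():
            if val < best_dist:
                better = True
            elif val == best_dist and best_pair is not None:
                key = tuple(sorted((leaf_sets[i][0], leaf_sets[j][0])))
                ref = tuple(sorted((leaf_sets[best_pair[0]][0], leaf_sets[best_pair[1]][0])))
                better = key < ref
            else:
                better = False
            if better:
                best_pair, best_dist = (i, j), val
        i, j = best_pair
        new_leaves = tuple(sorted(leaf_sets[i][0] + leaf_sets[j][0]))
        size = leaf_sets[i][1] + leaf_sets[j][1]
        merges.append((i, j, float(best_dist), next_id))
        for k in active - {i, j}:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(k, next_id)] = (
                leaf_sets[i][1] * dik + leaf_sets[j][1] * djk
            ) / size
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        active -= {i, j}
        active.add(next_id)
        leaf_sets[next_id] = (new_leaves, size)
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)


def model_dendrogram(est: EstimateMatrix, exclude_ponds=()) -> Dendrogram:
    """Correlate -> chord distance -> UPGMA in one step."""
    corr = correlation_matrix(est, exclude_ponds)
    return upgma(chord_distance(corr.to_numpy()), labels=list(corr.columns))


def bootstrap_support(est: EstimateMatrix, n_boot: int, seed: int,
                      exclude_ponds=()) -> Dendrogram:
    """Attach bootstrap-proportion clade support to the full-data dendrogram.

    Ponds are resampled with replacement; each replicate tree's clades vote
    for matching clades of the base tree.  Degenerate replicates (a model
    column with zero variance after resampling) are skipped but counted.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    sub = est.without_ponds(exclude_ponds)
    base = model_dendrogram(sub)
    target = base.clades()
    counts = {clade: 0 for clade in target}
    rng = np.random.default_rng(seed)
    n_ponds = len(sub.values)
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_ponds, size=n_ponds)
        resampled = EstimateMatrix(
            sub.values.iloc[idx].reset_index(drop=True)
        )
        try:
            tree = model_dendrogram(resampled)
        except (EstimationError, InputError):
            skipped += 1
            continue
        boot_clades = tree.clades()
        for clade in target:
            if clade in boot_clades:
                counts[clade] += 1
    if skipped:
        logger.info("bootstrap: skipped %d degenerate replicates of %d", skipped, n_boot)
    base.support = {clade: counts[clade] / n_boot for clade in target}
    return base


def cut_clusters(dendrogram: Dendrogram, threshold: float) -> list[set[str]]:
    """Partition leaves into groups connected by merges at height <= threshold."""
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    parent = {i: i for i in range(len(dendrogram.labels))}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members = dendrogram.members()
    for a, b, h, new in dendrogram.merges:
        parent[new] = new
        if h <= threshold:
            parent[find(a)] = new
            parent[find(b)] = new
    groups: dict[int, set[str]] = {}
    for i, lab in enumerate(dendrogram.labels):
        groups.setdefault(find(i), set()).add(lab)
    return sorted(groups.values(), key=lambda g: sorted(g))
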