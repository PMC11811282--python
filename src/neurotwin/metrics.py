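"""Analysis metrics: transfer entropy, silhouette width, k-NN assignment.

Transfer entropy quantifies the directed influence of the network-level
latents onto each region's deterministic dynamics (the functional-network
fingerprint).  The estimator is a discrete plug-in: both series are
quantile-binned, single-step histories are embedded, and the plug-in
estimate is bias-corrected by subtracting the mean over source-permuted
surrogates.  Silhouette width and k-NN (with leave-one-out selection of k)
assess and use the cluster structure of the global latent space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from scipy.stats import ttest_1samp


# --------------------------------------------------------------------------
# transfer entropy
# --------------------------------------------------------------------------
def _discretize(series: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin a series into integer codes ``0..n_bins-1``.

    Integer-valued series with at most ``n_bins`` distinct values are used
    as-is (exact discrete case, e.g. binary chains).
    """
    series = np.asarray(series, dtype=float).ravel()
    uniq = np.unique(series)
    if len(uniq) <= n_bins and np.allclose(uniq, np.round(uniq)):
        codes = np.searchsorted(uniq, series)
        return codes.astype(np.int64)
    qs = np.quantile(series, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, series, side="right").astype(np.int64)


def _plugin_te(src: np.ndarray, tgt: np.ndarray, n_bins: int,
               hist_target: int, hist_source: int) -> float:
    """Plug-in transfer entropy (nats) of discretized integer series."""
    n = len(tgt)
    L = max(hist_target, hist_source)
    if n - L < 2:
        raise ValueError("series too short for the history embedding")
    # embed histories as base-n_bins integers
    y1 = tgt[L:]
    y_hist = np.zeros(n - L, dtype=np.int64)
    for j in range(hist_target):
        y_hist = y_hist * n_bins + tgt[L - 1 - j:n - 1 - j]
    x_hist = np.zeros(n - L, dtype=np.int64)
    for j in range(hist_source):
        x_hist = x_hist * n_bins + src[L - 1 - j:n - 1 - j]
    ny = n_bins
    nyh = n_bins ** hist_target
    nxh = n_bins ** hist_source
    joint = np.bincount(
        (y1 * nyh + y_hist) * nxh + x_hist, minlength=ny * nyh * nxh
    ).reshape(ny, nyh, nxh).astype(float)
    N = joint.sum()
    p_yyx = joint / N
    p_yx = joint.sum(axis=0)            # (yh, xh)
    p_y1y = joint.sum(axis=2)           # (y1, yh)
    p_yh = joint.sum(axis=(0, 2))       # (yh,)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = joint * p_yh[None, :, None]
        den = p_y1y[:, :, None] * p_yx[None, :, :]
        logterm = np.where(joint > 0, np.log(num / den), 0.0)
    return float(np.sum(p_yyx * logterm))


@dataclass
class TransferEntropyResult:
    value: float          # bias-corrected estimate (nats)
    raw: float
    null_mean: float
    null_sd: float


def transfer_entropy(source, target, *, history: int = 1,
                     history_source: int | None = None, n_bins: int = 4,
                     n_permutations: int = 100,
                     rng: np.random.Generator | None = None, seed: int = 0,
                     full: bool = False):
    """Transfer entropy ``source -> target`` in nats, bias-corrected.

    The plug-in estimate on quantile-binned series is corrected by
    subtracting the mean estimate over ``n_permutations`` source-shuffled
    surrogates (which destroys the directed coupling but preserves the
    marginals).  Returns a float, or a :class:`TransferEntropyResult`
    when ``full=True``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    src = _discretize(source, n_bins)
    tgt = _discretize(target, n_bins)
    if len(src) != len(tgt):
        raise ValueError("source and target must have equal length")
    hs = history if history_source is None else history_source
    raw = _plugin_te(src, tgt, n_bins, history, hs)
    if n_permutations <= 0:
        return TransferEntropyResult(raw, raw, 0.0, 0.0) if full else raw
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _plugin_te(rng.permutation(src), tgt, n_bins, history, hs)
    value = raw - float(null.mean())
    if full:
        return TransferEntropyResult(value, raw, float(null.mean()),
                                     float(null.std()))
    return value


@dataclass
class TransferEntropyTable:
    """Sources x targets TE matrix with labelled axes.

    Rows: ``(fold, network-latent unit)``; columns: ``(region, condition)``.
    Under the reference geometry (3 network latents, 4 folds, 10 regions,
    2 conditions) this is the 12 x 20 fingerprint matrix.
    """

    data: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()

    def zscored(self) -> pd.DataFrame:
        """Matrix-wide z-score (single colour scale across all entries)."""
        m = self.matrix
        return pd.DataFrame((m - m.mean()) / m.std(),
                            index=self.data.index, columns=self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def te_matrix(traces: dict, regions, *, n_bins: int = 4,
              n_permutations: int = 100, seed: int = 0,
              history: int = 1) -> TransferEntropyTable:
    """TE fingerprints from network latents to region dynamics.

    ``traces`` maps ``(fold, condition)`` to a pair ``(z2, d1)`` with
    ``z2`` of shape ``(T, L2)`` and ``d1`` of shape ``(T, R, D1)`` (or
    ``(T, R)`` if already aggregated).  The target series of a region is
    the mean of its deterministic outputs per step.
    """
    folds = sorted({f for f, _ in traces})
    conditions = sorted({c for _, c in traces})
    regions = list(regions)
    first = next(iter(traces.values()))
    L2 = first[0].shape[1]
    rows = []
    index = []
    rng = np.random.default_rng(seed)
    for fold in folds:
        for unit in range(L2):
            row = {}
            for cond in conditions:
                if (fold, cond) not in traces:
                    raise KeyError(f"missing trace for fold={fold}, "
                                   f"condition={cond}")
                z2, d1 = traces[(fold, cond)]
                d1 = np.asarray(d1, dtype=float)
                tgt = d1 if d1.ndim == 2 else d1.mean(axis=2)
                for r, reg in enumerate(regions):
                    row[(reg, cond)] = transfer_entropy(
                        z2[:, unit], tgt[:, r], history=history,
                        n_bins=n_bins, n_permutations=n_permutations,
                        rng=rng)
            rows.append(row)
            index.append((fold, unit))
    cols = pd.MultiIndex.from_tuples(
        [(reg, cond) for reg in regions for cond in conditions],
        names=["region", "condition"])
    idx = pd.MultiIndex.from_tuples(index, names=["fold", "unit"])
    df = pd.DataFrame(rows, index=idx)[cols]
    return TransferEntropyTable(df, params=dict(
        n_bins=n_bins, n_permutations=n_permutations, history=history))


# --------------------------------------------------------------------------
# silhouette width
# --------------------------------------------------------------------------
@dataclass
class ClusterAssessment:
    s: np.ndarray
    mean: float
    labels: np.ndarray
    k: int | None = None


def silhouette_width(points, labels) -> ClusterAssessment:
    """Per-point silhouette width in Euclidean space.

    ``a(i)`` is the mean distance to the other members of the point's own
    cluster, ``b(i)`` the smallest mean distance to any other cluster, and
    ``s(i) = (b - a) / max(a, b)``.  Points in singleton clusters get
    ``s = 0``.  Requires at least two clusters.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette width needs at least two clusters")
    D = cdist(points, points)
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        b = np.inf
        for lab in uniq:
            if lab == labels[i]:
                continue
            members = labels == lab
            b = min(b, D[i, members].mean())
        if n_own < 2:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        s[i] = (b - a) / max(a, b)
    return ClusterAssessment(s=s, mean=float(s.mean()), labels=labels)


def mean_silhouette_positive(s_values):
    """One-sided one-sample t-test that the mean silhouette exceeds zero."""
    res = ttest_1samp(np.asarray(s_values, dtype=float), 0.0,
                      alternative="greater")
    return float(res.statistic), float(res.pvalue)


def assign_by_silhouette(point, clusters: dict):
    """Classify a point into the candidate cluster giving the larger s(i).

    ``clusters`` maps label -> member points.  The silhouette of the point
    is evaluated under each hypothetical membership; ties go to the first
    label in canonical sorted order.
    """
    point = np.asarray(point, dtype=float).ravel()
    labels = sorted(clusters.keys(), key=str)
    if len(labels) < 2:
        raise ValueError("need at least two candidate clusters")
    mean_d = {}
    for lab in labels:
        members = np.atleast_2d(np.asarray(clusters[lab], dtype=float))
        if members.shape[0] == 0:
            raise ValueError(f"cluster {lab!r} is empty")
        mean_d[lab] = float(cdist(point[None, :], members).mean())
    best_lab, best_s = None, -np.inf
    for lab in labels:
        a = mean_d[lab]
        b = min(mean_d[other] for other in labels if other != lab)
        s = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        if s > best_s:
            best_lab, best_s = lab, s
    return best_lab


# --------------------------------------------------------------------------
# k-NN with leave-one-out selection of k
# --------------------------------------------------------------------------
@dataclass
class KnnResult:
    labels: np.ndarray
    proportions: dict
    k: int
    loocv_accuracy: float


def _majority(votes: np.ndarray):
    """Majority label; ties go to the first label in sorted order."""
    uniq, counts = np.unique(votes, return_counts=True)
    return uniq[np.argmax(counts)]


def knn_assign(queries, reference_points, reference_labels, *,
               k_candidates=None) -> KnnResult:
    """k-NN classification with k chosen by leave-one-out cross-validation.

    Candidate k values are odd (to avoid two-class vote ties); the k
    maximising LOOCV accuracy on the reference set wins (smallest k on
    ties).  Queries are then classified by Euclidean majority vote.
    """
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    lab = np.asarray(reference_labels)
    n_ref = ref.shape[0]
    if n_ref == 0:
        raise ValueError("reference set is empty")
    if k_candidates is None:
        k_candidates = list(range(1, min(15, n_ref - 1) + 1, 2))
    k_candidates = sorted(int(k) for k in k_candidates)
    if any(k % 2 == 0 for k in k_candidates):
        raise ValueError("candidate k values must be odd")
    if k_candidates[-1] > n_ref - 1:
        raise ValueError("fewer reference points than largest k + 1")

    D = cdist(ref, ref)
    np.fill_diagonal(D, np.inf)      # leave-one-out: exclude self
    order = np.argsort(D, axis=1)
    best_k, best_acc = k_candidates[0], -1.0
    for k in k_candidates:
        pred = np.array([_majority(lab[order[i, :k]]) for i in range(n_ref)])
        acc = float(np.mean(pred == lab))
        if acc > best_acc:
            best_k, best_acc = k, acc

    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    Dq = cdist(queries, ref)
    oq = np.argsort(Dq, axis=1)
    labels = np.array([_majority(lab[oq[i, :best_k]])
                       for i in range(queries.shape[0])])
    uniq, counts = np.unique(labels, return_counts=True)
    proportions = {u: c / len(labels) for u, c in zip(uniq, counts)}
    return KnnResult(labels=labels, proportions=proportions, k=best_k,
                     loocv_accuracy=best_acc)


# --------------------------------------------------------------------------
# hierarchical clustering of TE fingerprints
# --------------------------------------------------------------------------
@dataclass
class RowClustering:
    groups: np.ndarray       # group id per row, 1-based, order of appearance
    group_names: list
    linkage: np.ndarray
    newick: str
    row_labels: list


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return str(labels[node.id])
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    return f"({left},{right})"


def cluster_te_rows(table: TransferEntropyTable,
                    n_groups: int = 3) -> RowClustering:
    """Average-linkage clustering of z-scored TE rows into FN groups.

    Rows (network-latent fingerprints) whose TE profiles across regions and
    conditions are similar merge into the same functional-network group.
    """
    Z_df = table.zscored()
    rows = Z_df.to_numpy()
    if rows.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    link = hierarchy.linkage(rows, method="average", metric="euclidean")
    flat = hierarchy.fcluster(link, t=min(n_groups, rows.shape[0]),
                              criterion="maxclust")
    # stable relabel by first appearance -> FN1, FN2, ...
    remap: dict[int, int] = {}
    groups = np.empty_like(flat)
    for i, g in enumerate(flat):
        remap.setdefault(g, len(remap) + 1)
        groups[i] = remap[g]
    names = [f"FN{g}" for g in sorted(set(groups))]
    row_labels = ["/".join(str(p) for p in idx) if isinstance(idx, tuple)
                  else str(idx) for idx in Z_df.index]
    tree = hierarchy.to_tree(link)
    newick = _tree_to_newick(tree, row_labels) + ";"
    return RowClustering(groups=groups, group_names=names, linkage=link,
                         newick=newick, row_labels=row_labels)
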