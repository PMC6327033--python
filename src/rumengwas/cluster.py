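"""Hierarchical clustering of animals with multiscale-bootstrap cluster support.

Animals are clustered on their selected-contig CPM profiles with correlation
distance (1 - Pearson) and average linkage (UPGMA).  Cluster uncertainty is
assessed pvclust-style: contigs (features) are resampled with replacement at a
grid of scales r (resample size ceil(r * p)), the animals are re-clustered, and
each original internal edge's bootstrap probability BP_r is the fraction of
replicates whose dendrogram contains that edge's exact leaf set.  The
approximately unbiased (AU) p-value extrapolates across scales: with
psi(r) = Phi^-1(1 - BP_r), a two-parameter curve psi(r) = v*sqrt(r) + c/sqrt(r)
is fitted by weighted least squares (binomial weights), and AU = 1 - Phi(v - c).
BP values of exactly 0 or 1 are moved off the boundary with the continuity
correction (count + 0.5) / (b + 1) before the probit transform; an edge present
in every replicate at every scale is reported with AU = 1 (absent everywhere,
AU = 0) without fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import GROUP_HIGH, GROUP_LOW, AbundanceMatrix, DataError, PhenotypeTable

logger = logging.getLogger("rumengwas")

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


# ---------------------------------------------------------------------------
# Dendrogram container
# ---------------------------------------------------------------------------

@dataclass
class SupportedDendrogram:
    """UPGMA merge tree over animals, optionally annotated with BP/AU support.

    ``linkage`` is a scipy linkage matrix; ``edges`` maps each internal node's
    leaf-set bitmask to a record with the member animal ids, merge height and —
    after :func:`multiscale_bootstrap` — bp_by_scale, bp1, au and fit
    diagnostics.
    """

    leaf_ids: list
    linkage: np.ndarray
    edges: pd.DataFrame
    scales: tuple = ()
    n_boot: int = 0
    seed: int | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Newick string with au/bp edge annotations in comment blocks."""
        n = self.n_leaves
        has_support = "au" in self.edges.columns
        masks = _subtree_masks(self.linkage, n)

        def node(i: int) -> str:
            if i < n:
                return str(self.leaf_ids[i])
            row = self.linkage[i - n]
            left, right, height = int(row[0]), int(row[1]), row[2]
            label = ""
            if has_support:
                mask = masks[i - n]
                if mask in self.edges.index:
                    e = self.edges.loc[mask]
                    label = f"[&&au={e['au']:.3f},bp={e['bp1']:.3f}]"
            return f"({node(left)},{node(right)}){label}:{height:.6g}"

        return node(2 * n - 2) + ";"


def _correlation_distance(X: np.ndarray, sample_ids) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows; errors on flat profiles."""
    sds = X.std(axis=1, ddof=0)
    flat = np.where(sds == 0)[0]
    if len(flat):
        raise DataError(f"zero-variance profile for animal(s) {[sample_ids[i] for i in flat]}")
    corr = np.corrcoef(X)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return squareform(d, checks=False)


def _subtree_masks(linkage: np.ndarray, n: int) -> list[int]:
    """Leaf-set bitmask of each internal node, in merge order."""
    masks: list[int] = []
    for k in range(linkage.shape[0]):
        left, right = int(linkage[k, 0]), int(linkage[k, 1])
        m = 0
        for child in (left, right):
            m |= (1 << child) if child < n else masks[child - n]
        masks.append(m)
    return masks


def _mask_members(mask: int, leaf_ids) -> tuple:
    return tuple(leaf_ids[i] for i in range(len(leaf_ids)) if mask >> i & 1)


def log2_cpm(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2(1 + x) transform of an abundance matrix, for clustering and PCA.

    Raw CPM span orders of magnitude across contigs, so a Pearson-correlation
    distance on the linear scale is dominated by the handful of most abundant
    contigs; the log transform gives every selected contig comparable leverage.
    """
    out = AbundanceMatrix.__new__(AbundanceMatrix)
    out.data = np.log2(m.data + 1.0)
    out.unit = m.unit
    return out


def hcluster(m: AbundanceMatrix, metric: str = "correlation") -> SupportedDendrogram:
    """Average-linkage (UPGMA) clustering of animals on their feature profiles.

    ``metric`` is ``correlation`` (1 - Pearson, the default of the multiscale
    bootstrap tooling this mirrors) or ``euclidean``.
    """
    if m.n_samples < 3:
        raise DataError("need at least 3 samples to cluster")
    if m.n_features < 2:
        raise DataError("need at least 2 features to cluster")
    X = m.values
    if metric == "correlation":
        cond = _correlation_distance(X, m.sample_ids)
    elif metric == "euclidean":
        cond = squareform(np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)), checks=False)
    else:
        raise DataError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(cond, method="average")
    n = m.n_samples
    masks = _subtree_masks(Z, n)
    edges = pd.DataFrame(
        {
            "members": [_mask_members(mk, m.sample_ids) for mk in masks],
            "size": [bin(mk).count("1") for mk in masks],
            "height": Z[:, 2],
        },
        index=pd.Index(masks, name="leaf_mask"),
    )
    return SupportedDendrogram(leaf_ids=list(m.sample_ids), linkage=Z, edges=edges)


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------

def scale_rng(seed: int, r: float) -> np.random.Generator:
    """Independent random stream for one resampling scale.

    Keyed by (seed, round(1000*r)) so the replicate stream at a given scale —
    and hence BP at that scale — does not depend on which other scales are in
    the grid.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, int(round(1000 * r)))))


def _boot_edge_counts(X: np.ndarray, sample_ids, masks: list[int], scales,
                      b_per_scale: int, seed: int,
                      metric: str) -> np.ndarray:
    """counts[e, s] = replicates at scale s whose dendrogram contains edge e.

    Each scale has its own seeded stream (:func:`scale_rng`); each replicate
    draws ceil(r * p) feature indices with one rng.integers call.
    """
    n, p = X.shape
    counts = np.zeros((len(masks), len(scales)), dtype=int)
    mask_pos = {mk: i for i, mk in enumerate(masks)}
    for s, r in enumerate(scales):
        m_feat = int(math.ceil(r * p))
        rng = scale_rng(seed, r)
        for _ in range(b_per_scale):
            idx = rng.integers(0, p, size=m_feat)
            Xb = X[:, idx]
            sds = Xb.std(axis=1, ddof=0)
            if metric == "correlation":
                if (sds == 0).any():
                    continue  # flat profile in a replicate: no edge can be scored
                cond = squareform(np.clip(1.0 - np.corrcoef(Xb), 0, 2), checks=False)
            else:
                cond = squareform(
                    np.sqrt(((Xb[:, None, :] - Xb[None, :, :]) ** 2).sum(-1)), checks=False)
            Zb = hierarchy.linkage(cond, method="average")
            for mk in _subtree_masks(Zb, n):
                pos = mask_pos.get(mk)
                if pos is not None:
                    counts[pos, s] += 1
    return counts


def _fit_au(counts: np.ndarray, scales: np.ndarray, b: int) -> tuple[float, float, float, int]:
    """Fit psi(r) = v*sqrt(r) + c/sqrt(r) by WLS; return (au, residual, v-c, dof).

    Boundary counts are moved off 0/1 with (count + 0.5) / (b + 1).  Weights
    are the delta-method binomial weights b * phi(psi)^2 / (bp * (1 - bp)).
    """
    bp = counts.astype(float) / b
    boundary = (counts == 0) | (counts == b)
    bp_adj = np.where(boundary, (counts + 0.5) / (b + 1.0), bp)
    psi = stats.norm.ppf(1.0 - bp_adj)
    w = b * stats.norm.pdf(psi) ** 2 / (bp_adj * (1.0 - bp_adj))
    sq = np.sqrt(scales)
    A = np.column_stack([sq, 1.0 / sq])
    Aw = A * w[:, None]
    coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ psi, rcond=None)
    v, c = coef
    resid = float(np.sum(w * (psi - A @ coef) ** 2))
    dof = len(scales) - 2
    au = float(1.0 - stats.norm.cdf(v - c))
    return au, resid, float(v - c), dof


def multiscale_bootstrap(m: AbundanceMatrix, scales=DEFAULT_SCALES,
                         b_per_scale: int = 1000, seed: int = 0,
                         metric: str = "correlation") -> SupportedDendrogram:
    """Cluster the animals and attach multiscale-bootstrap BP/AU support.

    Contigs are resampled (size ceil(r*p), with replacement) ``b_per_scale``
    times per scale r; the animals are re-clustered per replicate.  Per edge:
    bp_by_scale (raw count/b), bp1 (BP at the scale closest to 1), the AU
    p-value from the probit extrapolation, and fit diagnostics.
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) < 2:
        raise DataError("need at least 2 scales for the AU fit")
    if b_per_scale < 100:
        raise DataError("b_per_scale must be >= 100 for a stable AU fit")
    dendro = hcluster(m, metric=metric)
    masks = list(dendro.edges.index)
    counts = _boot_edge_counts(m.values, m.sample_ids, masks,
                               scales, b_per_scale, seed, metric)
    scale_arr = np.asarray(scales)
    s1 = int(np.argmin(np.abs(scale_arr - 1.0)))
    bp_by_scale, au, bp1, resid, vc, flags = [], [], [], [], [], []
    for e in range(len(masks)):
        row = counts[e]
        bp_by_scale.append({s: row[i] / b_per_scale for i, s in enumerate(scales)})
        bp1.append(row[s1] / b_per_scale)
        if (row == b_per_scale).all():
            au.append(1.0); resid.append(0.0); vc.append(-np.inf); flags.append("always present")
        elif (row == 0).all():
            au.append(0.0); resid.append(0.0); vc.append(np.inf); flags.append("never observed")
        else:
            try:
                a, rs, d, _ = _fit_au(row, scale_arr, b_per_scale)
                au.append(a); resid.append(rs); vc.append(d); flags.append("")
            except np.linalg.LinAlgError:
                au.append(np.nan); resid.append(np.nan); vc.append(np.nan)
                flags.append("fit failure")
    edges = dendro.edges.copy()
    edges["bp_by_scale"] = bp_by_scale
    edges["bp1"] = bp1
    edges["au"] = au
    edges["fit_residual"] = resid
    edges["v_minus_c"] = vc
    edges["flag"] = flags
    edges["fit_dof"] = len(scales) - 2
    return SupportedDendrogram(leaf_ids=dendro.leaf_ids, linkage=dendro.linkage,
                               edges=edges, scales=scales, n_boot=b_per_scale, seed=seed)


# ---------------------------------------------------------------------------
# Cluster accuracy and nested clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAccuracyReport:
    k: int
    predicted: pd.Series         # animal -> cluster id
    accuracy: float              # best over cluster->label assignments
    contingency: pd.DataFrame


def cluster_accuracy(d: SupportedDendrogram, truth: dict | pd.Series, k: int = 2) -> ClusterAccuracyReport:
    """Cut the dendrogram into k clusters and score against known labels.

    Accuracy is the concordant fraction maximized over one-to-one
    cluster -> label assignments (Hungarian matching on the contingency table).
    """
    if k > d.n_leaves:
        raise DataError(f"k={k} exceeds {d.n_leaves} leaves")
    truth = pd.Series(truth)
    missing = [a for a in d.leaf_ids if a not in truth.index]
    if missing:
        raise DataError(f"no truth label for animal(s) {missing[:5]}")
    clusters = hierarchy.fcluster(d.linkage, t=k, criterion="maxclust")
    pred = pd.Series(clusters, index=d.leaf_ids, name="cluster")
    cont = pd.crosstab(pred, truth.loc[d.leaf_ids])
    from scipy.optimize import linear_sum_assignment
    cost = -cont.to_numpy()
    # pad to square so every cluster can map to at most one label
    size = max(cost.shape)
    padded = np.zeros((size, size))
    padded[: cost.shape[0], : cost.shape[1]] = cost
    rows, cols = linear_sum_assignment(padded)
    matched = -padded[rows, cols].sum()
    acc = matched / len(pred)
    return ClusterAccuracyReport(k=k, predicted=pred, accuracy=float(acc), contingency=cont)


def nested_group_clustering(m: AbundanceMatrix, phen: PhenotypeTable,
                            inner_trait: str, assoc_inner: pd.DataFrame,
                            scales=DEFAULT_SCALES, b_per_scale: int = 1000,
                            seed: int = 0, alpha: float = 0.05,
                            log_transform: bool = True) -> dict:
    """Cluster animals on inner-trait-selected contigs within each outer FE group.

    Within each HIGH/LOW FE subgroup the animals are re-labelled HIGH/LOW on
    ``inner_trait`` (median split), clustered on the contigs significant in
    ``assoc_inner`` (log2-transformed by default, like the main clustering
    stage), and scored.  Composite class labels follow the
    H-Hdmi / H-Ldmi / L-Hdmi / L-Ldmi convention.  Subgroups smaller than 3
    are skipped with a warning.
    """
    feats = list(assoc_inner.index[assoc_inner["significant"]])
    if not feats:
        raise DataError("no significant inner-trait contigs to cluster on")
    out = {}
    for outer in (GROUP_HIGH, GROUP_LOW):
        animals = [a for a in m.sample_ids if phen.data.loc[a, "group"] == outer]
        if len(animals) < 3:
            logger.warning("outer group %s has %d (<3) animals; skipped", outer, len(animals))
            out[outer] = None
            continue
        sub = m.restrict(feats)
        subm = AbundanceMatrix.__new__(AbundanceMatrix)
        subm.data = sub.data.loc[animals]
        subm.unit = sub.unit
        if log_transform:
            subm = log2_cpm(subm)
        tv = phen.data.loc[animals, inner_trait].astype(float)
        med = tv.median()
        inner = pd.Series(np.where(tv > med, GROUP_HIGH, GROUP_LOW), index=animals)
        composite = {a: f"{outer[0]}-{inner[a][0]}{inner_trait}" for a in animals}
        dendro = multiscale_bootstrap(subm, scales=scales, b_per_scale=b_per_scale, seed=seed)
        report = cluster_accuracy(dendro, inner, k=2)
        out[outer] = {"dendrogram": dendro, "report": report,
                      "inner_labels": inner, "composite_labels": composite}
    return out


def top_split_edges(d: SupportedDendrogram) -> pd.DataFrame:
    """Edge records of the root's two child clusters (the top two-cluster split)."""
    n = d.n_leaves
    masks = _subtree_masks(d.linkage, n)
    root = d.linkage[-1]
    child_masks = []
    for child in (int(root[0]), int(root[1])):
        child_masks.append((1 << child) if child < n else masks[child - n])
    return d.edges.loc[[mk for mk in child_masks if mk in d.edges.index]]


def pca_scores(m: AbundanceMatrix, n_components: int = 2) -> pd.DataFrame:
    """First principal-component coordinates of the animals (column-centered SVD).

    Sign convention: each component's largest-magnitude loading is positive.
    """
    if m.n_samples < 3:
        raise DataError("need at least 3 animals for PCA")
    X = m.values - m.values.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=pd.Index(m.sample_ids, name="sample_id"),
                        columns=[f"PC{i+1}" for i in range(k)])


def write_edges_tsv(d: SupportedDendrogram, path) -> None:
    cols = [c for c in ("members", "size", "height", "bp1", "au", "flag") if c in d.edges.columns]
    d.edges[cols].to_csv(path, sep="\t")
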