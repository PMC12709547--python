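"""Group-level cluster-based permutation inference and FDR post-hocs.

One-sample (or paired-difference) t maps over a domain — time points,
time-frequency grids, or parcels on an adjacency graph — are thresholded
at a cluster-forming t value; contiguous suprathreshold points of equal
sign form clusters scored by mass (summed t). Significance comes from a
sign-flip null: subject maps are multiplied by random signs and the
maximum |mass| over both signs is collected (a max-statistic two-tailed
convention that controls family-wise error without doubling).

When 2^n_subjects <= n_perm the full set of sign assignments is
enumerated, making p-values exact, deterministic, and invariant to
subject ordering; otherwise assignments are drawn with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

__all__ = [
    "StatMap",
    "ClusterResult",
    "one_sample_t_map",
    "cluster_permutation_test",
    "bh_adjust",
    "posthoc_fdr",
    "read_adjacency",
    "write_cluster_result",
]

_GRID_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connected


@dataclass
class StatMap:
    """Per-subject values over a common domain.

    values: (n_subjects, *domain_shape). ``domain`` is one of ``"time"``,
    ``"time_frequency"``, ``"parcels"``; parcel domains require an
    adjacency edge list (pairs of parcel indices).
    """

    values: np.ndarray
    domain: str = "time"
    adjacency: np.ndarray | None = None
    coords: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        expected_ndim = {"time": 2, "time_frequency": 3, "parcels": 2}
        if self.domain not in expected_ndim:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.values.ndim != expected_ndim[self.domain]:
            raise ValueError(
                f"domain {self.domain!r} expects values of ndim "
                f"{expected_ndim[self.domain]}, got {self.values.ndim}"
            )
        if self.domain == "parcels" and self.adjacency is None:
            raise ValueError("parcel domains require an adjacency edge list")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape[1:]


@dataclass
class ClusterResult:
    """Suprathreshold clusters, masses, and permutation p-values."""

    clusters: list[np.ndarray]  # flat index arrays into the domain
    masses: np.ndarray
    p_values: np.ndarray
    threshold: float
    n_perm: int
    tail: str
    shape: tuple[int, ...]
    t_map: np.ndarray | None = None
    exhaustive: bool = False

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [i for i, p in enumerate(self.p_values) if p < alpha]

    def mask(self, index: int) -> np.ndarray:
        m = np.zeros(int(np.prod(self.shape)), bool)
        m[self.clusters[index]] = True
        return m.reshape(self.shape)


def one_sample_t_map(maps: StatMap | np.ndarray) -> np.ndarray:
    """Elementwise t = mean / (sd / sqrt(n)); zero-variance points get t=0.

    Paired contrasts reduce to the same computation on difference maps.
    """
    X = maps.values if isinstance(maps, StatMap) else np.asarray(maps, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def _adjacency_matrix(n: int, edges: np.ndarray) -> scipy.sparse.csr_matrix:
    edges = np.asarray(edges, int)
    if edges.size == 0:
        return scipy.sparse.csr_matrix((n, n))
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise ValueError("adjacency must be an (n_edges, 2) index array")
    data = np.ones(len(edges))
    A = scipy.sparse.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return ((A + A.T) > 0).tocsr()


def _clusters_from_mask(mask: np.ndarray, adjacency: scipy.sparse.csr_matrix | None):
    """Connected components of a boolean domain mask; yields flat index arrays."""
    if adjacency is not None:  # parcel graph
        flat = mask.ravel()
        idx = np.flatnonzero(flat)
        if idx.size == 0:
            return
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, labels = scipy.sparse.csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            yield idx[labels == c]
    elif mask.ndim == 1:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):
            yield seg
    else:
        lab, n_lab = scipy.ndimage.label(mask, structure=_GRID_STRUCTURE)
        if n_lab == 0:
            return
        flat = lab.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_flat = flat[order]
        first = np.searchsorted(sorted_flat, np.arange(1, n_lab + 1))
        last = np.searchsorted(sorted_flat, np.arange(1, n_lab + 1), side="right")
        for a, b in zip(first, last):
            yield order[a:b]


def _signed_clusters(t: np.ndarray, threshold: float, adjacency):
    """(indices, mass) for positive and negative suprathreshold clusters."""
    out = []
    tf = t.ravel()
    for sign in (1.0, -1.0):
        mask = (sign * t) > threshold
        for idx in _clusters_from_mask(mask, adjacency):
            out.append((idx, float(tf[idx].sum())))
    return out


def _null_stat(t: np.ndarray, threshold: float, adjacency, tail: str) -> float:
    masses = [m for _, m in _signed_clusters(t, threshold, adjacency)]
    if tail == "pos":
        masses = [m for m in masses if m > 0]
    elif tail == "neg":
        masses = [-m for m in masses if m < 0]
    else:
        masses = [abs(m) for m in masses]
    return max(masses) if masses else 0.0


def _sign_matrix(n_subjects: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """All 2^n sign assignments if affordable, else n_perm random draws."""
    if 2 ** n_subjects <= n_perm:
        bits = np.arange(2 ** n_subjects)[:, None] >> np.arange(n_subjects)[None, :]
        return 1.0 - 2.0 * (bits & 1), True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def cluster_permutation_test(
    maps: StatMap,
    threshold: float,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "two-sided",
) -> ClusterResult:
    """Sign-flip cluster permutation test of subject maps against zero.

    ``tail="two-sided"`` (default) uses the max-|mass| statistic over both
    signs, controlling family-wise error without doubling. Note that under
    sign flipping every assignment is paired with its complement (which
    mirrors the t map exactly), so the smallest attainable two-sided p is
    2 / 2^n_subjects; directional hypotheses at small n should use
    ``tail="pos"`` or ``tail="neg"``, whose null is the max mass of the
    corresponding sign only (and which report only that sign's clusters).
    """
    if tail not in ("two-sided", "pos", "neg"):
        raise ValueError(f"unknown tail {tail!r}")
    X = maps.values
    n = maps.n_subjects
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    adjacency = None
    if maps.domain == "parcels":
        adjacency = _adjacency_matrix(X.shape[1], maps.adjacency)

    t_obs = one_sample_t_map(maps)
    observed = _signed_clusters(t_obs, threshold, adjacency)
    if tail == "pos":
        observed = [(idx, m) for idx, m in observed if m > 0]
    elif tail == "neg":
        observed = [(idx, m) for idx, m in observed if m < 0]

    signs, exhaustive = _sign_matrix(n, n_perm, seed)
    n_draws = signs.shape[0]
    flat = X.reshape(n, -1)
    sumsq = (flat ** 2).sum(axis=0)
    null_max = np.empty(n_draws)
    chunk = max(1, int(5e6 / max(flat.shape[1], 1)))
    shape = maps.shape
    pos = 0
    for start in range(0, n_draws, chunk):
        s = signs[start:start + chunk]
        means = (s @ flat) / n
        var = np.maximum(sumsq[None, :] - n * means ** 2, 0.0) / (n - 1)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(sd > 0, means / (sd / np.sqrt(n)), 0.0)
        for row in t_perm:
            null_max[pos] = _null_stat(row.reshape(shape), threshold, adjacency, tail)
            pos += 1

    clusters, masses, pvals = [], [], []
    for idx, mass in observed:
        # tolerance guards against float noise between the observed t map
        # and the identity permutation's recomputed t map
        crit = abs(mass) * (1.0 - 1e-9)
        if exhaustive:
            p = float(np.mean(null_max >= crit))
        else:
            p = float((1 + np.sum(null_max >= crit)) / (1 + n_draws))
        clusters.append(idx)
        masses.append(mass)
        pvals.append(p)
    return ClusterResult(
        clusters=clusters,
        masses=np.array(masses),
        p_values=np.array(pvals),
        threshold=threshold,
        n_perm=n_draws,
        tail=tail,
        shape=shape,
        t_map=t_obs,
        exhaustive=exhaustive,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def posthoc_fdr(comparisons: list[dict], q: float = 0.05):
    """One-sample / paired t-tests with Benjamini-Hochberg correction.

    Each comparison is a dict: ``name``, ``kind`` ("one_sample" or
    "paired"), ``a`` (per-subject scalars), and ``b`` for paired contrasts.
    Returns a DataFrame with raw and BH-adjusted p per comparison.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    if not comparisons:
        raise ValueError("empty comparison family")
    rows = []
    for comp in comparisons:
        a = np.asarray(comp["a"], float)
        if comp.get("kind", "one_sample") == "paired":
            b = np.asarray(comp["b"], float)
            stat, p = scipy.stats.ttest_rel(a, b)
        else:
            stat, p = scipy.stats.ttest_1samp(a, 0.0)
        rows.append({"name": comp["name"], "kind": comp.get("kind", "one_sample"),
                     "t": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(df["p_raw"], alpha=q, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["reject"] = reject
    return df


def read_adjacency(path) -> np.ndarray:
    """Two-column whitespace-separated parcel-index edge list."""
    edges = np.loadtxt(path, dtype=int, ndmin=2)
    if edges.shape[1] != 2:
        raise ValueError("adjacency file must have two columns")
    return edges


def write_cluster_result(path, result: ClusterResult) -> None:
    import json

    payload = {
        "threshold": result.threshold,
        "n_perm": result.n_perm,
        "tail": result.tail,
        "exhaustive": result.exhaustive,
        "shape": list(result.shape),
        "clusters": [c.tolist() for c in result.clusters],
        "masses": result.masses.tolist(),
        "p_values": result.p_values.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
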