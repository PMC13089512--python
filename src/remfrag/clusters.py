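"""Cluster-based Monte-Carlo permutation inference.

Nonparametric multiple-comparison correction in the Maris-Oostenveld style:
point-wise statistics (paired/one-sample t, or Pearson r against a
behavioral covariate) are thresholded at the cluster-formation alpha,
adjacent suprathreshold points of equal sign are grouped (2-D
time-frequency adjacency, or a channel-neighborhood graph built from
montage coordinates), and each cluster's mass (sum of the point statistics)
is compared with the permutation distribution of the maximum absolute
cluster mass: random sign flips of per-subject maps for paired designs,
random reassignment of the behavioral covariate for correlations.
Monte-Carlo p uses the add-one rule, so p is never below 1/(n_permutations+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import Delaunay

N_PERMUTATIONS_DEFAULT = 5000
CLUSTER_ALPHA_DEFAULT = 0.05
ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# channel adjacency

@dataclass(frozen=True)
class ChannelAdjacency:
    """Symmetric, irreflexive channel-neighbor structure."""

    matrix: np.ndarray                  # (n_ch, n_ch) bool
    ch_names: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, bool)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ch_names):
            raise ValueError("adjacency must be square and match ch_names")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(m)):
            raise ValueError("adjacency must be irreflexive")

    @property
    def isolated(self) -> list[str]:
        deg = self.matrix.sum(axis=1)
        return [c for c, d in zip(self.ch_names, deg) if d == 0]

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.matrix]

    def reorder(self, order: list[int]) -> "ChannelAdjacency":
        idx = np.asarray(order)
        return ChannelAdjacency(
            matrix=self.matrix[np.ix_(idx, idx)],
            ch_names=tuple(self.ch_names[i] for i in idx),
        )


def _azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Project 3D scalp positions to the plane (polar angle preserves distance)."""
    p = np.asarray(pos3d, float)
    p = p / np.linalg.norm(p, axis=1, keepdims=True)
    theta = np.arccos(np.clip(p[:, 2], -1, 1))
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.c_[theta * np.cos(phi), theta * np.sin(phi)]


def adjacency_from_positions(
    pos3d: np.ndarray, ch_names: list[str], prune_factor: float = 1.8,
    target_median_degree: int = 6,
) -> ChannelAdjacency:
    """Neighbor graph from montage coordinates.

    Hybrid of a Delaunay triangulation of the azimuthally projected
    positions (edges longer than ``prune_factor`` times the median edge
    length removed, so hull chords do not link distant sites) and a
    distance threshold grown until the median neighbor count reaches
    ``target_median_degree``.
    """
    xy = _azimuthal_projection(pos3d)
    tri = Delaunay(xy)
    n = len(ch_names)
    m = np.zeros((n, n), bool)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    lengths = {e: np.linalg.norm(xy[e[0]] - xy[e[1]]) for e in edges}
    cutoff = prune_factor * np.median(list(lengths.values()))
    for (i, j), L in lengths.items():
        if L <= cutoff:
            m[i, j] = m[j, i] = True
    # distance threshold: grow until the median degree reaches the target
    dist = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    np.fill_diagonal(dist, np.inf)
    for thr in np.sort(np.unique(dist[np.isfinite(dist)])):
        if np.median(m.sum(axis=1)) >= target_median_degree:
            break
        grow = dist <= thr
        m |= grow
    return ChannelAdjacency(matrix=m, ch_names=tuple(ch_names))


# ---------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class Cluster:
    members: np.ndarray          # point indices: (k,) channels or (k, 2) f/t bins
    mass: float
    sign: int
    p: float
    cluster_mean_r: float | None = None   # correlation tests only


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[Cluster, ...]        # sorted by |mass| descending
    n_permutations: int
    cluster_alpha: float
    alpha: float
    threshold: float                      # |t| (or |r|) forming threshold
    max_mass_distribution: np.ndarray = field(repr=False, default=None)

    def significant(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p < self.alpha)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "clusters": [
                {
                    "members": np.asarray(c.members).tolist(),
                    "mass": c.mass,
                    "sign": c.sign,
                    "p": c.p,
                    **({"cluster_mean_r": c.cluster_mean_r}
                       if c.cluster_mean_r is not None else {}),
                }
                for c in self.clusters
            ],
        }


def _finalize(raw, max_masses, n_perm, cluster_alpha, alpha, threshold):
    max_masses = np.asarray(max_masses)
    clusters = []
    for members, mass, sign, extra in raw:
        p = (1.0 + np.sum(max_masses >= abs(mass) - 1e-12)) / (n_perm + 1.0)
        clusters.append(Cluster(members=members, mass=float(mass), sign=sign,
                                p=float(p), cluster_mean_r=extra))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=tuple(clusters), n_permutations=n_perm,
        cluster_alpha=cluster_alpha, alpha=alpha, threshold=threshold,
        max_mass_distribution=max_masses,
    )


# ---------------------------------------------------------------------------
# shared machinery

def _t_from_mean(mean, sumsq, n):
    """One-sample t from the mean, given the (sign-flip invariant) sum of squares."""
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sumsq - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    return t


def _grid_clusters(t, thr, valid):
    """Same-sign suprathreshold clusters on a 2-D grid (full 2-D adjacency)."""
    out = []
    for sign in (1, -1):
        mask = valid & ((t > thr) if sign > 0 else (t < -thr))
        labels, nlab = ndimage.label(mask)
        for k in range(1, nlab + 1):
            members = np.argwhere(labels == k)
            out.append((members, float(t[labels == k].sum()), sign))
    return out


def _grid_max_mass(t, thr, valid):
    best = 0.0
    for sign in (1, -1):
        mask = valid & ((t > thr) if sign > 0 else (t < -thr))
        labels, nlab = ndimage.label(mask)
        if nlab:
            sums = ndimage.sum_labels(t, labels, index=np.arange(1, nlab + 1))
            best = max(best, float(np.abs(sums).max()))
    return best


def _graph_clusters(t, thr, valid, neighbors):
    """Same-sign suprathreshold connected components on the channel graph."""
    out = []
    for sign in (1, -1):
        mask = valid & ((t > thr) if sign > 0 else (t < -thr))
        seen = np.zeros(t.size, bool)
        for start in np.flatnonzero(mask):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            stack = [start]
            while stack:
                u = stack.pop()
                for v in neighbors[u]:
                    if mask[v] and not seen[v]:
                        seen[v] = True
                        comp.append(v)
                        stack.append(v)
            members = np.array(sorted(comp))
            out.append((members, float(t[members].sum()), sign))
    return out


def _graph_max_mass(t, thr, valid, neighbors):
    best = 0.0
    for _, mass, _ in _graph_clusters(t, thr, valid, neighbors):
        best = max(best, abs(mass))
    return best


def _check_subjects(x, minimum):
    if x.shape[0] < minimum:
        raise ValueError(f"need at least {minimum} subjects, got {x.shape[0]}")


# ---------------------------------------------------------------------------
# tests

def tf_cluster_test(
    maps: np.ndarray,
    times_ms: np.ndarray,
    freqs: np.ndarray,
    baseline_window_ms: tuple[float, float] = (-2000.0, -1000.0),
    test_window_ms: tuple[float, float] = (0.0, 14000.0),
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    cluster_alpha: float = CLUSTER_ALPHA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Paired test of post-stimulus time-frequency power against baseline.

    ``maps`` is (n_subjects, n_freqs, n_times) for one channel (dB or raw
    power).  Each subject's per-frequency baseline mean is subtracted, the
    post-stimulus window is tested point-wise against zero, and clusters are
    formed over full 2-D time-frequency adjacency.  The null is built from
    random sign flips of the per-subject difference maps.
    """
    maps = np.asarray(maps, float)
    _check_subjects(maps, 2)
    n = maps.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    bmask = (times_ms >= baseline_window_ms[0] - 1e-9) & (times_ms <= baseline_window_ms[1] + 1e-9)
    wmask = (times_ms >= test_window_ms[0] - 1e-9) & (times_ms <= test_window_ms[1] + 1e-9)
    if not bmask.any() or not wmask.any():
        raise ValueError("baseline/test window outside the time grid")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(maps[:, :, bmask], axis=2)   # (n, n_freq)
    D = maps[:, :, wmask] - base[:, :, None]           # per-subject difference maps
    valid = np.all(np.isfinite(D), axis=0)
    Dz = np.where(np.isfinite(D), D, 0.0)

    sumsq = (Dz**2).sum(axis=0)
    t_obs = _t_from_mean(Dz.mean(axis=0), sumsq, n)
    with np.errstate(invalid="ignore"):
        sd = Dz.std(axis=0)
    valid &= sd > 0                                     # zero-variance points excluded
    thr = float(stats.t.ppf(1 - cluster_alpha / 2, df=n - 1))

    raw = [(m, mass, s, None) for m, mass, s in _grid_clusters(t_obs, thr, valid)]
    flat = Dz.reshape(n, -1)
    sumsq_flat = sumsq.reshape(-1)
    shape = t_obs.shape
    max_masses = np.empty(n_permutations)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    for p_i in range(n_permutations):
        mean_p = (signs[p_i] @ flat) / n
        t_p = _t_from_mean(mean_p, sumsq_flat, n).reshape(shape)
        max_masses[p_i] = _grid_max_mass(t_p, thr, valid)
    return _finalize(raw, max_masses, n_permutations, cluster_alpha, alpha, thr)


def topo_cluster_test(
    maps: np.ndarray,
    adjacency: ChannelAdjacency,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    cluster_alpha: float = CLUSTER_ALPHA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Paired test of per-channel band power against its baseline reference.

    ``maps`` is (n_subjects, n_channels) of baseline-referenced values
    (e.g. band-mean dB, whose baseline reference is zero); channels form
    clusters through the montage neighbor graph, and the null comes from
    random sign flips of the subject maps.
    """
    maps = np.asarray(maps, float)
    _check_subjects(maps, 2)
    if maps.shape[1] != len(adjacency.ch_names):
        raise ValueError("maps and adjacency disagree on channel count")
    n = maps.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    neighbors = adjacency.neighbor_lists()

    sumsq = (maps**2).sum(axis=0)
    t_obs = _t_from_mean(maps.mean(axis=0), sumsq, n)
    valid = np.isfinite(t_obs) & (maps.std(axis=0) > 0)
    thr = float(stats.t.ppf(1 - cluster_alpha / 2, df=n - 1))

    raw = [(m, mass, s, None) for m, mass, s in _graph_clusters(t_obs, thr, valid, neighbors)]
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    means = (signs @ maps) / n                          # (n_perm, n_ch)
    t_perm = _t_from_mean(means, sumsq[None, :], n)
    max_masses = np.array(
        [_graph_max_mass(t_perm[i], thr, valid, neighbors) for i in range(n_permutations)]
    )
    return _finalize(raw, max_masses, n_permutations, cluster_alpha, alpha, thr)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each column of X (n, p) and y (n,), vectorized."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _r_to_t(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-12, None))


def topo_cluster_correlation(
    maps: np.ndarray,
    behavior: np.ndarray,
    adjacency: ChannelAdjacency,
    n_permutations: int = N_PERMUTATIONS_DEFAULT,
    cluster_alpha: float = CLUSTER_ALPHA_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-corrected correlation between channel power and a behavioral change.

    Pearson r between each channel's value across subjects and the
    per-subject behavioral score; channels whose |r| exceeds the two-tailed
    cluster-alpha critical r form clusters via the neighbor graph, with
    cluster mass the sum of r-derived t values.  The null permutes the
    behavior vector across subjects.  For each cluster, ``cluster_mean_r``
    reports the correlation between the cluster-mean map value and the
    behavior (the scatter statistic for a significant cluster).
    """
    maps = np.asarray(maps, float)
    behavior = np.asarray(behavior, float)
    _check_subjects(maps, 4)
    n = maps.shape[0]
    if behavior.shape != (n,):
        raise ValueError("behavior must be one scalar per subject")
    if not np.all(np.isfinite(behavior)):
        raise ValueError("behavior must be finite")
    if np.allclose(behavior, behavior[0]):
        raise ValueError("behavior is constant; correlation undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    neighbors = adjacency.neighbor_lists()

    t_crit = stats.t.ppf(1 - cluster_alpha / 2, df=n - 2)
    r_thr = float(np.sqrt(t_crit**2 / (t_crit**2 + n - 2)))

    r_obs = _pearson_rows(maps, behavior)
    valid = np.isfinite(r_obs)
    t_obs = _r_to_t(r_obs, n)

    raw = []
    for members, _, sign in _graph_clusters(np.where(valid, r_obs, 0.0), r_thr, valid, neighbors):
        mass = float(t_obs[members].sum())
        mean_map = maps[:, members].mean(axis=1)
        cmr = float(_pearson_rows(mean_map[:, None], behavior)[0])
        raw.append((members, mass, sign, cmr))

    max_masses = np.empty(n_permutations)
    for p_i in range(n_permutations):
        perm = rng.permutation(behavior)
        r_p = _pearson_rows(maps, perm)
        t_p = _r_to_t(r_p, n)
        best = 0.0
        for members, _, _ in _graph_clusters(np.where(valid, r_p, 0.0), r_thr, valid, neighbors):
            best = max(best, abs(float(t_p[members].sum())))
        max_masses[p_i] = best
    return _finalize(raw, max_masses, n_permutations, cluster_alpha, alpha, r_thr)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two non-constant vectors (n >= 3)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
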