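"""Time-course transcriptome analytics.

Covers the desk-scale analytics around the Boolean model: polynomial
smoothing of densely sampled expression series, selection of strongly
regulated genes, high-throughput multidimensional scaling (HiT-MDS) of the
gene-gene distance matrix with a skew-normal uniqueness score for outlying
temporal profiles, CAST clustering of response shapes, and detection of
inversely regulated gene pairs.

Expression matrices are pandas DataFrames with genes as rows and timepoints
(hours, strictly increasing) as columns, on the log2 fold-change scale
unless noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SmoothingConfig",
    "MdsEmbedding",
    "SkewGaussianFit",
    "ClusterSet",
    "smooth_polynomial",
    "smooth_matrix",
    "select_top_regulated",
    "hitmds_embed",
    "fit_skew_gaussian",
    "uniqueness_pvalue",
    "cast_cluster",
    "detect_anticorrelated",
]


class DegenerateSeriesWarning(UserWarning):
    """A constant gene series has no defined correlation; it is excluded."""


@dataclass(frozen=True)
class SmoothingConfig:
    polynomial_order: int = 5


def smooth_polynomial(times, values, config: SmoothingConfig = SmoothingConfig()):
    """Least-squares polynomial fit evaluated back at the original timepoints.

    Requires at least ``order + 1`` timepoints; a series that is exactly a
    polynomial of the given order is reproduced to numerical precision.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = config.polynomial_order
    if len(times) < order + 1:
        raise ValueError(
            f"need at least {order + 1} timepoints for order-{order} smoothing")
    coeffs = np.polynomial.polynomial.polyfit(times, values, order)
    return np.polynomial.polynomial.polyval(times, coeffs)


def smooth_matrix(matrix: pd.DataFrame,
                  config: SmoothingConfig = SmoothingConfig()) -> pd.DataFrame:
    times = matrix.columns.to_numpy(dtype=float)
    out = matrix.copy()
    for gene in matrix.index:
        out.loc[gene] = smooth_polynomial(times, matrix.loc[gene].to_numpy(), config)
    return out


def select_top_regulated(matrix: pd.DataFrame, fc_threshold: float = 1.7) -> list[str]:
    """Genes exceeding +/- the log2 fold-change threshold at two consecutive
    timepoints with the same sign both times.

    The same-sign requirement keeps inverse regulation (an up spike followed
    by a down spike) from counting as sustained strong regulation.
    """
    vals = matrix.to_numpy(dtype=float)
    up = vals > fc_threshold
    down = vals < -fc_threshold
    hit = (up[:, :-1] & up[:, 1:]) | (down[:, :-1] & down[:, 1:])
    return [g for g, h in zip(matrix.index, hit.any(axis=1)) if h]


# -- HiT-MDS ---------------------------------------------------------------


@dataclass
class MdsEmbedding:
    coordinates: pd.DataFrame  # columns x, y
    stress: float              # 1 - Pearson correlation(input d, embedded d)
    stress_trace: list[float] = field(default_factory=list)


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def hitmds_embed(distance_matrix, seed: int = 0, iterations: int = 2000,
                 labels=None) -> MdsEmbedding:
    """2-D embedding maximizing the Pearson correlation between input and
    embedded pairwise distances (the HiT-MDS criterion).

    Optimized by gradient ascent on the correlation from a seeded random
    start; reports ``stress = 1 - correlation`` and its per-iteration trace
    (non-increasing at accepted steps).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    if np.all(d == 0):
        raise ValueError("all-zero distance matrix is degenerate")
    # classical-MDS start: deterministic, permutation-equivariant, and close
    # enough to the optimum that gradient ascent on the correlation converges
    # reliably; a seeded random start is used only for degenerate inputs
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    top = np.argsort(eigval)[::-1][:2]
    x0 = (eigvec[:, top] * np.sqrt(np.clip(eigval[top], 0, None))).ravel()
    if not np.any(x0):
        rng = np.random.default_rng(seed)
        x0 = rng.standard_normal(n * 2) * d.mean()

    Dc = d - d.mean()
    sdd = float((Dc ** 2).sum())
    trace: list[float] = []

    def _chain(gpair, coords, delta):
        G = np.zeros((n, n))
        G[iu] = gpair
        G = G + G.T
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(delta > 0, G / delta, 0.0)
        return (coords * W.sum(1)[:, None] - W @ coords).ravel()

    def objective(flat):
        coords = flat.reshape(n, 2)
        delta = _pair_distances(coords)
        e = delta[iu]
        if sdd == 0:
            # all input distances equal: the correlation is undefined, so
            # match the distances directly (normalized residual as stress)
            resid = e - d
            value = float((resid ** 2).sum() / (d ** 2).sum())
            return value, _chain(2 * resid / (d ** 2).sum(), coords, delta)
        Ec = e - e.mean()
        see = float((Ec ** 2).sum())
        if see == 0:
            return 1.0, np.zeros_like(flat)
        sde = float((Dc * Ec).sum())
        r = sde / np.sqrt(sdd * see)
        # d(-r)/d e_ij, then chain through e_ij = |x_i - x_j|
        gpair = -(Dc - (sde / see) * Ec) / np.sqrt(sdd * see)
        return 1.0 - r, _chain(gpair, coords, delta)

    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        callback=lambda xk: trace.append(float(objective(xk)[0])),
        options={"maxiter": iterations, "ftol": 1e-12, "gtol": 1e-10})
    coords = res.x.reshape(n, 2)
    stress = float(objective(res.x)[0])
    if labels is None:
        labels = range(n)
    frame = pd.DataFrame(coords, index=list(labels), columns=["x", "y"])
    trace = [t for i, t in enumerate(trace) if i == 0 or t <= trace[i - 1]] or [stress]
    return MdsEmbedding(coordinates=frame, stress=stress, stress_trace=trace)


# -- skew-Gaussian uniqueness ----------------------------------------------


@dataclass
class SkewGaussianFit:
    location: np.ndarray          # xi, length 2
    scale: np.ndarray             # Omega, 2x2 positive definite
    skew: np.ndarray              # alpha, length 2
    log_likelihood: float

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        omega = np.sqrt(np.diag(self.scale))
        z = (pts - self.location) / omega
        phi2 = stats.multivariate_normal(mean=self.location, cov=self.scale).pdf(pts)
        return 2.0 * phi2 * stats.norm.cdf(z @ self.skew)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        omega = np.sqrt(np.diag(self.scale))
        corr = self.scale / np.outer(omega, omega)
        denom = np.sqrt(1.0 + self.skew @ corr @ self.skew)
        delta = corr @ self.skew / denom
        big = np.block([[np.ones((1, 1)), delta[None, :]], [delta[:, None], corr]])
        draws = rng.multivariate_normal(np.zeros(3), big, size=n,
                                        method="cholesky")
        z = np.where(draws[:, :1] > 0, draws[:, 1:], -draws[:, 1:])
        return self.location + z * omega


def fit_skew_gaussian(points: np.ndarray) -> SkewGaussianFit:
    """Maximum-likelihood bivariate skew-normal fit to a 2-D point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 10:
        raise ValueError("need an (n, 2) array with n >= 10")
    cov = np.cov(pts.T)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point cloud; skew-normal fit fails")
    L0 = np.linalg.cholesky(cov)
    theta0 = np.array([pts[:, 0].mean(), pts[:, 1].mean(),
                       np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1]), 0.0, 0.0])

    def unpack(theta):
        xi = theta[:2]
        L = np.array([[np.exp(theta[2]), 0.0], [theta[3], np.exp(theta[4])]])
        omega_mat = L @ L.T
        alpha = theta[5:7]
        return xi, omega_mat, alpha

    def nll(theta):
        xi, omega_mat, alpha = unpack(theta)
        try:
            mvn = stats.multivariate_normal(mean=xi, cov=omega_mat)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        omega = np.sqrt(np.diag(omega_mat))
        z = (pts - xi) / omega
        logphi = mvn.logpdf(pts)
        logcdf = stats.norm.logcdf(z @ alpha)
        ll = np.log(2.0) + logphi + logcdf
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    xi, omega_mat, alpha = unpack(res.x)
    return SkewGaussianFit(location=xi, scale=omega_mat, skew=alpha,
                           log_likelihood=-res.fun)


def uniqueness_pvalue(embedding: MdsEmbedding, n_mc: int = 20000,
                      seed: int = 0) -> pd.Series:
    """Per-gene density-quantile p-values from a skew-normal fit.

    A point's p-value is the fitted-distribution probability of landing at a
    location of equal or lower density, so isolated points in the embedding
    (unique temporal profiles) receive small p; the conventional selection
    rule is p < 0.01.  Estimated by seeded Monte Carlo from the fitted
    distribution; values lie in (0, 1].
    """
    pts = embedding.coordinates[["x", "y"]].to_numpy()
    fit = fit_skew_gaussian(pts)
    rng = np.random.default_rng(seed)
    ref = fit.density(fit.sample(n_mc, rng))
    dens = fit.density(pts)
    counts = (ref[None, :] <= dens[:, None]).sum(axis=1)
    pvals = (counts + 1) / (n_mc + 1)
    return pd.Series(pvals, index=embedding.coordinates.index, name="p_value")


# -- CAST clustering -------------------------------------------------------


@dataclass
class ClusterSet:
    clusters: list[list]
    affinity_threshold: float
    excluded: list = field(default_factory=list)

    def labels(self) -> dict:
        return {g: i for i, members in enumerate(self.clusters) for g in members}


def cast_cluster(matrix: pd.DataFrame, affinity_threshold: float = 0.8) -> ClusterSet:
    """Cluster Affinity Search Technique on gene time series.

    Affinity between two genes is the Pearson correlation of their series
    mapped to [0, 1] via (r + 1) / 2, so the default threshold t = 0.8
    corresponds to r = 0.6.  Clusters are grown greedily: the unassigned
    gene of maximal total affinity to the open cluster is added while its
    affinity is at least t times the cluster size, members whose affinity
    falls below that bound are expelled, and the cluster closes when stable.
    No cluster count is fixed in advance.  Constant series are excluded with
    a warning (their correlation is undefined).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two genes to cluster")
    genes = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    excluded = [g for g, s in zip(genes, sd) if s == 0]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant series from clustering",
            DegenerateSeriesWarning, stacklevel=2)
    keep = sd > 0
    genes = [g for g, k in zip(genes, keep) if k]
    vals = vals[keep]
    t = affinity_threshold
    S = (np.corrcoef(vals) + 1.0) / 2.0
    np.fill_diagonal(S, 1.0)

    n = len(genes)
    unassigned = set(range(n))
    clusters: list[list] = []
    while unassigned:
        pool = sorted(unassigned)
        seed = max(pool, key=lambda i: (S[i, pool].sum(), -i))
        copen = [seed]
        unassigned.discard(seed)
        changed = True
        while changed:
            changed = False
            # ADD the highest-affinity outside element while it clears t|C|
            if unassigned:
                pool = sorted(unassigned)
                aff = {u: S[u, copen].sum() for u in pool}
                u = max(pool, key=lambda i: (aff[i], -i))
                if aff[u] >= t * len(copen):
                    copen.append(u)
                    unassigned.discard(u)
                    changed = True
                    continue
            # REMOVE the lowest-affinity member that falls below t|C|
            if len(copen) > 1:
                aff_in = {v: S[v, copen].sum() for v in copen}
                v = min(copen, key=lambda i: (aff_in[i], i))
                if aff_in[v] < t * len(copen):
                    copen.remove(v)
                    unassigned.add(v)
                    changed = True
        clusters.append(sorted(copen))
    clusters.sort(key=lambda c: (-len(c), c[0]))
    named = [[genes[i] for i in c] for c in clusters]
    return ClusterSet(clusters=named, affinity_threshold=t, excluded=excluded)


def detect_anticorrelated(times, series_a, series_b, r2_threshold: float = 0.7,
                          alpha: float = 0.05) -> bool:
    """True iff two smoothed series move linearly in opposite directions.

    Both linear fits over time must have a significant slope (t-test p below
    ``alpha``), the slopes must have opposite signs, and both fits must
    achieve r^2 strictly above the threshold.
    """
    times = np.asarray(times, dtype=float)
    fa = stats.linregress(times, np.asarray(series_a, dtype=float))
    fb = stats.linregress(times, np.asarray(series_b, dtype=float))
    return bool(
        fa.pvalue < alpha and fb.pvalue < alpha
        and fa.slope * fb.slope < 0
        and fa.rvalue ** 2 > r2_threshold and fb.rvalue ** 2 > r2_threshold
    )
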