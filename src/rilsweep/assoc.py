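"""Kinship-based mixed-linear-model association scan.

The model is the standard single-marker mixed model

    y = X b + g a + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K a VanRaden genomic relationship matrix.  Variance components are
profiled over delta = se2/sg2 by restricted maximum likelihood in the
eigenbasis of K (one decomposition for the whole scan).  With P3D
("population parameters previously determined") the components are estimated
once under the no-marker model and held fixed, so each marker test is a
generalized-least-squares fit in the rotated coordinates — the EMMAX/P3D
strategy.  An optional compression step clusters lines and replaces K by the
group-mean kinship (the compressed mixed linear model); with one group per
line it reproduces the uncompressed scan exactly.

Marker significance uses a Wald test with a t reference on
n - rank(X) - 1 degrees of freedom; the genome-wide threshold defaults to
the fixed cutoff 1e-6.  Per-locus variance explained is reported as the
plain marker R^2 (squared trait-dosage correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .core import MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "AssocConfig",
    "kinship_vanraden",
    "compress_kinship",
    "expand_group_kinship",
    "reml_variance_components",
    "mlm_scan",
    "significant_hits",
    "marker_pve",
    "manhattan_plot",
]

_PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -_PSD_TOL * max(np.trace(self.values) / n, 1.0):
            raise ValueError("kinship is not positive semi-definite")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    log_likelihood: float


@dataclass
class AssocConfig:
    p_threshold: float = 1e-6
    kinship_method: str = "vanraden"
    p3d: bool = True
    n_groups: int | str = "n"  # "n" = no compression (one group per line)
    covariates: np.ndarray | None = None
    locus_merge_gap_bp: int = 1_000_000
    #: markers whose P3D screening p falls below this are re-tested by exact
    #: per-marker REML (None disables the refit; ignored when p3d=False)
    exact_refit_p: float | None = 0.01

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.kinship_method != "vanraden":
            raise ValueError(f"unknown kinship method {self.kinship_method!r}")


def _mean_imputed_dosage(G: GenotypeMatrix) -> np.ndarray:
    d = G.calls.astype(float)
    miss = G.calls == MISSING
    d[miss] = np.nan
    means = np.nanmean(np.where(miss, np.nan, d), axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing column
    return np.where(miss, means[None, :], d)


def kinship_vanraden(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship: K = W W' / (2 sum p(1-p)),
    W the dosage matrix with columns centered at 2p.  Missing calls are
    mean-imputed for this computation only."""
    if G.n_lines < 2:
        raise ValueError("kinship needs at least 2 lines")
    d = _mean_imputed_dosage(G)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    W = d - 2.0 * p[None, :]
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(G.line_ids), K)


def compress_kinship(K: KinshipMatrix, n_groups: int):
    """Average-linkage clustering of lines on kinship similarity, cut to
    ``n_groups``; group kinship is the mean of K over member pairs.
    n_groups = n reproduces K exactly (singleton groups)."""
    n = len(K.line_ids)
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    if n_groups == n:
        return np.arange(n), K.values.copy()
    D = K.values.max() - K.values  # similarity -> dissimilarity
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    groups = fcluster(Z, t=n_groups, criterion="maxclust") - 1
    g = groups.max() + 1
    B = np.zeros((g, g))
    for a in range(g):
        ia = groups == a
        for b in range(a, g):
            ib = groups == b
            B[a, b] = B[b, a] = K.values[np.ix_(ia, ib)].mean()
    return groups, B


def expand_group_kinship(groups: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Line-level covariance implied by group kinship."""
    return B[np.ix_(groups, groups)]


def _reml_loglik(log10_delta: float, lam: np.ndarray, yr: np.ndarray,
                 Xr: np.ndarray, logdet_xtx: float) -> float:
    """Restricted log-likelihood profiled over delta, in K's eigenbasis."""
    delta = 10.0 ** log10_delta
    n, q = Xr.shape
    h = lam + delta
    w = 1.0 / h
    XtHX = Xr.T @ (Xr * w[:, None])
    XtHy = Xr.T @ (yr * w)
    beta = np.linalg.solve(XtHX, XtHy)
    r = yr - Xr @ beta
    rss = float(np.sum(r * r * w))
    sg2 = rss / (n - q)
    sign, logdet_xhx = np.linalg.slogdet(XtHX)
    if sign <= 0 or sg2 <= 0:
        return -np.inf
    return -0.5 * (
        (n - q) * np.log(2.0 * np.pi * sg2)
        + float(np.sum(np.log(h)))
        + logdet_xhx
        - logdet_xtx
        + (n - q)
    )


def reml_variance_components(y: np.ndarray, X: np.ndarray, K: KinshipMatrix,
                             grid_points: int = 100,
                             log10_delta_range: tuple[float, float] = (-5.0, 5.0),
                             eigen: tuple[np.ndarray, np.ndarray] | None = None
                             ) -> VarianceComponents:
    """REML estimates of (sigma_g2, sigma_e2) by 1-D profiling over delta.

    K is eigendecomposed once; the restricted log-likelihood is evaluated on
    a log10-delta grid and the best bracket refined by bounded Brent search.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y are misaligned")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank-deficient")
    if eigen is None:
        lam, U = np.linalg.eigh(K.values)
    else:
        lam, U = eigen
    if lam.min() < -_PSD_TOL * max(lam.max(), 1.0):
        raise ValueError("kinship is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    yr, Xr = U.T @ y, U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)

    lo, hi = log10_delta_range
    grid = np.linspace(lo, hi, grid_points)
    ll = np.array([_reml_loglik(g, lam, yr, Xr, logdet_xtx) for g in grid])
    k = int(np.argmax(ll))
    a = grid[max(0, k - 1)]
    b = grid[min(grid_points - 1, k + 1)]
    res = minimize_scalar(
        lambda g: -_reml_loglik(g, lam, yr, Xr, logdet_xtx),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if -res.fun >= ll[k] else grid[k]
    ll_best = max(-res.fun, float(ll[k]))

    delta = 10.0 ** float(best)
    h = lam + delta
    w = 1.0 / h
    XtHX = Xr.T @ (Xr * w[:, None])
    beta = np.linalg.solve(XtHX, Xr.T @ (yr * w))
    r = yr - Xr @ beta
    sg2 = float(np.sum(r * r * w)) / (n - X.shape[1])
    return VarianceComponents(sg2, delta * sg2, delta, float(ll_best))


def _emma_delta_grid(yv: np.ndarray, X: np.ndarray, cols: np.ndarray,
                     lam: np.ndarray, U: np.ndarray,
                     grid_points: int = 161,
                     log10_delta_range: tuple[float, float] = (-5.0, 5.0)
                     ) -> np.ndarray:
    """Per-marker REML arg-max of delta with the marker in the fixed effects.

    The restricted likelihood of [X | g_j] is profiled on a log10-delta
    grid, evaluated for every marker at once per grid point (terms constant
    in delta are dropped: they do not move the arg max).  Returns the best
    delta per marker.
    """
    n, q = X.shape
    m = cols.shape[1]
    yr = U.T @ yv
    Xr = U.T @ X
    Gr = U.T @ cols
    df = n - q - 1
    best_ll = np.full(m, -np.inf)
    best_delta = np.empty(m)
    for g10 in np.linspace(*log10_delta_range, grid_points):
        delta = 10.0 ** g10
        w = 1.0 / (lam + delta)
        Xw = Xr * w[:, None]
        XtWX = Xr.T @ Xw                      # (q, q)
        XtWg = Xw.T @ Gr                      # (q, m)
        gtWg = np.einsum("ij,ij->j", Gr * w[:, None], Gr)
        XtWy = Xw.T @ yr                      # (q,)
        gtWy = Gr.T @ (yr * w)                # (m,)
        ytWy = float(yr @ (yr * w))
        A = np.empty((m, q + 1, q + 1))
        A[:, :q, :q] = XtWX[None, :, :]
        A[:, :q, q] = XtWg.T
        A[:, q, :q] = XtWg.T
        A[:, q, q] = gtWg
        b = np.empty((m, q + 1))
        b[:, :q] = XtWy[None, :]
        b[:, q] = gtWy
        sign, logdetA = np.linalg.slogdet(A)
        with np.errstate(all="ignore"):
            beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        rss = ytWy - np.einsum("ij,ij->i", beta, b)
        ok = (sign > 0) & (rss > 0)
        sg2 = np.where(ok, rss / df, np.nan)
        ll = np.where(
            ok,
            -0.5 * (df * (np.log(2.0 * np.pi * sg2) + 1.0)
                    + np.sum(np.log(lam + delta)) + logdetA),
            -np.inf,
        )
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_delta[better] = delta
    return best_delta


def _align(G: GenotypeMatrix, y: pd.DataFrame, K: KinshipMatrix):
    ids = list(G.line_ids)
    missing_y = sorted(set(ids) - set(y["line_id"]))
    extra_y = sorted(set(y["line_id"]) - set(ids))
    if missing_y or extra_y:
        raise ValueError(
            f"trait/genotype line mismatch: missing {missing_y[:5]}, extra {extra_y[:5]}"
        )
    if K.line_ids != ids:
        if set(K.line_ids) != set(ids):
            raise ValueError("kinship lines differ from genotype lines")
        order = [K.line_ids.index(l) for l in ids]
        K = KinshipMatrix(ids, K.values[np.ix_(order, order)])
    yv = y.set_index("line_id").loc[ids, "value"].to_numpy(dtype=float)
    return yv, K


def mlm_scan(G: GenotypeMatrix, y: pd.DataFrame, K: KinshipMatrix,
             cfg: AssocConfig | None = None) -> pd.DataFrame:
    """Single-marker mixed-model scan; returns a per-marker results frame
    (marker_id, effect, se, p_value, neg_log10_p, n_used).

    Constant-dosage markers are skipped and listed in
    ``result.attrs["skipped"]``.  Missing dosages are mean-imputed within
    marker.  With ``cfg.p3d`` the variance components are estimated once
    under the no-marker model; otherwise they are re-estimated per marker.
    """
    cfg = cfg or AssocConfig()
    if G.n_lines < 10:
        raise ValueError("scan requires at least 10 lines")
    yv, K = _align(G, y, K)
    n = G.n_lines

    Kv = K.values
    if cfg.n_groups != "n":
        groups, B = compress_kinship(K, int(cfg.n_groups))
        Kv = expand_group_kinship(groups, B)

    X = np.ones((n, 1))
    if cfg.covariates is not None:
        C = np.atleast_2d(np.asarray(cfg.covariates, dtype=float))
        X = np.hstack([X, C])
    q = X.shape[1]

    lam, U = np.linalg.eigh(Kv)
    lam = np.clip(lam, 0.0, None)
    Kobj = KinshipMatrix(list(G.line_ids), Kv)
    vc = reml_variance_components(yv, X, Kobj, eigen=(lam, U))

    dos = _mean_imputed_dosage(G)
    keep = dos.std(axis=0) > 0
    skipped = [m for m, k in zip(G.marker_ids, keep) if not k]

    df = n - q - 1

    def _fit(delta: float, cols: np.ndarray):
        w = 1.0 / np.sqrt(lam + delta)
        yw = (U.T @ yv) * w
        Xw = (U.T @ X) * w[:, None]
        Gw = (U.T @ cols) * w[:, None]
        # project out covariates
        Q, _ = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        Gr = Gw - Q @ (Q.T @ Gw)
        gg = np.einsum("ij,ij->j", Gr, Gr)
        gy = Gr.T @ yr
        eff = gy / gg
        rss = float(yr @ yr) - eff * gy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / gg)
        t = eff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return eff, se, p

    cols = dos[:, keep]
    if cfg.p3d:
        eff, se, p = _fit(vc.delta, cols)
        if cfg.exact_refit_p is not None:
            # refit promising markers exactly: under P3D the kinship term
            # absorbs part of a strong marker's own signal (proximal
            # contamination), deflating its test; with the marker in the
            # fixed effects the variance components are re-estimated free
            # of that signal
            sel = np.nonzero(p < cfg.exact_refit_p)[0]
            if sel.size:
                refit_delta = _emma_delta_grid(yv, X, cols[:, sel], lam, U)
                for d in np.unique(refit_delta):
                    sub = sel[refit_delta == d]
                    eff[sub], se[sub], p[sub] = _fit(float(d), cols[:, sub])
    else:
        # exact per-marker REML (EMMA): each marker joins the fixed effects
        # while its own delta is re-estimated on a dense log10 grid,
        # vectorized across markers per grid point
        best_delta = _emma_delta_grid(yv, X, cols, lam, U)
        eff = np.empty(cols.shape[1])
        se = np.empty(cols.shape[1])
        p = np.empty(cols.shape[1])
        for d in np.unique(best_delta):
            sel = best_delta == d
            eff[sel], se[sel], p[sel] = _fit(float(d), cols[:, sel])

    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "marker_id": [m for m, k in zip(G.marker_ids, keep) if k],
            "effect": eff,
            "se": se,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "n_used": n,
        }
    )
    out.attrs["skipped"] = skipped
    out.attrs["variance_components"] = vc
    return out


def significant_hits(result: pd.DataFrame, marker_map: MarkerMap,
                     cfg: AssocConfig | None = None) -> pd.DataFrame:
    """Markers below the genome-wide threshold, merged into loci when within
    ``locus_merge_gap_bp`` on the same chromosome; each locus reports its
    peak (smallest-p) marker."""
    cfg = cfg or AssocConfig()
    hits = result[result["p_value"] < cfg.p_threshold].copy()
    cols = ["chrom", "start_bp", "end_bp", "peak_marker", "peak_p", "n_markers"]
    if hits.empty:
        return pd.DataFrame(columns=cols)
    coords = marker_map.table.set_index("marker_id")
    hits["chrom"] = coords.loc[hits["marker_id"], "chrom"].to_numpy()
    hits["pos_bp"] = coords.loc[hits["marker_id"], "pos_bp"].to_numpy()
    hits = hits.sort_values(["chrom", "pos_bp"])
    loci = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        start = prev = None
        members = []
        for _, row in sub.iterrows():
            if prev is not None and row["pos_bp"] - prev > cfg.locus_merge_gap_bp:
                loci.append(_locus_row(chrom, members))
                members = []
            members.append(row)
            prev = row["pos_bp"]
        if members:
            loci.append(_locus_row(chrom, members))
    return pd.DataFrame(loci, columns=cols)


def _locus_row(chrom, members):
    peak = min(members, key=lambda r: r["p_value"])
    return {
        "chrom": chrom,
        "start_bp": int(min(r["pos_bp"] for r in members)),
        "end_bp": int(max(r["pos_bp"] for r in members)),
        "peak_marker": peak["marker_id"],
        "peak_p": float(peak["p_value"]),
        "n_markers": len(members),
    }


def marker_pve(y: pd.DataFrame, dosage: np.ndarray) -> float:
    """Proportion of trait variance explained by one marker: OLS R^2,
    i.e. the squared Pearson correlation of trait and dosage."""
    g = np.asarray(dosage, dtype=float)
    yv = np.asarray(y["value"] if isinstance(y, pd.DataFrame) else y, dtype=float)
    ok = ~np.isnan(g)
    g, yv = g[ok], yv[ok]
    if np.std(g) == 0:
        raise ValueError("marker dosage is constant; R^2 undefined")
    r = np.corrcoef(yv, g)[0, 1]
    return float(r * r)


def manhattan_plot(result: pd.DataFrame, marker_map: MarkerMap, path,
                   p_threshold: float = 1e-6) -> None:
    """Genome-wide -log10 p against cumulative position, threshold line drawn."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = marker_map.table.set_index("marker_id")
    res = result.copy()
    res["chrom"] = coords.loc[res["marker_id"], "chrom"].to_numpy()
    res["pos_bp"] = coords.loc[res["marker_id"], "pos_bp"].to_numpy()
    offset, xticks, xlabels = 0, [], []
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for i, (chrom, sub) in enumerate(res.groupby("chrom", sort=False)):
        x = sub["pos_bp"].to_numpy() + offset
        ax.scatter(x, sub["neg_log10_p"], s=6,
                   color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
        xticks.append(offset + sub["pos_bp"].max() / 2)
        xlabels.append(chrom)
        offset += sub["pos_bp"].max()
    ax.axhline(-np.log10(p_threshold), color="red", lw=1)
    ax.set_xticks(xticks, xlabels, rotation=60, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
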