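"""Distance-based hypothesis tests and ordination.

PERMANOVA (one-way, with R-squared) and the multivariate dispersion test
are implemented here; Mantel and PCoA delegate to scikit-bio behind this
module's surface.  Dispersion uses distances to the group spatial median
in PCoA space; the partial ordination residualizes PCoA coordinates on a
conditioning variable and re-ordinates, a distance-based approximation
to constrained ordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import cdist, pdist, squareform
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .containers import DistanceMatrix


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    sample_ids: list[str]
    negative_eigenvalue_mass: float = 0.0


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _group_indices(groups) -> tuple[np.ndarray, list]:
    labels = np.asarray(list(groups))
    uniq = list(pd.unique(labels))
    return labels, uniq


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq: list) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared distance matrix and labels."""
    n = d2.shape[0]
    k = len(uniq)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        mask = labels == g
        n_g = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 1000, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA with a label-permutation p-value."""
    labels, uniq = _group_indices(groups)
    if len(labels) != d.n:
        raise ValueError("group labels do not match distance matrix size")
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    d2 = d.values**2
    f_obs, r2 = _permanova_stats(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        f_p, _ = _permanova_stats(d2, rng.permutation(labels), uniq)
        if f_p >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=hits / (n_perm + 1),
        n_permutations=n_perm,
    )


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical MDS).

    Axes with negative eigenvalues (possible for non-Euclidean
    resemblances) are dropped; their absolute mass is reported.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*all dimensions.*")
        res = _skbio_pcoa(
            d.to_skbio(), method="eigh", dimensions=0, warn_neg_eigval=False
        )
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-10 * max(1.0, abs(eig).max())
    neg_mass = float(-eig[eig < 0].sum())
    coords = res.samples.to_numpy()[:, pos]
    denom = eig[pos].sum() + neg_mass
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[pos],
        proportion_explained=eig[pos] / denom,
        sample_ids=list(d.ids),
        negative_eigenvalue_mass=neg_mass,
    )


def _spatial_median(x: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    mu = x.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(x - mu, axis=1)
        if (dist < tol).any():
            return x[dist.argmin()]
        w = 1.0 / dist
        new = (w[:, None] * x).sum(axis=0) / w.sum()
        if np.linalg.norm(new - mu) < tol:
            return new
        mu = new
    return mu


def dispersion_test(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> dict:
    """Homogeneity of multivariate dispersions around group spatial medians.

    Embeds by PCoA, measures each sample's distance to its group's
    spatial median, and permutes those distances across groups to test
    whether mean dispersion differs.  Reports per-group median
    dispersion and pairwise differences of medians.
    """
    labels, uniq = _group_indices(groups)
    if len(uniq) < 2:
        raise ValueError("dispersion test needs at least two groups")
    ord_res = pcoa(d)
    x = ord_res.coordinates
    disp = np.empty(len(labels))
    for g in uniq:
        mask = labels == g
        med = _spatial_median(x[mask])
        disp[mask] = np.linalg.norm(x[mask] - med, axis=1)

    def f_stat(values: np.ndarray) -> float:
        means = np.array([values[labels == g].mean() for g in uniq])
        grand = values.mean()
        ns = np.array([(labels == g).sum() for g in uniq])
        ss_b = (ns * (means - grand) ** 2).sum() / (len(uniq) - 1)
        ss_w = sum(
            ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
            for g in uniq
        ) / (len(values) - len(uniq))
        return ss_b / ss_w if ss_w > 0 else np.inf

    f_obs = f_stat(disp)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        if f_stat(disp[rng.permutation(len(disp))]) >= f_obs - 1e-12:
            hits += 1
    medians = {g: float(np.median(disp[labels == g])) for g in uniq}
    diffs = {
        f"{a}-{b}": medians[a] - medians[b]
        for i, a in enumerate(uniq)
        for b in uniq[i + 1:]
    }
    return {
        "median_dispersion": medians,
        "median_differences": diffs,
        "per_sample_dispersion": pd.Series(disp, index=d.ids),
        "f": float(f_obs),
        "p": hits / (n_perm + 1),
        "n_permutations": n_perm,
    }


def envfit(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Fit environmental vectors to ordination axes.

    For each variable, the direction in the first ``n_axes`` ordination
    axes maximizing its correlation with sample scores; reports the
    squared multiple correlation and a permutation p-value.  Constant
    variables are skipped with a warning.
    """
    import warnings

    x = ordination.coordinates[:, :n_axes]
    xc = x - x.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = {}
    for name in variables.columns:
        v = variables[name].astype(float).to_numpy()
        if np.std(v) == 0 or not np.all(np.isfinite(v)):
            warnings.warn(f"envfit: skipping constant or non-finite variable {name!r}")
            continue
        vc = v - v.mean()
        beta, *_ = np.linalg.lstsq(xc, vc, rcond=None)
        fitted = xc @ beta
        r2 = float(fitted @ fitted / (vc @ vc))
        norm = np.linalg.norm(beta)
        arrow = beta / norm if norm > 0 else beta
        hits = 1
        for _ in range(n_perm):
            vp = vc[rng.permutation(len(vc))]
            bp, *_ = np.linalg.lstsq(xc, vp, rcond=None)
            fp = xc @ bp
            if fp @ fp / (vp @ vp) >= r2 - 1e-12:
                hits += 1
        rows[name] = {
            "r_squared": r2,
            "p": hits / (n_perm + 1),
            **{f"axis{i + 1}": arrow[i] for i in range(n_axes)},
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def partial_ordination(
    d: DistanceMatrix, condition: np.ndarray | pd.Series
) -> OrdinationResult:
    """Ordination of what remains after removing one variable's influence.

    PCoA coordinates are regressed on the conditioning variable and the
    residuals re-ordinated (distance-based partialling).
    """
    ord_full = pcoa(d)
    v = np.asarray(condition, dtype=float)
    if np.std(v) == 0:
        raise ValueError("conditioning variable is constant")
    design = np.column_stack([np.ones_like(v), v])
    beta, *_ = np.linalg.lstsq(design, ord_full.coordinates, rcond=None)
    resid = ord_full.coordinates - design @ beta
    d_resid = DistanceMatrix(
        squareform(pdist(resid)), list(d.ids), f"{d.metric_name}_partial",
        normalized=False,
    )
    return pcoa(d_resid)


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> dict:
    """Mantel test (Pearson) between two distance matrices."""
    if d1.ids != d2.ids:
        d2 = d2.filter(d1.ids)
    r, p, n = _skbio_mantel(
        d1.to_skbio(), d2.to_skbio(), method="pearson", permutations=n_perm,
        seed=seed,
    )
    return {"r": float(r), "p": float(p), "n": int(n), "n_permutations": n_perm}


def spatial_mantel(
    d: DistanceMatrix, xy: np.ndarray, n_perm: int = 999, seed: int = 0
) -> dict:
    """Mantel test of community distance against Euclidean spatial distance."""
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] != d.n:
        raise ValueError("coordinate rows do not match distance matrix")
    geo = DistanceMatrix(
        cdist(xy, xy), list(d.ids), "euclidean_spatial", normalized=False
    )
    return mantel(d, geo, n_perm=n_perm, seed=seed)
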