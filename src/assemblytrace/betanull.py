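"""Abundance-based beta-null deviation modeling.

For each null iteration a randomized table is built that preserves each
sample's observed richness S_j and total abundance N_j: occurring taxa
are drawn without replacement with probability proportional to their
occupancy in the observed table, then N_j individuals are allocated by
seeding one individual per chosen taxon and distributing the remainder
multinomially in proportion to the taxa's regional relative abundances.
The beta-null deviation of a sample pair is its observed dissimilarity
minus the mean dissimilarity across null iterations; positive deviations
index niche (non-null) structuring.  The same machinery runs on
Bray-Curtis and on weighted UniFrac (the tree is held fixed; only the
table is permuted), extending the abundance-null family to phylogenetic
resemblances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, spearmanr, ttest_ind

from .containers import CommunityTable, SampleFrame
from .diversity import TreeIndex

METRICS = ("bray_curtis", "weighted_unifrac")


@dataclass
class BetaNullResult:
    """Observed vs. null beta diversity for every sample pair."""

    metric_name: str
    n_iterations: int
    pairs: pd.DataFrame  # sample_a, sample_b, d_obs, null_mean, null_sd, deviation, ses
    per_sample: pd.Series  # mean deviation over each sample's comparison set
    comparison_scope: str = "all_pairs"
    seed: int | None = None


def _null_counts(
    counts: np.ndarray,
    rng: np.random.Generator,
    occ_w: np.ndarray,
    ab_w: np.ndarray,
) -> np.ndarray:
    """One randomized count matrix preserving per-sample richness and depth."""
    S = counts.shape[1]
    out = np.zeros_like(counts)
    p_occ = occ_w / occ_w.sum()
    for i in range(counts.shape[0]):
        s_j = int((counts[i] > 0).sum())
        n_j = int(counts[i].sum())
        if s_j > S:
            raise ValueError("sample richness exceeds taxon pool")
        chosen = rng.choice(S, size=s_j, replace=False, p=p_occ)
        probs = ab_w[chosen] / ab_w[chosen].sum()
        # seed one individual per chosen taxon, multinomial on the remainder:
        # guarantees presence while preserving S_j and N_j exactly
        alloc = np.ones(s_j, dtype=np.int64)
        alloc += rng.multinomial(n_j - s_j, probs)
        out[i, chosen] = alloc
    return out


def _null_weights(table, occupancy_weighted, abundance_weighted):
    occupancy = (table.counts > 0).sum(axis=0).astype(float)
    regional = table.counts.sum(axis=0).astype(float)
    occ_w = occupancy if occupancy_weighted else np.ones_like(occupancy)
    ab_w = regional if abundance_weighted else np.ones_like(regional)
    return occ_w, ab_w


def null_community(
    table: CommunityTable,
    seed: int | np.random.Generator,
    *,
    occupancy_weighted: bool = True,
    abundance_weighted: bool = True,
) -> CommunityTable:
    """One randomized table preserving per-sample richness and depth.

    Taxa that happen to receive no individuals anywhere are dropped (the
    table type keeps only observed taxa); the internal null loop of
    :func:`beta_null_deviation` keeps the full pool.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    occ_w, ab_w = _null_weights(table, occupancy_weighted, abundance_weighted)
    out = _null_counts(table.counts, rng, occ_w, ab_w)
    return CommunityTable(out, list(table.sample_ids), list(table.taxon_ids))


def _null_matrix_condensed(
    counts: np.ndarray, metric: str, idx: TreeIndex | None
) -> np.ndarray:
    if metric == "bray_curtis":
        return pdist(counts.astype(float), metric="braycurtis")
    rel = counts / counts.sum(axis=1, keepdims=True)
    prop = rel @ idx.incidence.T
    raw = pdist(prop, metric="cityblock", w=idx.lengths)
    scale = rel @ idx.tip_depths
    iu = np.triu_indices(counts.shape[0], k=1)
    return raw / (scale[iu[0]] + scale[iu[1]])


def beta_null_deviation(
    table: CommunityTable,
    tree: skbio.TreeNode | None = None,
    *,
    metric: str = "bray_curtis",
    n_iter: int = 999,
    scope: str = "all_pairs",
    seed: int = 0,
    occupancy_weighted: bool = True,
    abundance_weighted: bool = True,
) -> BetaNullResult:
    """Observed-minus-null beta diversity for all sample pairs.

    The tree is fixed across iterations; only the table is randomized.
    Deviation is raw (d_obs - null_mean); the standardized deviation
    (SES) is also reported, NaN where the null spread degenerates.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "weighted_unifrac" and tree is None:
        raise ValueError("weighted_unifrac requires a tree")
    if n_iter < 99:
        warnings.warn(f"n_iter={n_iter} < 99: null expectation will be noisy")

    idx = None if metric == "bray_curtis" else TreeIndex.build(tree, table.taxon_ids)
    d_obs = _null_matrix_condensed(table.counts, metric, idx)

    rng = np.random.default_rng(seed)
    n_pairs = table.n_samples * (table.n_samples - 1) // 2
    acc = np.zeros(n_pairs)
    acc2 = np.zeros(n_pairs)
    occ_w, ab_w = _null_weights(table, occupancy_weighted, abundance_weighted)
    for _ in range(n_iter):
        dn = _null_matrix_condensed(
            _null_counts(table.counts, rng, occ_w, ab_w), metric, idx
        )
        acc += dn
        acc2 += dn * dn
    null_mean = acc / n_iter
    null_var = np.maximum(acc2 / n_iter - null_mean**2, 0.0)
    null_sd = np.sqrt(null_var)
    deviation = d_obs - null_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(null_sd > 0, deviation / null_sd, np.nan)

    iu = np.triu_indices(table.n_samples, k=1)
    ids = np.asarray(table.sample_ids)
    pairs = pd.DataFrame(
        {
            "sample_a": ids[iu[0]],
            "sample_b": ids[iu[1]],
            "d_obs": d_obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "deviation": deviation,
            "ses": ses,
        }
    )
    per_sample = _per_sample_mean(pairs, list(table.sample_ids))
    return BetaNullResult(
        metric_name=metric,
        n_iterations=n_iter,
        pairs=pairs,
        per_sample=per_sample,
        comparison_scope=scope,
        seed=seed,
    )


def _per_sample_mean(pairs: pd.DataFrame, sample_ids: list[str]) -> pd.Series:
    out = {}
    for s in sample_ids:
        mask = (pairs["sample_a"] == s) | (pairs["sample_b"] == s)
        out[s] = float(pairs.loc[mask, "deviation"].mean())
    return pd.Series(out, name="mean_deviation")


def per_sample_deviations(
    result: BetaNullResult,
    metadata: SampleFrame | None = None,
    scope: str = "all_pairs",
) -> pd.Series:
    """Per-sample mean deviation over the chosen comparison set.

    ``all_pairs`` averages each sample's deviations against every other
    sample; ``within_group`` restricts to partners in the same fire
    class (requires metadata), which isolates a class's internal
    divergence from between-class contrasts.
    """
    if scope == "all_pairs":
        return result.per_sample
    if scope != "within_group":
        raise ValueError(f"unknown scope: {scope!r}")
    if metadata is None:
        raise ValueError("within_group scope requires sample metadata")
    classes = metadata.fire_class
    pairs = result.pairs
    out = {}
    for s in result.per_sample.index:
        partner = np.where(pairs["sample_a"] == s, pairs["sample_b"],
                           pairs["sample_a"])
        mask = ((pairs["sample_a"] == s) | (pairs["sample_b"] == s)) & (
            pd.Series(partner).map(classes).to_numpy() == classes[s]
        )
        out[s] = float(pairs.loc[mask, "deviation"].mean())
    return pd.Series(out, name="mean_deviation")


def deviation_by_group(
    result: BetaNullResult,
    metadata: SampleFrame,
    scope: str = "within_group",
) -> dict:
    """Per-class summaries, two-sample tests, and a temperature trajectory.

    Per-sample mean deviations (within-class comparison set by default,
    so a class's internal divergence is measured on its own pairs) are
    grouped by fire class; fire_affected is compared to recovered
    (Welch's t and Mann-Whitney, both reported) when both classes are
    present; the trajectory orders per-sample deviations by temperature
    rank.
    """
    dev = per_sample_deviations(result, metadata, scope=scope)
    classes = metadata.fire_class.reindex(dev.index)
    groups = {c: dev[classes == c] for c in classes.unique()}
    if len(groups) < 2:
        raise ValueError(
            "between-class comparison needs at least two fire classes; got "
            f"{list(groups)}"
        )
    out: dict = {
        "group_means": {c: float(v.mean()) for c, v in groups.items()},
        "group_medians": {c: float(v.median()) for c, v in groups.items()},
    }
    if "fire_affected" in groups and "recovered" in groups:
        a, b = groups["fire_affected"], groups["recovered"]
        t = ttest_ind(a, b, equal_var=False)
        u = mannwhitneyu(a, b, alternative="two-sided")
        t1 = ttest_ind(a, b, equal_var=False, alternative="greater")
        u1 = mannwhitneyu(a, b, alternative="greater")
        out["welch_t"] = {"statistic": float(t.statistic), "p": float(t.pvalue),
                          "p_greater": float(t1.pvalue)}
        out["mann_whitney"] = {"statistic": float(u.statistic), "p": float(u.pvalue),
                               "p_greater": float(u1.pvalue)}
    temp = metadata.temperature.reindex(dev.index)
    order = temp.sort_values().index
    out["trajectory"] = pd.DataFrame(
        {"temperature": temp.loc[order], "deviation": dev.loc[order],
         "fire_class": classes.loc[order]}
    )
    hot = classes == "fire_affected"
    if hot.sum() >= 3:
        rho, p = spearmanr(temp[hot], dev[hot])
        out["hot_temperature_spearman"] = {"rho": float(rho), "p": float(p)}
    return out
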