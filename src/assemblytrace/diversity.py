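"""Alpha and beta diversity.

Alpha: richness, Shannon H' (nats), Pielou's J, Faith's PD under the
whole-tree convention (the minimal subtree connecting observed tips plus
the path to the root — for any rooted tree this is exactly the set of
branches with at least one observed descendant).

Beta: Bray-Curtis, and unweighted/weighted UniFrac in both the raw
(non-normalized) and normalized variants.  UniFrac is computed from a
branch x taxon incidence matrix so that a whole distance matrix is a few
dense matrix products; this is what makes the beta-null permutation
loops affordable.  Raw weighted UniFrac is not bounded by 1; normalized
variants are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .containers import CommunityTable, DistanceMatrix, reconcile_taxa


@dataclass
class TreeIndex:
    """Branch decomposition of a rooted tree over a fixed taxon order.

    ``incidence[b, j]`` is True when tip j descends through branch b;
    ``lengths[b]`` is the branch length; ``tip_depths[j]`` is the
    root-to-tip distance of tip j.
    """

    lengths: np.ndarray
    incidence: np.ndarray
    tip_depths: np.ndarray
    taxon_ids: list[str]

    @classmethod
    def build(cls, tree: skbio.TreeNode, taxon_ids: list[str]) -> "TreeIndex":
        col = {t: j for j, t in enumerate(taxon_ids)}
        tips_missing = set(taxon_ids) - {t.name for t in tree.tips()}
        if tips_missing:
            raise ValueError(f"taxa missing from tree: {sorted(tips_missing)[:3]}")
        lengths, rows = [], []
        tipsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=False):
            mask = np.zeros(len(taxon_ids), dtype=bool)
            if node.is_tip():
                if node.name in col:
                    mask[col[node.name]] = True
            else:
                for child in node.children:
                    mask |= tipsets[id(child)]
            tipsets[id(node)] = mask
            length = node.length if node.length is not None else 0.0
            if mask.any():
                lengths.append(float(length))
                rows.append(mask)
        incidence = np.asarray(rows)
        lengths_arr = np.asarray(lengths)
        tip_depths = lengths_arr @ incidence
        return cls(lengths_arr, incidence, tip_depths, list(taxon_ids))


def _tree_index(table: CommunityTable, tree: skbio.TreeNode, prune: bool):
    table, tree, dropped = reconcile_taxa(table, tree, prune=prune)
    return table, TreeIndex.build(tree, table.taxon_ids), dropped


def alpha_diversity(
    table: CommunityTable, tree: skbio.TreeNode | None = None, *, prune: bool = False
) -> pd.DataFrame:
    """Per-sample richness, Shannon H', Pielou's J and (with a tree) Faith's PD.

    J = H'/ln(richness); undefined (NaN, with a warning) for single-taxon
    samples.  Samples with zero depth are rejected.
    """
    rel = table.relative_abundance()
    richness = (table.counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    pielou = np.full(table.n_samples, np.nan)
    multi = richness > 1
    pielou[multi] = shannon[multi] / np.log(richness[multi])
    if (~multi).any():
        warnings.warn("Pielou's J undefined for single-taxon samples; set to NaN")
    out = pd.DataFrame(
        {"richness": richness, "shannon": shannon, "pielou": pielou},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    if tree is not None:
        table_r, idx, _ = _tree_index(table, tree, prune)
        present = (table_r.counts > 0) @ idx.incidence.T > 0
        out["faith_pd"] = present @ idx.lengths
    return out


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on counts."""
    vals = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(vals, list(table.sample_ids), "bray_curtis", normalized=True)


def unifrac(
    table: CommunityTable,
    tree: skbio.TreeNode,
    *,
    weighted: bool,
    normalized: bool = True,
    prune: bool = False,
) -> DistanceMatrix:
    """UniFrac distance matrix between all sample pairs.

    Unweighted: unique branch length / total branch length across the two
    samples' subtrees (inherently normalized; the raw flag only affects
    the weighted variant).  Weighted raw: sum over branches of
    length x |proportion difference|; weighted normalized divides by the
    abundance-weighted root-to-tip scale, bounding it to [0, 1].
    """
    table, idx, _ = _tree_index(table, tree, prune)
    if weighted:
        prop = table.relative_abundance() @ idx.incidence.T  # samples x branches
        raw = squareform(pdist(prop, metric="cityblock", w=idx.lengths))
        if not normalized:
            return DistanceMatrix(
                raw, list(table.sample_ids), "weighted_unifrac_raw", normalized=False
            )
        scale = table.relative_abundance() @ idx.tip_depths  # per-sample depth scale
        denom = scale[:, None] + scale[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, raw / denom, 0.0)
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(
            vals, list(table.sample_ids), "weighted_unifrac", normalized=True
        )
    present = ((table.counts > 0) @ idx.incidence.T > 0).astype(float)
    shared = (present * idx.lengths) @ present.T
    totals = present @ idx.lengths
    union = totals[:, None] + totals[None, :] - shared
    unique = union - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, unique / union, 0.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(
        vals, list(table.sample_ids), "unweighted_unifrac", normalized=True
    )


def compare_resemblances(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> dict:
    """Mantel and Procrustes agreement between two resemblance matrices.

    Procrustes correlation is sqrt(1 - m2) between the two PCoA
    embeddings, with a permutation p-value from re-randomizing sample
    order in the second embedding.
    """
    from .mvstats import mantel, pcoa

    mantel_res = mantel(d1, d2, n_perm=n_perm, seed=seed)
    ord1, ord2 = pcoa(d1), pcoa(d2)
    k = min(ord1.coordinates.shape[1], ord2.coordinates.shape[1])
    from scipy.spatial import procrustes as _procrustes

    _, _, m2 = _procrustes(ord1.coordinates[:, :k], ord2.coordinates[:, :k])
    corr = float(np.sqrt(max(0.0, 1.0 - m2)))
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(d1.n)
        _, _, m2p = _procrustes(ord1.coordinates[:, :k], ord2.coordinates[perm, :k])
        if 1.0 - m2p >= 1.0 - m2 - 1e-12:
            hits += 1
    return {
        "mantel_r": mantel_res["r"],
        "mantel_p": mantel_res["p"],
        "procrustes_correlation": corr,
        "procrustes_p": hits / (n_perm + 1),
    }
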