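"""Prevalence and dominance analysis: top-k taxa and phylum summaries.

The divergence signature of interest: when communities in a group share
their dominants, the union of per-sample top-k sets stays near k; when
each community elevates its own dominants, the union approaches
k x n_samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import UNIDENTIFIED, CommunityTable, SampleFrame, TaxonomyTable


@dataclass
class TopKReport:
    k: int
    group: str
    ranked: dict[str, list[str]]  # per-sample ranked top-k taxon lists
    union: list[str]
    table: pd.DataFrame  # per union taxon: cumulative % abundance, % occurrence, phylum


def top_k_analysis(
    table: CommunityTable,
    metadata: SampleFrame,
    taxonomy: TaxonomyTable | None = None,
    k: int = 10,
    group: str = "fire_affected",
) -> TopKReport:
    """Top-k most abundant taxa per sample in a fire class, and their union.

    Ties are broken lexicographically by taxon id (deterministic).
    Cumulative % abundance is each taxon's share of the group's total
    count; % occurrence is the share of group samples where it is
    detected.
    """
    sample_ids = [s for s in table.sample_ids if metadata.fire_class.get(s) == group]
    if not sample_ids:
        raise ValueError(f"no samples in class {group!r}")
    sub = table.select_samples(sample_ids)
    ranked: dict[str, list[str]] = {}
    taxa_arr = np.asarray(sub.taxon_ids)
    for i, s in enumerate(sample_ids):
        counts = sub.counts[i]
        richness = int((counts > 0).sum())
        kk = min(k, richness)
        if kk < k:
            warnings.warn(f"sample {s}: richness {richness} < k={k}; list truncated")
        # sort by (-count, taxon id) for a deterministic tie-break
        order = np.lexsort((taxa_arr, -counts))[:kk]
        ranked[s] = [t for t in taxa_arr[order]]
    union = sorted(set().union(*ranked.values()))
    group_total = sub.counts.sum()
    rows = {}
    for t in union:
        j = sub.taxon_ids.index(t)
        rows[t] = {
            "cumulative_pct_abundance": 100.0 * sub.counts[:, j].sum() / group_total,
            "pct_occurrence": 100.0 * (sub.counts[:, j] > 0).mean(),
            "phylum": taxonomy.phylum(t) if taxonomy is not None else UNIDENTIFIED,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "cumulative_pct_abundance", ascending=False
    )
    return TopKReport(k=k, group=group, ranked=ranked, union=union, table=df)


def phylum_summary(
    table: CommunityTable,
    taxonomy: TaxonomyTable,
    metadata: SampleFrame,
    *,
    rare_threshold: float = 0.01,
) -> pd.DataFrame:
    """Mean per-class relative abundance collapsed to phylum.

    Taxa without a phylum assignment go to the 'unidentified' bin; phyla
    whose overall mean relative abundance is below ``rare_threshold``
    are pooled into a 'below 0.01' bin.  Rows are phyla, columns fire
    classes; each column sums to 1.
    """
    rel = table.relative_abundance()
    phyla = taxonomy.phyla(table.taxon_ids)
    rel_df = pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids)
    by_phylum = rel_df.T.groupby(phyla).sum().T  # samples x phyla
    classes = metadata.fire_class.reindex(by_phylum.index)
    class_means = by_phylum.groupby(classes).mean().T  # phyla x classes
    overall = by_phylum.mean(axis=0)
    rare = overall[overall < rare_threshold].index
    if len(rare):
        pooled = class_means.loc[rare].sum(axis=0)
        class_means = class_means.drop(index=rare)
        class_means.loc[f"below {rare_threshold:g}"] = pooled
    return class_means.sort_index()
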