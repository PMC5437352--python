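"""Standard preprocessing chain: collapse replicates, rarefy, drop singletons.

The pipeline order is fixed — collapse technical replicates, subsample
every soil to an even depth, then remove dataset-wide singletons — and
each step returns a new table so provenance can record before/after
depths.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CommunityTable

log = logging.getLogger(__name__)


def collapse_replicates(table: CommunityTable, mapping: dict[str, str]) -> CommunityTable:
    """Sum technical-replicate counts into one column per soil.

    ``mapping`` sends each replicate sample id to its soil id; every
    sample in the table must be mapped.
    """
    unmapped = [s for s in table.sample_ids if s not in mapping]
    if unmapped:
        raise KeyError(f"samples not mapped to a soil: {unmapped}")
    soils: list[str] = []
    for s in table.sample_ids:
        if mapping[s] not in soils:
            soils.append(mapping[s])
    out = np.zeros((len(soils), table.n_taxa), dtype=np.int64)
    for i, s in enumerate(table.sample_ids):
        out[soils.index(mapping[s])] += table.counts[i]
    return CommunityTable(out, soils, list(table.taxon_ids))


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; reproducible given
    ``seed``.  Refuses if any sample is shallower than ``depth``.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    depths = table.depths
    shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
    if shallow:
        raise ValueError(
            f"requested depth {depth} exceeds depth of samples: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        if depths[i] == depth:
            out[i] = table.counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CommunityTable(out, list(table.sample_ids), list(table.taxon_ids))


def remove_singletons(table: CommunityTable) -> CommunityTable:
    """Drop taxa observed exactly once in the whole data set.

    Singleton status is dataset-wide (total count == 1), not per-sample;
    taxon order is otherwise preserved.
    """
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("removed %d singleton taxa", n_dropped)
    return CommunityTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
    )


def standard_prep(
    table: CommunityTable,
    mapping: dict[str, str] | None,
    depth: int,
    seed: int,
) -> tuple[CommunityTable, dict]:
    """Collapse -> rarefy -> remove singletons, with a provenance record."""
    if mapping is not None:
        table = collapse_replicates(table, mapping)
    rarefied = rarefy(table, depth, seed)
    final = remove_singletons(rarefied)
    prov = {
        "depth_requested": int(depth),
        "seed": int(seed),
        "n_samples": final.n_samples,
        "n_taxa": final.n_taxa,
        "singletons_removed": rarefied.n_taxa - final.n_taxa,
        "post_singleton_depths": final.depths.tolist(),
    }
    return final, prov
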