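"""Shared data model: community tables, sample metadata, taxonomy, distances.

The central object is :class:`CommunityTable`, an integer sample x taxon
count matrix.  Phylogenies are represented directly as rooted
:class:`skbio.TreeNode` objects; this module only adds validation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

FIRE_CLASSES = ("fire_affected", "recovered", "reference")

#: Canonical seven-rank taxonomy, domain through species.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNIDENTIFIED = "unidentified"


class SchemaError(ValueError):
    """An input file or frame does not match the expected layout."""


@dataclass
class CommunityTable:
    """Integer count matrix, samples as rows, taxa as columns.

    Taxa whose whole-table total is zero are dropped at construction so
    that every retained taxon is observed at least once.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    #: optional generator/preprocessing record (config echo, seeds)
    provenance: dict | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts contain NaN or infinite values")
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise SchemaError("duplicate taxon ids")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        keep = counts.sum(axis=0) > 0
        if not keep.all():
            counts = counts[:, keep]
            self.taxon_ids = [t for t, k in zip(self.taxon_ids, keep) if k]
        self.counts = counts

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total counts (sequencing depth)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (rows sum to 1)."""
        depths = self.depths
        if (depths == 0).any():
            bad = [s for s, d in zip(self.sample_ids, depths) if d == 0]
            raise ValueError(f"samples with zero depth: {bad}")
        rel = self.counts / depths[:, None]
        # guard against accumulated rounding; renormalize within 1e-12
        rel /= rel.sum(axis=1, keepdims=True)
        return rel

    def to_dataframe(self) -> pd.DataFrame:
        """Taxa-as-rows DataFrame (the on-disk TSV orientation)."""
        return pd.DataFrame(
            self.counts.T, index=self.taxon_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityTable":
        """Build from a taxa-as-rows DataFrame."""
        return cls(
            counts=df.to_numpy().T,
            sample_ids=list(df.columns),
            taxon_ids=list(df.index),
        )

    def select_samples(self, sample_ids) -> "CommunityTable":
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        return CommunityTable(
            self.counts[idx], [self.sample_ids[i] for i in idx], list(self.taxon_ids)
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample resemblance matrix.

    ``normalized`` records whether the metric is bounded to [0, 1]; raw
    (non-normalized) weighted UniFrac can exceed 1.
    """

    values: np.ndarray
    ids: list[str]
    metric_name: str = "unknown"
    normalized: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        v = (v + v.T) / 2.0
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal not zero")
        np.fill_diagonal(v, 0.0)
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        v = np.clip(v, 0.0, None)
        if self.normalized and (v > 1 + 1e-12).any():
            raise ValueError(
                f"{self.metric_name}: values exceed 1 but matrix flagged normalized"
            )
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def filter(self, sample_ids) -> "DistanceMatrix":
        idx = [self.ids.index(str(s)) for s in sample_ids]
        return DistanceMatrix(
            self.values[np.ix_(idx, idx)],
            [self.ids[i] for i in idx],
            metric_name=self.metric_name,
            normalized=self.normalized,
        )


@dataclass
class SampleFrame:
    """Per-sample metadata: fire class, temperature, chemistry, coordinates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "fire_class" not in df.columns:
            raise SchemaError("metadata missing required column 'fire_class'")
        bad = set(df["fire_class"]) - set(FIRE_CLASSES)
        if bad:
            raise SchemaError(f"unknown fire_class values: {sorted(bad)}")
        if "temperature" in df.columns:
            if not np.all(np.isfinite(df["temperature"].astype(float))):
                raise SchemaError("temperature must be finite for all samples")
        if df.index.duplicated().any():
            raise SchemaError("duplicate sample ids in metadata")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def fire_class(self) -> pd.Series:
        return self.data["fire_class"]

    @property
    def temperature(self) -> pd.Series:
        return self.data["temperature"].astype(float)

    def xy(self) -> np.ndarray:
        """Planar coordinates in metres; requires x and y columns."""
        for c in ("x", "y"):
            if c not in self.data.columns:
                raise SchemaError(f"metadata missing coordinate column '{c}'")
        xy = self.data[["x", "y"]].astype(float).to_numpy()
        if not np.all(np.isfinite(xy)):
            raise SchemaError("non-finite coordinates")
        return xy

    def classes(self) -> dict[str, list[str]]:
        """Sample ids grouped by fire class, in table order."""
        out: dict[str, list[str]] = {}
        for sid, cls in self.fire_class.items():
            out.setdefault(cls, []).append(str(sid))
        return out

    def loc(self, sample_ids) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """Per-taxon ranked lineage (domain..species), 'unassigned' where unknown."""

    data: pd.DataFrame
    is_de_novo: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise SchemaError(f"taxonomy missing rank columns: {missing}")
        if self.is_de_novo is None:
            self.is_de_novo = pd.Series(False, index=self.data.index)

    def phylum(self, taxon_id: str) -> str:
        """Phylum assignment; never fails, returns the sentinel when unknown."""
        if taxon_id not in self.data.index:
            return UNIDENTIFIED
        p = str(self.data.loc[taxon_id, "phylum"])
        if p in ("", "unassigned", "nan", UNIDENTIFIED):
            return UNIDENTIFIED
        return p

    def phyla(self, taxon_ids) -> pd.Series:
        return pd.Series({t: self.phylum(t) for t in taxon_ids})


def validate_tree(tree: skbio.TreeNode, *, root_at_midpoint: bool = False) -> skbio.TreeNode:
    """Check a phylogeny against the pipeline's invariants.

    The tree must be rooted (bifurcation at the root), have unique tip
    labels and non-negative branch lengths.  An unrooted (trifurcating)
    tree is rejected unless ``root_at_midpoint`` is set.
    """
    n_children = len(tree.children)
    if n_children > 2:
        if not root_at_midpoint:
            raise ValueError(
                "tree is unrooted (root has >2 children); pass "
                "root_at_midpoint=True to root it"
            )
        tree = tree.root_at_midpoint()
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def reconcile_taxa(
    table: CommunityTable, tree: skbio.TreeNode, *, prune: bool = False
) -> tuple[CommunityTable, skbio.TreeNode, list[str]]:
    """Reconcile table taxa with tree tips.

    Taxa absent from the tree abort phylogenetic metrics by default
    (silent pruning changes UniFrac denominators); with ``prune`` they
    are dropped from the table and the dropped ids are returned.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if not missing:
        return table, tree, []
    if not prune:
        raise ValueError(
            f"{len(missing)} table taxa missing from tree (e.g. {missing[:3]}); "
            "pass prune=True to drop them"
        )
    keep = [i for i, t in enumerate(table.taxon_ids) if t in tips]
    pruned = CommunityTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [table.taxon_ids[i] for i in keep],
    )
    return pruned, tree, missing
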