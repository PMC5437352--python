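"""Synthetic communities with known assembly processes.

Three generators cover the assembly regimes the downstream statistics
are meant to distinguish:

* ``simulate_neutral_local`` — pure dispersal + drift: the Hubbell/Sloan
  urn with per-death immigration probability ``m`` from a fixed
  metacommunity.
* ``simulate_niche_local`` — the same urn with immigration and birth
  probabilities reweighted by a Gaussian thermal-fitness kernel raised
  to a selection strength ``sigma`` (``sigma=0`` reduces exactly to the
  neutral generator, same seed, same draws).
* ``simulate_divergent_dominants`` — thermally filtered multinomial
  communities in which round-robin "priority groups" of hot samples each
  elevate a distinct random subset of thermotolerant taxa, emulating
  priority effects: dominant membership diverges between groups while
  every boosted taxon stays detectable at low abundance everywhere.

``generate_chronosequence`` composes these into an 18-soil study: 2
reference + 7 recovered soils at ambient temperature (12-15 °C)
assembled neutrally, and 9 fire-affected soils at 21-58 °C assembled by
the divergent-dominants process, together with a coalescent-style tree,
clade-based synthetic taxonomy, and metadata (temperature, chemistry
with NH4/NO3 coupled to temperature, planar coordinates with no spatial
process).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from ._urn import run_urn_sample
from .containers import RANKS, CommunityTable, SampleFrame, TaxonomyTable

REFERENCE_TEMP_RANGE = (12.0, 15.0)
FIRE_TEMP_RANGE = (21.0, 58.0)


@dataclass
class Metacommunity:
    """Regional species pool: relative abundances and thermal traits."""

    taxon_ids: list[str]
    p: np.ndarray
    thermal_optimum: np.ndarray
    thermal_breadth: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p <= 0).any():
            raise ValueError("metacommunity abundances must be positive")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("metacommunity abundances must sum to 1")
        if (np.asarray(self.thermal_breadth) <= 0).any():
            raise ValueError("thermal breadths must be positive")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def fitness(self, temperature: float, sigma: float) -> np.ndarray:
        """Gaussian thermal fitness raised to the selection strength."""
        z = (temperature - self.thermal_optimum) / self.thermal_breadth
        return np.exp(-0.5 * z * z) ** sigma


@dataclass
class ScenarioConfig:
    """Study design for the synthetic chronosequence.

    Defaults mirror the study layout: 18 soils in three fire classes,
    ambient classes at 12-15 °C and fire-affected at 21-58 °C, three
    priority groups among the hot soils.
    """

    n_reference: int = 2
    n_recovered: int = 7
    n_fire_affected: int = 9
    n_taxa: int = 300
    N: int = 1000
    m: float = 0.5
    selection_strength: float = 5.0
    priority_groups: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_reference", "n_recovered", "n_fire_affected", "n_taxa", "N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.m <= 1:
            raise ValueError("m must be in (0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.priority_groups < 1:
            raise ValueError("priority_groups must be >= 1")


def make_metacommunity(
    S: int, seed: int, *, lognormal_sigma: float = 1.5
) -> Metacommunity:
    """Lognormal regional pool with uniform thermal optima on [5, 65] °C."""
    rng = np.random.default_rng(seed)
    ids = [f"OTU{j + 1:04d}" for j in range(S)]
    raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=S)
    p = raw / raw.sum()
    optima = rng.uniform(5.0, 65.0, size=S)
    breadths = rng.uniform(4.0, 12.0, size=S)
    return Metacommunity(ids, p, optima, breadths)


def _check_urn_args(N: int, m: float) -> None:
    if N < 10:
        raise ValueError("N < 10: urn stationarity unreliable at tiny community size")
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")


def simulate_niche_local(
    meta: Metacommunity,
    N: int,
    m: float,
    temperatures,
    sigma: float,
    seed: int,
    *,
    burn_in_factor: int | None = None,
) -> CommunityTable:
    """Urn dynamics with thermal selection of strength ``sigma``.

    Each sample runs an independent N-individual community for
    ``burn_in_factor * N`` death/replacement events from a
    metacommunity-weighted initial draw.  The default burn-in scales
    with the relaxation time of the immigration process,
    max(10, ceil(3/m)) generations of N events, so low-immigration
    communities still reach stationarity.  ``sigma=0`` is exactly the
    neutral process.
    """
    _check_urn_args(N, m)
    if burn_in_factor is None:
        burn_in_factor = max(10, int(np.ceil(3.0 / m)))
    temperatures = np.atleast_1d(np.asarray(temperatures, dtype=float))
    rng = np.random.default_rng(seed)
    n_steps = burn_in_factor * N
    counts = np.zeros((len(temperatures), meta.n_taxa), dtype=np.int64)
    for i, T in enumerate(temperatures):
        w = meta.fitness(T, sigma)
        q = meta.p * w
        if q.sum() <= 0:
            raise ValueError(f"no taxon has positive fitness at T={T}")
        q = q / q.sum()
        init = rng.multinomial(N, q)
        counts[i] = run_urn_sample(rng, init, w, q, m, n_steps)
    sample_ids = [f"S{i + 1:03d}" for i in range(len(temperatures))]
    table = CommunityTable(counts, sample_ids, list(meta.taxon_ids))
    table.provenance = {
        "generator": "niche_urn",
        "N": int(N),
        "m": float(m),
        "sigma": float(sigma),
        "temperatures": temperatures.tolist(),
        "seed": int(seed),
        "burn_in_steps": int(n_steps),
    }
    return table


def simulate_neutral_local(
    meta: Metacommunity, N: int, m: float, n_samples: int, seed: int, **kwargs
) -> CommunityTable:
    """Neutral urn: ``simulate_niche_local`` at ``sigma=0``."""
    temps = np.full(n_samples, 13.0)  # irrelevant at sigma=0
    return simulate_niche_local(meta, N, m, temps, 0.0, seed, **kwargs)


def simulate_divergent_dominants(
    meta: Metacommunity,
    N: int,
    temperatures,
    priority_groups: int,
    seed: int,
    *,
    filter_sigma: float = 2.5,
    n_boost: int = 8,
    dominance_share: float = 0.10,
    background_share: float = 0.004,
    share_jitter: float = 0.8,
    thermotolerant_threshold: float = 38.0,
) -> CommunityTable:
    """Priority-effect communities with group-specific dominants.

    Samples are assigned round-robin to ``priority_groups``; each group
    elevates its own random subset of ``n_boost`` thermotolerant taxa
    (optimum above ``thermotolerant_threshold``) to a fixed per-taxon
    probability ``dominance_share`` before an N-individual multinomial
    draw.  A priority effect decouples local dominance from regional
    abundance, so the boost is a share, not a multiplier: the same taxon
    dominates its own group's soils while keeping only a small
    ``background_share`` elsewhere — part of the rare biosphere, but
    detectable.  Non-boosted taxa split the remaining mass in proportion
    to pool abundance times Gaussian thermal fitness (``filter_sigma``).
    """
    temperatures = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if priority_groups < 1:
        raise ValueError("priority_groups must be >= 1")
    rng = np.random.default_rng(seed)
    thermo = np.flatnonzero(meta.thermal_optimum >= thermotolerant_threshold)
    if len(thermo) < n_boost * priority_groups:
        raise ValueError(
            "not enough thermotolerant taxa for the requested priority groups"
        )
    chosen = rng.choice(thermo, size=n_boost * priority_groups, replace=False)
    group_sets = [
        chosen[g * n_boost : (g + 1) * n_boost] for g in range(priority_groups)
    ]
    all_boosted = np.concatenate(group_sets)
    boost_mass = (
        n_boost * dominance_share
        + (len(all_boosted) - n_boost) * background_share
    )
    if boost_mass >= 0.9:
        raise ValueError("boost shares leave too little mass for the community")
    counts = np.zeros((len(temperatures), meta.n_taxa), dtype=np.int64)
    for i, T in enumerate(temperatures):
        g = i % priority_groups
        q = meta.p * meta.fitness(T, filter_sigma)
        q[all_boosted] = 0.0
        if q.sum() <= 0:
            raise ValueError(f"no non-boosted taxon has positive fitness at T={T}")
        q *= (1.0 - boost_mass) / q.sum()
        # lognormal per-sample jitter: group-mates share dominants but not
        # their ranks, mirroring strong abundance contrasts between soils;
        # the rare-biosphere background fluctuates less, keeping dominants
        # of other groups reliably detectable
        q[all_boosted] = background_share * rng.lognormal(
            0.0, share_jitter / 2.0, len(all_boosted)
        )
        q[group_sets[g]] = dominance_share * rng.lognormal(
            0.0, share_jitter, n_boost
        )
        counts[i] = rng.multinomial(N, q / q.sum())
    sample_ids = [f"S{i + 1:03d}" for i in range(len(temperatures))]
    table = CommunityTable(counts, sample_ids, list(meta.taxon_ids))
    table.provenance = {
        "generator": "divergent_dominants",
        "N": int(N),
        "priority_groups": int(priority_groups),
        "temperatures": temperatures.tolist(),
        "seed": int(seed),
        "group_of_sample": [int(i % priority_groups) for i in range(len(temperatures))],
        "boosted_taxa_by_group": [
            [meta.taxon_ids[j] for j in g] for g in group_sets
        ],
    }
    return table


def simulate_tree(
    taxon_ids,
    seed: int,
    *,
    thermal_optimum: np.ndarray | None = None,
    cluster_threshold: float = 38.0,
    branch_scale: float = 0.1,
) -> skbio.TreeNode:
    """Random Kingman-coalescent tree (ultrametric, time-scaled).

    Coalescence intervals are exponential with rate k(k-1)/2 in units of
    ``branch_scale``.  With ``thermal_optimum`` given, thermotolerant
    tips (optimum above ``cluster_threshold``) coalesce among themselves
    before joining the rest, so thermophiles are phylogenetically
    aggregated.
    """
    taxon_ids = list(taxon_ids)
    rng = np.random.default_rng(seed)

    def _coalesce(labels: list[str], t0: float = 0.0) -> tuple[str, float]:
        # lineages: (newick fragment, node height); returns (fragment, height)
        nodes: list[tuple[str, float]] = [(t, 0.0) for t in labels]
        t = t0
        while len(nodes) > 1:
            k = len(nodes)
            t += rng.exponential(branch_scale * 2.0 / (k * (k - 1)))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            (a, ha), (b, hb) = nodes[i], nodes[j]
            nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
            nodes.append((f"({a}:{t - ha:.8f},{b}:{t - hb:.8f})", t))
        return nodes[0]

    if len(taxon_ids) == 1:
        newick = f"({taxon_ids[0]}:{rng.exponential(branch_scale):.8f});"
    elif thermal_optimum is not None and 0 < (
        np.asarray(thermal_optimum) >= cluster_threshold
    ).sum() < len(taxon_ids) - 1:
        hot = np.asarray(thermal_optimum) >= cluster_threshold
        hot_frag, h1 = _coalesce([t for t, h in zip(taxon_ids, hot) if h])
        cold_frag, h2 = _coalesce([t for t, h in zip(taxon_ids, hot) if not h])
        root_h = max(h1, h2) + rng.exponential(branch_scale)
        newick = (
            f"({hot_frag}:{root_h - h1:.8f},{cold_frag}:{root_h - h2:.8f});"
        )
    else:
        frag, _ = _coalesce(taxon_ids)
        newick = f"{frag};"
    return skbio.TreeNode.read([newick])


def assign_taxonomy(
    tree: skbio.TreeNode,
    seed: int,
    *,
    n_phyla: int = 12,
    frac_unassigned: float = 0.08,
    frac_de_novo: float = 0.2,
) -> TaxonomyTable:
    """Synthetic clade-based taxonomy: phyla are contiguous tree clades."""
    rng = np.random.default_rng(seed)
    tips = [t.name for t in tree.tips()]
    per_phylum = max(1, int(np.ceil(len(tips) / n_phyla)))
    rows = {}
    for i, t in enumerate(tips):
        phylum = f"Phylum{i // per_phylum + 1:02d}"
        if rng.random() < frac_unassigned:
            lineage = ["Bacteria"] + ["unassigned"] * (len(RANKS) - 1)
        else:
            lineage = ["Bacteria", phylum] + ["unassigned"] * (len(RANKS) - 3) + [t]
        rows[t] = lineage
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    de_novo = pd.Series(rng.random(len(tips)) < frac_de_novo, index=df.index)
    return TaxonomyTable(df, is_de_novo=de_novo)


def generate_chronosequence(config: ScenarioConfig | None = None) -> dict:
    """Full 18-soil synthetic study with known assembly processes.

    Returns a dict with ``table``, ``tree``, ``metadata``, ``taxonomy``
    and ``metacommunity``.  Reference and recovered soils assemble
    neutrally at ambient temperature; fire-affected soils assemble by
    the divergent-dominants (priority-effect) process along the 21-58 °C
    gradient.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    meta = make_metacommunity(config.n_taxa, int(rng.integers(2**31)))
    n_ambient = config.n_reference + config.n_recovered
    t_ambient = rng.uniform(*REFERENCE_TEMP_RANGE, size=n_ambient)
    t_fire = np.sort(rng.uniform(*FIRE_TEMP_RANGE, size=config.n_fire_affected))

    ambient = simulate_niche_local(
        meta, config.N, config.m, t_ambient, 0.0, int(rng.integers(2**31))
    )
    fire = simulate_divergent_dominants(
        meta, config.N, t_fire, config.priority_groups, int(rng.integers(2**31)),
        filter_sigma=max(config.selection_strength / 2.0, 1.0),
    )

    sample_ids = (
        [f"Ref{i + 1:02d}" for i in range(config.n_reference)]
        + [f"Rec{i + 1:02d}" for i in range(config.n_recovered)]
        + [f"Fire{i + 1:02d}" for i in range(config.n_fire_affected)]
    )
    counts = np.vstack([ambient.counts, _aligned(fire, ambient.taxon_ids)])
    taxa = list(ambient.taxon_ids)
    extra = [t for t in fire.taxon_ids if t not in set(ambient.taxon_ids)]
    if extra:
        counts = np.hstack(
            [counts, np.vstack([np.zeros((n_ambient, len(extra)), dtype=np.int64),
                                 _extract(fire, extra)])]
        )
        taxa += extra
    table = CommunityTable(counts, sample_ids, taxa)

    classes = (
        ["reference"] * config.n_reference
        + ["recovered"] * config.n_recovered
        + ["fire_affected"] * config.n_fire_affected
    )
    temps = np.concatenate([t_ambient, t_fire])
    n = len(sample_ids)
    chem = {
        "pH": np.where(
            np.array(classes) == "recovered",
            rng.normal(4.4, 0.3, n),
            np.where(np.array(classes) == "reference", rng.normal(5.9, 0.3, n),
                     rng.normal(5.0, 0.8, n)),
        ),
        # ammonium and nitrate increase with temperature
        "NH4": 2.0 + 0.15 * (temps - 12.0) + rng.normal(0, 0.8, n),
        "NO3": 3.0 + 0.20 * (temps - 12.0) + rng.normal(0, 1.0, n),
        "SO4": rng.lognormal(2.0, 0.5, n),
        "K": rng.lognormal(4.0, 0.3, n),
        "Ca": rng.lognormal(5.0, 0.6, n),
        "Mg": rng.lognormal(4.5, 0.4, n),
        "P": rng.lognormal(2.5, 0.4, n),
        "As": rng.lognormal(0.5, 0.6, n),
        "Fe": rng.lognormal(3.5, 0.5, n),
        "moisture": rng.uniform(10, 40, n),
        "organic_matter": rng.uniform(2, 15, n),
    }
    metadata = SampleFrame(
        pd.DataFrame(
            {
                "fire_class": classes,
                "temperature": temps,
                "x": rng.uniform(0, 500, n),
                "y": rng.uniform(0, 500, n),
                "fire_history_years": np.where(
                    np.array(classes) == "recovered", rng.integers(10, 35, n), 0
                ),
                **chem,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    # unclustered coalescent: thermal tolerance is treated as phylogenetically
    # dispersed so phylogenetic and taxonomic beta signals stay comparable
    tree = simulate_tree(meta.taxon_ids, int(rng.integers(2**31)))
    taxonomy = assign_taxonomy(tree, int(rng.integers(2**31)))
    return {
        "table": table,
        "tree": tree,
        "metadata": metadata,
        "taxonomy": taxonomy,
        "metacommunity": meta,
        "config": config,
    }


def _aligned(table: CommunityTable, taxon_ids: list[str]) -> np.ndarray:
    idx = {t: j for j, t in enumerate(table.taxon_ids)}
    out = np.zeros((table.n_samples, len(taxon_ids)), dtype=np.int64)
    for j, t in enumerate(taxon_ids):
        if t in idx:
            out[:, j] = table.counts[:, idx[t]]
    return out


def _extract(table: CommunityTable, taxon_ids: list[str]) -> np.ndarray:
    idx = {t: j for j, t in enumerate(table.taxon_ids)}
    return table.counts[:, [idx[t] for t in taxon_ids]]
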