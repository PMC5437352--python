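"""End-to-end chronosequence analysis.

``run_chronosequence_analysis`` strings every stage together on one data
bundle (real files or the synthetic chronosequence): alpha diversity
with class-wise tests, beta resemblances, PERMANOVA / dispersion /
envfit / temperature-partialled ordination, spatial Mantel, per-class
neutral fits, beta-null deviations with group comparison, and the
top-10 / phylum summaries.  All randomness is routed through seeds
derived from one master seed, so a rerun with the same inputs is
numerically identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from scipy.stats import ttest_ind

from . import betanull, diversity, dominance, mvstats, neutral
from .containers import CommunityTable, SampleFrame, TaxonomyTable


@dataclass
class AnalysisConfig:
    beta_null_iterations: int = 199
    n_permutations: int = 999
    permanova_permutations: int = 1000
    top_k: int = 10
    seed: int = 0
    metrics: tuple[str, ...] = ("bray_curtis", "weighted_unifrac")


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def run_chronosequence_analysis(
    table: CommunityTable,
    tree: skbio.TreeNode,
    metadata: SampleFrame,
    taxonomy: TaxonomyTable | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full analysis bundle; any stage failure names its stage."""
    config = config or AnalysisConfig()
    seeds = _child_seeds(config.seed, 8)
    bundle: dict = {"config": config, "stages_completed": []}

    def stage(name):
        def deco(fn):
            try:
                bundle[name] = fn()
                bundle["stages_completed"].append(name)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    classes = metadata.fire_class.reindex(table.sample_ids)

    @stage("alpha")
    def _alpha():
        alpha = diversity.alpha_diversity(table, tree)
        tests = {}
        for metric in ("richness", "pielou", "faith_pd"):
            if metric not in alpha.columns:
                continue
            pairs = {}
            for a, b in (("fire_affected", "recovered"),
                         ("fire_affected", "reference"),
                         ("recovered", "reference")):
                va = alpha.loc[classes == a, metric].dropna()
                vb = alpha.loc[classes == b, metric].dropna()
                if len(va) >= 2 and len(vb) >= 2:
                    t = ttest_ind(va, vb, equal_var=False)
                    pairs[f"{a}_vs_{b}"] = {
                        "statistic": float(t.statistic),
                        "p": float(t.pvalue),
                        "mean_diff": float(va.mean() - vb.mean()),
                    }
            tests[metric] = pairs
        return {"records": alpha, "class_tests": tests}

    @stage("beta")
    def _beta():
        out = {"bray_curtis": diversity.bray_curtis(table)}
        out["weighted_unifrac"] = diversity.unifrac(
            table, tree, weighted=True, normalized=True
        )
        out["weighted_unifrac_raw"] = diversity.unifrac(
            table, tree, weighted=True, normalized=False
        )
        out["unweighted_unifrac"] = diversity.unifrac(table, tree, weighted=False)
        return out

    beta = bundle["beta"]
    d_main = beta["weighted_unifrac"]

    @stage("permanova")
    def _permanova():
        return mvstats.permanova(
            d_main, classes, n_perm=config.permanova_permutations, seed=seeds[0]
        )

    @stage("dispersion")
    def _dispersion():
        return mvstats.dispersion_test(
            d_main, classes, n_perm=config.n_permutations, seed=seeds[1]
        )

    @stage("ordination")
    def _ordination():
        ord_res = mvstats.pcoa(d_main)
        env_cols = [
            c for c in metadata.data.columns
            if c not in ("fire_class", "x", "y", "fire_history_years")
        ]
        fit = mvstats.envfit(
            ord_res, metadata.data[env_cols].astype(float),
            n_perm=config.n_permutations, seed=seeds[2],
        )
        hot_ids = [s for s in table.sample_ids
                   if metadata.fire_class.get(s) == "fire_affected"]
        partial = None
        if len(hot_ids) >= 4:
            partial = mvstats.partial_ordination(
                d_main.filter(hot_ids),
                metadata.temperature.loc[hot_ids],
            )
        return {"pcoa": ord_res, "envfit": fit, "partial_hot": partial}

    @stage("spatial")
    def _spatial():
        return mvstats.spatial_mantel(
            d_main, metadata.loc(table.sample_ids).xy(),
            n_perm=config.n_permutations, seed=seeds[3],
        )

    @stage("neutral")
    def _neutral():
        fits = {}
        for cls, ids in metadata.classes().items():
            ids = [s for s in ids if s in table.sample_ids]
            if len(ids) >= 5:
                fits[cls] = neutral.fit_neutral(table.select_samples(ids))
        fits["all"] = neutral.fit_neutral(table)
        return fits

    @stage("beta_null")
    def _beta_null():
        out = {}
        for i, metric in enumerate(config.metrics):
            res = betanull.beta_null_deviation(
                table,
                tree if metric == "weighted_unifrac" else None,
                metric=metric,
                n_iter=config.beta_null_iterations,
                seed=seeds[4 + i],
            )
            out[metric] = {
                "result": res,
                "groups": betanull.deviation_by_group(res, metadata),
            }
        return out

    @stage("dominance")
    def _dominance():
        reports = {}
        for cls in ("fire_affected", "recovered"):
            if (classes == cls).sum() > 0:
                reports[cls] = dominance.top_k_analysis(
                    table, metadata, taxonomy, k=config.top_k, group=cls
                )
        phyla = None
        if taxonomy is not None:
            phyla = dominance.phylum_summary(table, taxonomy, metadata)
        return {"top_k": reports, "phylum_summary": phyla}

    return bundle


def bundle_summary(bundle: dict, metadata: SampleFrame) -> dict:
    """JSON-serializable numeric summary of an analysis bundle."""
    perman = bundle["permanova"]
    disp = bundle["dispersion"]
    alpha = bundle["alpha"]["records"]
    classes = metadata.fire_class.reindex(alpha.index)
    out = {
        "permanova": {
            "pseudo_f": perman.pseudo_f,
            "r_squared": perman.r_squared,
            "p": perman.p_value,
        },
        "dispersion": {
            "median_dispersion": disp["median_dispersion"],
            "p": disp["p"],
        },
        "spatial_mantel": bundle["spatial"],
        "alpha_means_by_class": {
            m: alpha.groupby(classes)[m].mean().to_dict()
            for m in alpha.columns
        },
        "neutral": {k: v.summary() for k, v in bundle["neutral"].items()},
        "beta_null": {
            metric: entry["groups"]["group_means"]
            for metric, entry in bundle["beta_null"].items()
        },
        "top_k_union_size": {
            cls: len(rep.union)
            for cls, rep in bundle["dominance"]["top_k"].items()
        },
    }
    return out


def save_bundle(bundle: dict, out_dir) -> None:
    """Write the bundle's tabular pieces and a JSON summary to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["alpha"]["records"].to_csv(out / "alpha_diversity.tsv", sep="\t")
    for name, dm in bundle["beta"].items():
        pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(
            out / f"distance_{name}.tsv", sep="\t"
        )
    for metric, entry in bundle["beta_null"].items():
        entry["result"].pairs.to_csv(out / f"betanull_{metric}_pairs.tsv",
                                     sep="\t", index=False)
        entry["result"].per_sample.to_csv(out / f"betanull_{metric}_samples.tsv",
                                          sep="\t")
    summary = {
        "permanova": vars(bundle["permanova"]),
        "spatial_mantel": bundle["spatial"],
        "dispersion_medians": bundle["dispersion"]["median_dispersion"],
        "dispersion_p": bundle["dispersion"]["p"],
        "neutral": {k: v.summary() for k, v in bundle["neutral"].items()},
        "stages_completed": bundle["stages_completed"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
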