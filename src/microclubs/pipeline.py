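"""Configuration-driven orchestration of the full per-group analysis.

Per group the pipeline writes the prevalence-filtered table, the per-sample
diversity table and group summary, the richness-diversity correlation, the
SparCC rho and p matrices, the co-occurrence network (GraphML + edge list),
the Markov clustering, the club report and the heatmap-ordered correlation
matrix; across groups it writes the UniFrac distance matrix, PCoA
coordinates, the PERMANOVA result and per-group dispersions.  A JSON manifest
records every parameter, seed and surviving taxon count so any stage can be
rerun from disk; identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clubs as clubs_mod
from . import diversity as div_mod
from . import io as io_mod
from . import ordination as ord_mod
from . import sparcc as sparcc_mod
from .preprocess import FilterConfig, prevalent_taxa, remove_contaminants, total_sum_scale

__all__ = ["PipelineConfig", "run_pipeline", "summarize_groups", "auto_min_weight"]

log = logging.getLogger("microclubs")


@dataclass
class PipelineConfig:
    table: str
    metadata: str
    output_dir: str
    tree: str | None = None
    orientation: str = "samples_in_rows"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    # correlation stage
    n_inner: int = 20
    n_boot: int = 100
    exclusion_threshold: float = 0.1
    alpha: float = 0.05
    min_abs_r: float = 0.0
    # markov clustering
    inflation: float = 2.0
    expansion: int = 2
    prune: float = 1e-5
    mcl_tol: float = 1e-8
    mcl_min_weight: float | None = None  # None -> tanh(3.29 / sqrt(n - 3))
    # clubs
    min_club_size: int = 3
    rival_threshold: float = -0.4
    min_rival_edges: int = 3
    # beta diversity
    n_permutations: int = 999
    weighted_unifrac: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        return cls(**raw)


def auto_min_weight(n_samples: int) -> float:
    """Flow-graph edge threshold: the two-sided 99.9 % null band of a
    correlation coefficient at this sample size, tanh(3.29 / sqrt(n - 3))."""
    if n_samples <= 4:
        return 1.0
    return float(np.tanh(3.29 / math.sqrt(n_samples - 3)))


def summarize_groups(records: pd.DataFrame, group_of: dict[str, str]) -> pd.DataFrame:
    """Mean +/- sd of each diversity index, pooled (ALL) and per group.

    ``records`` is the per-sample table from
    :func:`microclubs.diversity.alpha_diversity_table` (samples in the index).
    """
    if records.empty:
        raise ValueError("no diversity records")
    labels = pd.Series({s: group_of[s] for s in records.index})
    out: dict[str, dict[str, str]] = {}
    columns = ["ALL"] + sorted(labels.unique())
    for col in records.columns:
        row = {}
        for name in columns:
            vals = records[col] if name == "ALL" else records.loc[labels == name, col]
            row[name] = f"{vals.mean():.4g}±{vals.std(ddof=1):.4g}" if len(vals) > 1 \
                else f"{vals.mean():.4g}±0"
        out[col] = row
    return pd.DataFrame(out).T[columns]


def _float_df(values: np.ndarray, labels) -> pd.DataFrame:
    return pd.DataFrame(values, index=labels, columns=labels)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "groups": {}}

    counts = io_mod.read_counts_table(config.table, config.orientation)
    group_of = io_mod.read_metadata(config.metadata)
    counts = counts.with_groups(group_of)
    tree = io_mod.read_tree(config.tree) if config.tree else None

    counts = remove_contaminants(counts, config.filter.contaminant_patterns)
    log.info("contaminant filter: %d taxa remain", counts.n_taxa)
    rel = total_sum_scale(counts)
    per_group_taxa = prevalent_taxa(rel, config.filter.min_prevalence, uniform_set=False)
    uniform_taxa = prevalent_taxa(rel, config.filter.min_prevalence, uniform_set=True)
    manifest["n_taxa_input"] = counts.n_taxa
    manifest["n_taxa_uniform_set"] = len(uniform_taxa)

    # --- across-group analyses -------------------------------------------
    div = div_mod.alpha_diversity_table(counts, tree=tree)
    div.to_csv(out / "diversity_per_sample.tsv", sep="\t")
    summary = summarize_groups(div, counts.group_of)
    summary.to_csv(out / "diversity_summary.tsv", sep="\t")

    groups = counts.groups()
    corr_rows = []
    for name in ["ALL"] + groups:
        sub = div if name == "ALL" else div.loc[[s for s in div.index
                                                 if counts.group_of[s] == name]]
        if len(sub) >= 3 and sub["s_obs"].nunique() > 1 and sub["inv_simpson"].nunique() > 1:
            r, p = div_mod.richness_diversity_correlation(sub["s_obs"], sub["inv_simpson"])
        else:
            r, p = float("nan"), float("nan")
        corr_rows.append({"group": name, "pearson_r": r, "p_value": p, "n": len(sub)})
    pd.DataFrame(corr_rows).to_csv(out / "richness_diversity_correlation.tsv",
                                   sep="\t", index=False)

    anova = {}
    if len(groups) >= 2:
        for col in [c for c in ("chao1", "inv_simpson", "faith_pd") if c in div.columns]:
            vecs = [div.loc[[s for s in div.index if counts.group_of[s] == g], col]
                    for g in groups]
            f, p = div_mod.one_way_anova(vecs)
            anova[col] = {"F": f, "p": p}
    manifest["anova"] = anova

    if tree is not None:
        uniform_counts = counts.select_taxa(uniform_taxa)
        dm = ord_mod.unifrac_matrix(uniform_counts, tree,
                                    weighted=config.weighted_unifrac)
        _float_df(dm.values, dm.sample_ids).to_csv(out / "unifrac_distance.tsv",
                                                   sep="\t", index_label="")
        ordn = ord_mod.pcoa(dm)
        axes = [f"PC{i + 1}" for i in range(ordn.coordinates.shape[1])]
        pd.DataFrame(ordn.coordinates, index=ordn.sample_ids, columns=axes
                     ).to_csv(out / "pcoa_coordinates.tsv", sep="\t", index_label="sample")
        labels = [counts.group_of[s] for s in dm.sample_ids]
        if len(groups) >= 2:
            perma = ord_mod.permanova(dm, labels, config.n_permutations,
                                      seed=config.seed)
            disp = ord_mod.dispersion(dm, labels, center="median")
            manifest["permanova"] = {"pseudo_F": perma.pseudo_f,
                                     "p_value": perma.p_value,
                                     "n_permutations": perma.n_permutations}
            manifest["dispersion_to_median"] = disp

    # --- per-group analyses ----------------------------------------------
    for gi, name in enumerate(groups):
        gdir = out / f"group_{name}"
        gdir.mkdir(exist_ok=True)
        samples = [s for s in counts.sample_ids if counts.group_of[s] == name]
        taxa = per_group_taxa[name]
        ginfo: dict = {"n_samples": len(samples), "n_taxa_after_filter": len(taxa)}
        log.info("group %s: %d samples, %d taxa pass the prevalence filter",
                 name, len(samples), len(taxa))
        gcounts = counts.select_samples(samples).select_taxa(taxa)
        io_mod.write_table(gcounts, gdir / "filtered_counts.tsv")
        grel = total_sum_scale(gcounts)

        if len(taxa) < 4 or len(samples) < 5:
            ginfo["skipped"] = "too few taxa or samples for correlation inference"
            manifest["groups"][name] = ginfo
            continue

        est = sparcc_mod.sparcc(gcounts, n_inner=config.n_inner,
                                exclusion_threshold=config.exclusion_threshold,
                                seed=config.seed + 101 * (gi + 1))
        est.pvals = sparcc_mod.sparcc_pvalues(gcounts, est, n_boot=config.n_boot,
                                              seed=config.seed + 101 * (gi + 1) + 1)
        est.n_boot = config.n_boot
        io_mod.write_matrix(_float_df(est.rho, est.taxon_ids), gdir / "sparcc_rho.tsv")
        io_mod.write_matrix(_float_df(est.pvals, est.taxon_ids), gdir / "sparcc_pvalues.tsv")

        network = clubs_mod.build_network(est, grel, alpha=config.alpha,
                                          min_abs_r=config.min_abs_r)
        min_w = (auto_min_weight(len(samples)) if config.mcl_min_weight is None
                 else config.mcl_min_weight)
        clustering = clubs_mod.mcl_cluster(network, inflation=config.inflation,
                                           expansion=config.expansion,
                                           prune=config.prune, tol=config.mcl_tol,
                                           min_weight=min_w)
        report = clubs_mod.club_statistics(network, clustering, config.min_club_size)
        report = clubs_mod.rival_clubs(network, clustering, report,
                                       config.min_club_size, config.rival_threshold,
                                       config.min_rival_edges)
        io_mod.write_network(network, clustering, gdir / "network.graphml", "graphml")
        io_mod.write_network(network, clustering, gdir / "network_edges.tsv", "edgelist")
        _write_club_report(report, gdir / "clubs.tsv")
        order = clubs_mod.heatmap_order(est, clustering)
        oidx = [est.taxon_ids.index(t) for t in order]
        io_mod.write_matrix(_float_df(est.rho[np.ix_(oidx, oidx)], order),
                            gdir / "sparcc_rho_heatmap_order.tsv")

        ginfo.update({
            "n_edges": network.number_of_edges(),
            "mcl_min_weight": min_w,
            "mcl_converged": clustering.converged,
            "n_social_clubs": len(report.social),
            "n_rival_pairs": len(report.rivals),
            "social_clubs": report.social,
            "rival_pairs": report.rivals,
        })
        manifest["groups"][name] = ginfo

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return manifest


def _write_club_report(report: clubs_mod.ClubReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# social clubs\nclub_id\tsize\ttightness_mean\ttightness_sd\tmembers\n")
        for c in report.social:
            fh.write(f"{c['club_id']}\t{c['size']}\t{c['tightness_mean']!r}\t"
                     f"{c['tightness_sd']!r}\t{','.join(c['members'])}\n")
        fh.write("# rival clubs\nclub_a\tclub_b\tmean_correlation\tn_edges\n")
        for r in report.rivals:
            fh.write(f"{r['club_a']}\t{r['club_b']}\t{r['mean_correlation']!r}\t{r['n_edges']}\n")


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
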