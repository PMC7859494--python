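"""Stage orchestration shared by the CLI.

Each stage takes loaded domain objects, performs its analyses, writes
its outputs (TSV with comment headers, JSON summaries, GraphML) under
an output directory, and returns the key results for reuse.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison, diversity, drivers, network, quantify
from .io import (
    CountTable,
    RunConfig,
    SampleMetadata,
    SpikeInDesign,
    TaxonomyTable,
    write_result_table,
)


def _write_json(obj, path, config: RunConfig) -> None:
    from . import __version__

    payload = {"_spikequant_version": __version__, "_seed": config.rng_seed}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def run_quantify(
    counts: CountTable,
    taxonomy: TaxonomyTable,
    design: SpikeInDesign,
    metadata: SampleMetadata,
    config: RunConfig,
    out_dir=None,
):
    """Cleaning, calibration, absolute quantification and the rarefied
    relative branch.  Returns (quant, relative, rarefied, curves)."""
    spike_counts, biological = quantify.split_spikeins(counts, taxonomy, design)
    curves = quantify.fit_standard_curves(spike_counts, design)
    cleaned = quantify.clean_biological(counts, taxonomy)
    quant = quantify.estimate_absolute_abundance(cleaned, curves, metadata)
    rarefied = quantify.rarefy(cleaned, config.rarefaction_depth, config.rng_seed)
    relative = quantify.to_relative(rarefied)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_result_table(quant.data.T, out / "quant.tsv", config)
        write_result_table(relative.data.T, out / "relative.tsv", config)
        write_result_table(rarefied.data.T, out / "rarefied.tsv", config)
        write_result_table(quantify.curves_frame(curves), out / "curves.tsv", config)
        totals, summary = quantify.summarize_totals(quant)
        report = {
            "n_input_otus": len(counts.otu_ids),
            "n_spikein_otus": spike_counts.shape[1],
            "n_cleaned_otus": len(cleaned.otu_ids),
            "rarefaction_depth": int(rarefied.sample_totals().iloc[0]),
            "total_copies_per_L": summary,
        }
        _write_json(report, out / "cleaning_report.json", config)
    return quant, relative, rarefied, curves


def run_diversity(rarefied: CountTable, tree, config: RunConfig, out_dir=None):
    alpha = diversity.alpha_diversity(
        rarefied, tree=tree, shannon_base=config.shannon_log_base
    )
    depth = int(rarefied.sample_totals().min())
    depths = sorted({max(1, depth // k) for k in (100, 20, 5, 2, 1)})
    curves = {
        sid: diversity.rarefaction_curve(
            rarefied.data.loc[sid].to_numpy(), depths, n_reps=10, seed=config.rng_seed
        )
        for sid in rarefied.sample_ids
    }
    rarefaction = pd.DataFrame(curves).T
    rarefaction.index.name = "sample_id"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_result_table(alpha, out / "alpha.tsv", config)
        write_result_table(rarefaction, out / "rarefaction.tsv", config)
    return alpha, rarefaction


def run_compare(
    relative, quant, taxonomy: TaxonomyTable, config: RunConfig, out_dir=None
):
    d_rel = comparison.bray_curtis(relative)
    d_quant = comparison.bray_curtis(quant)
    ord_rel = comparison.pcoa(d_rel)
    ord_quant = comparison.pcoa(d_quant)
    proc = comparison.procrustes_test(
        ord_rel, ord_quant, n_perm=config.n_permutations, seed=config.rng_seed
    )
    conc, conc_summary = comparison.per_otu_concordance(
        relative, quant, alpha=config.corr_alpha
    )
    agg_rel = comparison.aggregate_taxonomy(relative, taxonomy, "order", top_n=12)
    agg_quant = comparison.aggregate_taxonomy(quant, taxonomy, "order", top_n=12)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_result_table(d_rel.to_frame(), out / "distances_rel.tsv", config)
        write_result_table(d_quant.to_frame(), out / "distances_quant.tsv", config)
        for name, o in (("pcoa_rel", ord_rel), ("pcoa_quant", ord_quant)):
            coords = pd.DataFrame(
                o.coordinates,
                index=o.sample_ids,
                columns=[f"PC{i + 1}" for i in range(o.coordinates.shape[1])],
            )
            write_result_table(coords, out / f"{name}.tsv", config)
        _write_json(
            {**asdict(proc), "concordance_summary": conc_summary},
            out / "procrustes.json",
            config,
        )
        write_result_table(conc, out / "concordance.tsv", config)
        write_result_table(agg_rel.T, out / "composition_order_rel.tsv", config)
        write_result_table(agg_quant.T, out / "composition_order_quant.tsv", config)
    return d_rel, d_quant, proc, conc, conc_summary


def run_network(rarefied: CountTable, quant, config: RunConfig, out_dir=None):
    subset = network.filter_abundant(rarefied, config.abundance_threshold)
    nets = {}
    for name, table in (("relative", rarefied), ("quantitative", quant)):
        g = network.build_network(
            table,
            r_cutoff=config.corr_r_cutoff,
            alpha=config.corr_alpha,
            otu_subset=[o for o in subset if o in table.data.columns],
        )
        nets[name] = (g, network.network_attributes(g, seed=config.rng_seed))
    attrs = pd.DataFrame(
        {name: attr.to_series() for name, (_, attr) in nets.items()}
    ).T
    attrs.index.name = "branch"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        network.write_graphml(nets["relative"][0], out / "network_rel.graphml")
        network.write_graphml(nets["quantitative"][0], out / "network_quant.graphml")
        write_result_table(attrs, out / "attributes.tsv", config)
    return nets, attrs


def spatial_predictors(metadata: SampleMetadata) -> pd.DataFrame:
    """Longitude/latitude predictor block with longitude unwrapped so a
    transect crossing the antimeridian stays monotone."""
    lon = metadata.data["longitude"].to_numpy().copy()
    if lon.max() - lon.min() > 180:  # crosses the antimeridian
        lon = np.where(lon < 0, lon + 360.0, lon)
    return pd.DataFrame(
        {"longitude": lon, "latitude": metadata.data["latitude"]},
        index=metadata.data.index,
    )


def run_drivers(
    relative,
    quant,
    rarefied: CountTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable,
    alpha_table: pd.DataFrame | None,
    config: RunConfig,
    out_dir=None,
):
    from .io import ENV_VARS

    d_rel = comparison.bray_curtis(relative)
    d_quant = comparison.bray_curtis(quant)
    env = metadata.data[list(ENV_VARS)]
    space = spatial_predictors(metadata)

    rows = []
    predictor_dms = {
        var: drivers.variable_distance(metadata, var) for var in ENV_VARS
    }
    predictor_dms["Envdist"] = drivers.environmental_distance(metadata)
    predictor_dms["Geodist"] = drivers.geographic_distance(metadata)
    for var, dm in predictor_dms.items():
        row = {"variable": var}
        for branch, dcomm in (("relative", d_rel), ("quantitative", d_quant)):
            res = drivers.mantel(
                dcomm,
                dm,
                method=config.mantel_method,
                n_perm=config.n_permutations,
                seed=config.rng_seed,
            )
            row[f"r_{branch}"] = res.r
            row[f"p_{branch}"] = res.p
        rows.append(row)
    mantel_table = pd.DataFrame(rows).set_index("variable")

    vpa_results = {
        branch: drivers.vpa(
            table,
            env,
            space,
            n_perm=config.n_permutations,
            seed=config.rng_seed,
        )
        for branch, table in (("relative", relative), ("quantitative", quant))
    }

    variables = env.join(space.add_prefix("geo_"))
    if alpha_table is not None:
        variables = variables.join(alpha_table)
    corr_r, corr_q, corr_masked = drivers.variable_correlation_matrix(
        variables, alpha=config.corr_alpha
    )

    spls_results = {}
    for rank in ("phylum", "order"):
        for branch, table in (("relative", relative), ("quantitative", quant)):
            agg = comparison.aggregate_taxonomy(table, taxonomy, rank)
            agg = agg.loc[:, (agg > 0).all(axis=0)]  # subgroups present everywhere
            agg = agg.loc[:, agg.std(ddof=1) > 0]
            keepx = min(5, agg.shape[1])
            spls_results[(rank, branch)] = drivers.spls_select(
                agg, variables[list(ENV_VARS) + ["geo_longitude", "geo_latitude"]],
                ncomp=min(2, agg.shape[1], len(ENV_VARS)),
                keepx=keepx,
            )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_result_table(mantel_table, out / "mantel.tsv", config)
        _write_json(
            {branch: res.to_dict() for branch, res in vpa_results.items()},
            out / "vpa.json",
            config,
        )
        write_result_table(corr_r, out / "variable_correlations.tsv", config)
        write_result_table(corr_masked, out / "variable_correlations_masked.tsv", config)
        loadings, heatmaps = [], []
        for (rank, branch), res in spls_results.items():
            ld = res.x_loadings.copy()
            ld.insert(0, "rank", rank)
            ld.insert(1, "branch", branch)
            loadings.append(ld)
            hm = res.heatmap_r.copy()
            hm.insert(0, "rank", rank)
            hm.insert(1, "branch", branch)
            heatmaps.append(hm)
        write_result_table(pd.concat(loadings), out / "spls_loadings.tsv", config)
        write_result_table(pd.concat(heatmaps), out / "spls_heatmap.tsv", config)
    return mantel_table, vpa_results, (corr_r, corr_q, corr_masked), spls_results
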