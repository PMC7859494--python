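"""Synthetic spike-in sequencing experiments with known ground truth.

The generator places samples on a zonal transect crossing the
antimeridian, draws a lognormal community whose composition drifts
with position (distance decay), adds nine spike-in standards at
10^3/10^4/10^5/10^6 copies (3/2/2/2), and sequences each sample by a
single multinomial draw of fixed depth over the pooled spike-in and
biological template copies.

The sequenceable biological template of OTU i in sample j is
``true_abundance[j, i] * V_j * R_j`` copies, competing with the
spike-ins for reads.  Note the spike-in panel spans 10^3-10^6 copies,
so the recovery ratio ``R`` must be small enough that the sequenced
pool is commensurate with the panel -- exactly as in a real library
where only a small aliquot of the extract is amplified.  The default
``r_range`` is chosen accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .io import (
    CountTable,
    RunConfig,
    SampleMetadata,
    SpikeInDesign,
    TaxonomyTable,
    write_count_table,
    write_sample_metadata,
    write_spikein_design,
    write_taxonomy,
    write_tree,
    write_result_table,
)

#: added copies of the nine standards: three at 1e3, two each at 1e4..1e6
DEFAULT_SPIKEIN_PANEL = (1e3, 1e3, 1e3, 1e4, 1e4, 1e5, 1e5, 1e6, 1e6)

#: printed environmental ranges used as simulation defaults
DEFAULT_ENV_RANGES = {
    "temperature": (28.55, 29.68),
    "salinity": (33.66, 35.12),
    "nox": (0.014, 0.104),
    "drp": (0.01, 0.15),
    "silicate": (0.57, 1.93),
    "chla": (5.4, 48.8),
    "bacterial_abundance": (1.15e5, 1.68e5),
}

_PHYLA = (
    ("Proteobacteria", 0.50, ("SAR11 clade", "SAR86 clade", "Alteromonadales")),
    ("Cyanobacteria", 0.22, ("Synechococcales",)),
    ("Bacteroidetes", 0.10, ("Flavobacteriales", "Chitinophagales")),
    ("Actinobacteria", 0.08, ("Actinomycetales",)),
    ("Planctomycetes", 0.05, ("Pirellulales", "Planctomycetales")),
    ("Verrucomicrobia", 0.05, ("Verrucomicrobiales", "Opitutales")),
)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_samples: int = 20
    n_otus: int = 1200
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.7
    total_copies_per_L: float = 7.09e8
    spikein_panel: tuple = DEFAULT_SPIKEIN_PANEL
    depth: int = 100_000
    noise_cv: float = 0.0
    spatial_decay: float = 1.0
    sample_noise_sd: float = 0.3
    env_ranges: dict = field(default_factory=lambda: dict(DEFAULT_ENV_RANGES))
    #: range of the sequenced-aliquot scale V*R (liters of seawater whose
    #: template copies compete with the spike-ins); R is derived as
    #: pool_scale / V, keeping every sample's spike-in reads in a fittable
    #: range regardless of the volume draw
    pool_scale_range: tuple = (2.6e-3, 3.4e-3)
    v_range: tuple = (4.25, 7.3)
    lon_range: tuple = (158.77, 233.79)  # eastward across the antimeridian
    lat_range: tuple = (9.31, 28.96)
    n_archaea: int = 4
    n_chloroplast: int = 4
    contaminant_fraction: float = 0.01
    unassigned_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_otus < 1:
            raise SimulationError("n_samples and n_otus must be positive")
        if self.depth <= 0:
            raise SimulationError("sequencing depth must be > 0")
        for name in ("lognormal_sigma", "total_copies_per_L"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if self.noise_cv < 0 or self.spatial_decay < 0:
            raise SimulationError("noise_cv and spatial_decay must be >= 0")
        if any(c <= 0 for c in self.spikein_panel) or len(set(self.spikein_panel)) < 2:
            raise SimulationError("spike-in panel needs positive copies at >= 2 levels")


@dataclass
class TrueCommunity:
    true_abundance: pd.DataFrame  # samples x OTUs, copies / L
    efficiency: pd.Series  # per-OTU amplification factor, mean 1
    tree: skbio.TreeNode


def generate_tree(otu_ids, seed: int) -> skbio.TreeNode:
    """Random coalescent-style rooted binary tree over ``otu_ids``.

    Deterministic given the seed; every branch length is positive.
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise SimulationError("need >= 2 OTUs to build a tree")
    rng = np.random.default_rng(seed)
    lineages = [skbio.TreeNode(name=o) for o in otu_ids]
    k = len(lineages)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        for child in (left, right):
            child.length = float(rng.exponential(1.0 / k) + 0.01)
        parent = skbio.TreeNode(children=[left, right])
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return root


def _smooth_env(rng, positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth function of transect position plus noise, clipped into [lo, hi]."""
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0.0, 1.0)
    trend_w = rng.uniform(-0.3, 0.3)
    u = 0.5 + 0.35 * np.sin(2 * np.pi * (freq * positions + phase)) + trend_w * positions
    u = u + rng.normal(0.0, 0.05, size=len(positions))
    u = np.clip(u, 0.0, 1.0)
    return lo + (hi - lo) * u


def generate_community(cfg: SimConfig) -> tuple[TrueCommunity, SampleMetadata]:
    """Draw true copies/L per (sample, OTU) plus matching metadata.

    Composition drifts along the transect at rate ``spatial_decay``; with
    decay 0 the expected composition is position-independent.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_otus
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    otu_ids = [f"OTU{i + 1:04d}" for i in range(m)]

    s = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    base = rng.normal(cfg.lognormal_mu, cfg.lognormal_sigma, size=m)
    gradient = rng.normal(0.0, 1.0, size=m)
    eps = rng.normal(0.0, cfg.sample_noise_sd, size=(n, m))
    log_abund = base[None, :] + cfg.spatial_decay * np.outer(s, gradient) + eps
    abund = np.exp(log_abund)
    abund *= cfg.total_copies_per_L / abund.sum(axis=1, keepdims=True)
    true = pd.DataFrame(abund, index=sample_ids, columns=otu_ids)

    if cfg.noise_cv > 0:
        sigma2 = np.log1p(cfg.noise_cv**2)
        eff = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=m)
    else:
        eff = np.ones(m)
    efficiency = pd.Series(eff, index=otu_ids, name="efficiency")

    lon = np.linspace(*cfg.lon_range, n) if n > 1 else np.array([cfg.lon_range[0]])
    lon = ((lon + 180.0) % 360.0) - 180.0
    lat = np.linspace(*cfg.lat_range, n) if n > 1 else np.array([cfg.lat_range[0]])
    meta = {
        var: _smooth_env(rng, s, lo, hi) for var, (lo, hi) in cfg.env_ranges.items()
    }
    meta["longitude"] = lon
    meta["latitude"] = lat
    volume = rng.uniform(*cfg.v_range, size=n)
    pool_scale = rng.uniform(*cfg.pool_scale_range, size=n)
    meta["recovery_ratio"] = np.minimum(pool_scale / volume, 1.0)
    meta["volume"] = volume
    # stations are not perfectly aligned; keeps lon/lat non-collinear
    meta["latitude"] = np.clip(lat + rng.normal(0.0, 0.2, size=n), -90.0, 90.0)
    metadata = SampleMetadata(pd.DataFrame(meta, index=sample_ids))

    tree = generate_tree(otu_ids, seed=cfg.seed + 1)
    return TrueCommunity(true_abundance=true, efficiency=efficiency, tree=tree), metadata


def _assign_lineages(rng, otu_ids, unassigned_fraction: float) -> pd.DataFrame:
    names, weights = zip(*[(p[0], p[1]) for p in _PHYLA])
    probs = np.array(weights) / sum(weights)
    rows = {}
    for o in otu_ids:
        if rng.random() < unassigned_fraction:
            rows[o] = {"lineage": "Unassigned", "category": "unassigned"}
            continue
        idx = rng.choice(len(names), p=probs)
        phylum, _, orders = _PHYLA[idx]
        order = orders[rng.integers(len(orders))]
        rows[o] = {
            "lineage": f"Bacteria;{phylum};{phylum}_class;{order}",
            "category": "bacteria",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_sequencing(
    community: TrueCommunity, metadata: SampleMetadata, cfg: SimConfig
) -> tuple[CountTable, TaxonomyTable, SpikeInDesign]:
    """Multinomial sequencing of spike-ins plus biological templates.

    Per sample the pool is {spike s: added copies} union
    {OTU i: true_ij * V_j * R_j * efficiency_i}; read counts are one
    multinomial draw of ``cfg.depth`` over the pool.  A small
    archaea/chloroplast contaminant block is injected so the cleaning
    stage has work to do.
    """
    if cfg.depth <= 0:
        raise SimulationError("sequencing depth must be > 0")
    rng = np.random.default_rng(cfg.seed + 2)
    true = community.true_abundance
    sample_ids = list(true.index)
    otu_ids = list(true.columns)
    spike_ids = [f"SPIKE{i + 1}" for i in range(len(cfg.spikein_panel))]
    design = SpikeInDesign(
        pd.Series(list(cfg.spikein_panel), index=spike_ids, dtype=float)
    )

    n_cont = cfg.n_archaea + cfg.n_chloroplast
    cont_ids = [f"ARCH{i + 1:02d}" for i in range(cfg.n_archaea)] + [
        f"CHLORO{i + 1:02d}" for i in range(cfg.n_chloroplast)
    ]
    cont_rel = (
        rng.dirichlet(np.ones(n_cont), size=len(sample_ids))
        * cfg.contaminant_fraction
        if n_cont
        else np.zeros((len(sample_ids), 0))
    )

    rv = (
        metadata.data.loc[sample_ids, "recovery_ratio"].to_numpy()
        * metadata.data.loc[sample_ids, "volume"].to_numpy()
    )
    bio_pool = true.to_numpy() * rv[:, None] * community.efficiency.to_numpy()[None, :]
    cont_pool = cont_rel * bio_pool.sum(axis=1, keepdims=True)
    spike_pool = np.tile(np.asarray(cfg.spikein_panel, dtype=float), (len(sample_ids), 1))
    pool = np.hstack([spike_pool, bio_pool, cont_pool])
    probs = pool / pool.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(cfg.depth, probs[i]) for i in range(len(sample_ids))]
    )
    all_ids = spike_ids + otu_ids + cont_ids
    table = CountTable(pd.DataFrame(counts, index=sample_ids, columns=all_ids))

    tax = _assign_lineages(rng, otu_ids, cfg.unassigned_fraction)
    spike_tax = pd.DataFrame(
        {"lineage": "Synthetic;spike_in", "category": "spike_in"}, index=spike_ids
    )
    cont_tax = pd.DataFrame.from_dict(
        {
            o: {
                "lineage": "Archaea;Euryarchaeota"
                if o.startswith("ARCH")
                else "Bacteria;Cyanobacteria;Oxyphotobacteria;Chloroplast",
                "category": "archaea" if o.startswith("ARCH") else "chloroplast",
            }
            for o in cont_ids
        },
        orient="index",
    ) if cont_ids else pd.DataFrame(columns=["lineage", "category"])
    taxonomy = TaxonomyTable(pd.concat([spike_tax, tax, cont_tax]))
    return table, taxonomy, design


def simulate_experiment(cfg: SimConfig):
    """Full simulation: community + metadata + sequenced tables."""
    community, metadata = generate_community(cfg)
    counts, taxonomy, design = simulate_sequencing(community, metadata, cfg)
    return community, metadata, counts, taxonomy, design


def write_simulation(out_dir, cfg: SimConfig, run_config: RunConfig | None = None):
    """Run the simulation and write the standard file set to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    community, metadata, counts, taxonomy, design = simulate_experiment(cfg)
    write_count_table(counts, out / "counts.tsv", run_config)
    write_taxonomy(taxonomy, out / "taxonomy.tsv", run_config)
    write_spikein_design(design, out / "design.tsv", run_config)
    write_sample_metadata(metadata, out / "metadata.tsv", run_config)
    write_tree(community.tree, out / "tree.nwk")
    truth = community.true_abundance.T
    truth.index.name = "otu_id"
    write_result_table(truth, out / "truth.tsv", run_config)
    return community, metadata, counts, taxonomy, design
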