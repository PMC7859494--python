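"""Spike-in calibration and absolute abundance estimation.

Per sample, the standard curve regresses log10(spike-in reads) on
log10(added copies) by ordinary least squares (``y = a*x + b``).  The
curve is then inverted to map a biological OTU's read count to its copy
number in the sequenced pool, which is scaled to copies per liter of
seawater by the DNA recovery ratio ``R`` and filtered volume ``V``::

    Y_otu  = 10 ** ((log10(reads) - b) / a)      (reads > 0, else 0)
    AB_otu = Y_otu / (R * V)                      [copies / L]

Division by ``R`` scales the sequenced aliquot back up to the whole
extract; division by ``V`` converts to a per-liter concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, SampleMetadata, SpikeInDesign, TaxonomyTable


class CalibrationError(ValueError):
    """Raised when a per-sample standard curve cannot be fit."""


@dataclass
class StandardCurve:
    sample_id: object
    a: float  # slope of the log10-log10 fit
    b: float  # intercept, log10 reads
    r_squared: float
    n_points: int
    excluded_spikeins: tuple = ()

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise CalibrationError(
                f"sample {self.sample_id!r}: only {self.n_points} spike-ins with "
                "reads > 0; need >= 3"
            )
        if not np.isfinite(self.a):
            raise CalibrationError(f"sample {self.sample_id!r}: non-finite slope")


@dataclass
class QuantTable:
    """Absolute abundances (copies per liter), samples x OTUs."""

    data: pd.DataFrame  # copies / L
    y_otu: pd.DataFrame | None = None  # copies in sequenced pool, optional

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("copies_per_L must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class RelativeTable:
    """Per-sample proportions, samples x OTUs."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.data.to_numpy()
        if (arr < 0).any():
            raise ValueError("proportions must be non-negative")
        sums = arr.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not ok.all():
            raise ValueError("sample proportions must sum to 1 (or 0 for empty rows)")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)


def split_spikeins(
    counts: CountTable, taxonomy: TaxonomyTable, design: SpikeInDesign | None = None
) -> tuple[pd.DataFrame, CountTable]:
    """Partition columns into spike-in and biological blocks.

    Returns the spike-in block as a plain DataFrame (it may legitimately be
    empty) and the biological block as a CountTable.  Spike-ins listed in
    the design but absent from the table are recorded with 0 reads.
    """
    spike_ids = [o for o in counts.otu_ids if taxonomy.category_of(o) == "spike_in"]
    bio_ids = [o for o in counts.otu_ids if o not in set(spike_ids)]
    spike = counts.data[spike_ids].copy()
    if not spike_ids:
        warnings.warn("no spike-in OTUs found in count table", stacklevel=2)
    if design is not None:
        for sid in design.spikein_ids:
            if sid not in spike.columns:
                warnings.warn(
                    f"spike-in {sid!r} in design but absent from count table; "
                    "recorded as 0 reads",
                    stacklevel=2,
                )
                spike[sid] = 0
    return spike, CountTable(counts.data[bio_ids].copy())


def clean_biological(counts: CountTable, taxonomy: TaxonomyTable) -> CountTable:
    """Drop spike-in/archaea/chloroplast OTUs and global singletons.

    A singleton is an OTU whose total read count across *all* samples is 1.
    Unassigned OTUs are retained.
    """
    drop_cats = {"spike_in", "archaea", "chloroplast"}
    keep = [
        o for o in counts.otu_ids if taxonomy.category_of(o) not in drop_cats
    ]
    df = counts.data[keep]
    totals = df.sum(axis=0)
    df = df.loc[:, totals > 1]
    if df.shape[1] == 0:
        raise ValueError("no bacterial OTUs remain after cleaning")
    return CountTable(df.copy())


def fit_standard_curve(
    spike_reads: pd.Series, design: SpikeInDesign, sample_id=None
) -> StandardCurve:
    """OLS fit of log10(reads) on log10(added copies) for one sample.

    Spike-ins with zero reads are excluded from the fit and reported in
    ``excluded_spikeins``.
    """
    common = [s for s in design.spikein_ids if s in spike_reads.index]
    if not common:
        raise CalibrationError(f"sample {sample_id!r}: no spike-in reads available")
    reads = spike_reads[common].astype(float)
    positive = reads[reads > 0]
    excluded = tuple(reads.index[reads <= 0])
    if len(positive) < 3:
        raise CalibrationError(
            f"sample {sample_id!r}: only {len(positive)} spike-ins with reads > 0"
        )
    x = np.log10(design.added_copies[positive.index].to_numpy())
    y = np.log10(positive.to_numpy())
    if np.allclose(x, x[0]):
        raise CalibrationError(
            f"sample {sample_id!r}: zero variance in spike-in concentrations"
        )
    res = stats.linregress(x, y)
    return StandardCurve(
        sample_id=sample_id,
        a=float(res.slope),
        b=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(positive),
        excluded_spikeins=excluded,
    )


def fit_standard_curves(
    spike_counts: pd.DataFrame, design: SpikeInDesign
) -> dict[object, StandardCurve]:
    """Fit one standard curve per sample (rows of ``spike_counts``)."""
    return {
        sid: fit_standard_curve(spike_counts.loc[sid], design, sample_id=sid)
        for sid in spike_counts.index
    }


def curves_frame(curves: dict[object, StandardCurve]) -> pd.DataFrame:
    rows = {
        sid: {
            "a": c.a,
            "b": c.b,
            "r_squared": c.r_squared,
            "n_points": c.n_points,
            "excluded": ",".join(map(str, c.excluded_spikeins)),
        }
        for sid, c in curves.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def estimate_absolute_abundance(
    biological_counts: CountTable,
    curves: dict[object, StandardCurve],
    metadata: SampleMetadata,
) -> QuantTable:
    """Invert each sample's standard curve and scale by R and V."""
    counts = biological_counts.data
    y = np.zeros(counts.shape, dtype=float)
    ab = np.zeros(counts.shape, dtype=float)
    for i, sid in enumerate(counts.index):
        if sid not in curves:
            raise CalibrationError(f"no standard curve for sample {sid!r}")
        curve = curves[sid]
        if curve.a <= 0:
            raise CalibrationError(
                f"sample {sid!r}: non-monotone curve (a={curve.a:.4g} <= 0)"
            )
        if sid not in metadata.data.index:
            raise ValueError(f"sample {sid!r} missing from metadata (R, V required)")
        r = metadata.data.at[sid, "recovery_ratio"]
        v = metadata.data.at[sid, "volume"]
        row = counts.iloc[i].to_numpy(dtype=float)
        pos = row > 0
        y[i, pos] = 10.0 ** ((np.log10(row[pos]) - curve.b) / curve.a)
        ab[i] = y[i] / (r * v)
    return QuantTable(
        data=pd.DataFrame(ab, index=counts.index, columns=counts.columns),
        y_otu=pd.DataFrame(y, index=counts.index, columns=counts.columns),
    )


def rarefy(counts: CountTable, depth: int | str, seed: int) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth="min"`` resolves to the minimum sample total.  Deterministic
    given ``seed``.
    """
    totals = counts.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"samples below rarefaction depth {depth}: {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty(counts.data.shape, dtype=np.int64)
    for i in range(counts.data.shape[0]):
        row = counts.data.iloc[i].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(
        pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns)
    )


def to_relative(counts: CountTable) -> RelativeTable:
    totals = counts.sample_totals().to_numpy(dtype=float)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"all-zero samples kept as zero rows: {list(counts.data.index[empty])}",
            stacklevel=2,
        )
    safe = np.where(empty, 1.0, totals)
    props = counts.data.to_numpy(dtype=float) / safe[:, None]
    props[empty] = 0.0
    return RelativeTable(
        pd.DataFrame(props, index=counts.data.index, columns=counts.data.columns)
    )


def summarize_totals(quant: QuantTable) -> tuple[pd.Series, dict]:
    """Per-sample total copies per liter plus cohort min/mean/max."""
    totals = quant.data.sum(axis=1)
    summary = {
        "min": float(totals.min()),
        "mean": float(totals.mean()),
        "max": float(totals.max()),
    }
    return totals, summary
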