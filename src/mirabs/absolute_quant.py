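"""Spike-in anchored absolute quantification of small RNA counts.

The central conversion:

    molecules per 10 pg total RNA =
        miRNA_reads x spikein_added(mol) x 6.022e23 x 10
        / (spikein_reads x total_RNA_added(pg))

where ``spikein_added`` is the molar amount of the synthetic pool added to
the sample before library preparation and ``spikein_reads`` the deduplicated
reads matching it.  Since every library molecule, endogenous or synthetic,
passes through the same ligation and amplification, the spike-in read yield
calibrates reads per molecule; scaling by 10/total_RNA_added expresses the
result per 10 pg of total RNA, approximately one cell's worth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

AVOGADRO = 6.022e23


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample quantification metadata."""

    sample_id: str
    total_rna_pg: float
    spikein_added_mol: float
    tissue: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.total_rna_pg <= 0:
            raise ValueError("total_rna_pg must be positive")
        if self.spikein_added_mol <= 0:
            raise ValueError("spikein_added_mol must be positive")


@dataclass
class BiasReport:
    """Observed/expected read-count ratios for an equimolar spike-in pool."""

    ratios: pd.Series  # per-oligo ratio (mean across replicates when several)
    median: float
    q1: float
    q3: float
    relative_sd: pd.Series | None  # per-oligo SD/mean across replicate libraries
    n_replicates: int


def molecules_per_10pg(
    mirna_reads: float,
    spikein_added_mol: float,
    spikein_reads: float,
    total_rna_pg: float,
) -> float:
    """Absolute abundance of one feature, molecules per 10 pg total RNA."""
    if spikein_reads <= 0:
        raise ValueError("spikein_reads must be positive (no normalization anchor)")
    if total_rna_pg <= 0 or spikein_added_mol <= 0:
        raise ValueError("total_rna_pg and spikein_added_mol must be positive")
    return mirna_reads * spikein_added_mol * AVOGADRO * 10.0 / (spikein_reads * total_rna_pg)


def quantify_sample(
    isomir_counts: pd.DataFrame,
    spikein_counts: pd.DataFrame,
    meta: SampleMeta,
    pool=None,
    spike_mode: str = "pooled",
) -> tuple[pd.DataFrame, float]:
    """Convert per-isomiR counts into absolute abundances for one sample.

    ``spike_mode="pooled"`` (default) anchors on the ratio of sums: total
    pool moles over total spike reads, which is robust to single-oligo
    dropout.  ``spike_mode="per_oligo"`` instead averages each oligo's own
    moles/reads scale (oligos with zero reads are excluded); it requires
    ``pool`` (a list of SpikeInOligo) for per-oligo molar amounts.

    Returns (records, total): one AbundanceRecord row per isomiR plus the
    sample total miRNA abundance (sum over all isomiRs).
    """
    total_spike_reads = float(spikein_counts["count"].sum())
    if total_spike_reads <= 0:
        raise ValueError("no spike-in reads: cannot anchor absolute quantification")
    if spike_mode == "pooled":
        scale = meta.spikein_added_mol / total_spike_reads
    elif spike_mode == "per_oligo":
        if pool is None:
            raise ValueError("per_oligo mode requires the spike-in pool")
        moles = {o.oligo_id: o.moles_added for o in pool}
        per = [
            moles[row.oligo_id] * len(pool) / row.count
            for row in spikein_counts.itertuples()
            if row.count > 0
        ]
        scale = float(np.mean(per)) / len(pool) if per else None
        if scale is None:
            raise ValueError("no spike-in oligo has reads")
    else:
        raise ValueError(f"unknown spike_mode {spike_mode!r}")

    per_read = scale * AVOGADRO * 10.0 / meta.total_rna_pg
    records = isomir_counts.copy()
    if records.empty:
        records = pd.DataFrame(columns=list(isomir_counts.columns) + ["molecules_per_10pg", "sample_id"])
        return records, 0.0
    records["molecules_per_10pg"] = records["count"].astype(float) * per_read
    records["sample_id"] = meta.sample_id
    return records, float(records["molecules_per_10pg"].sum())


def aggregate_replicates(
    records: pd.DataFrame,
    feature_col: str = "feature",
    value_col: str = "molecules_per_10pg",
) -> pd.DataFrame:
    """Per-feature mean, sample SD (n-1 denominator), and replicate count.

    SD is reported as NaN when n = 1, matching mean +- SD reporting with
    small n.
    """
    g = records.groupby(feature_col)[value_col]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})
    return out.reset_index()


def observed_expected_ratios(counts: pd.DataFrame | pd.Series) -> BiasReport:
    """Observed-to-expected read ratios for an equimolar pool.

    ``counts`` is a per-oligo Series (one library) or an oligo x replicate
    DataFrame.  Expected reads per oligo in each library are total/n (the
    pool is equimolar), so the per-library mean ratio is exactly 1; the
    spread of ratios measures ligation bias.  Median and IQR use
    linear-interpolation quantiles.  With >= 2 replicate libraries the
    per-oligo relative SD of the ratio across replicates is also reported.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_frame("rep1")
    if len(counts.index) < 2:
        raise ValueError("need >= 2 oligos for a bias report")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("each library must have a positive total count")
    expected = totals / len(counts.index)
    ratio_matrix = counts / expected
    ratios = ratio_matrix.mean(axis=1)
    q1, med, q3 = np.quantile(ratios.to_numpy(), [0.25, 0.5, 0.75])
    rel_sd = None
    if counts.shape[1] >= 2:
        rel_sd = ratio_matrix.std(axis=1, ddof=1) / ratio_matrix.mean(axis=1)
    return BiasReport(
        ratios=ratios,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        relative_sd=rel_sd,
        n_replicates=counts.shape[1],
    )


def sphere_volume_um3(diameter_um: float) -> float:
    """Volume of a sphere from its diameter, in cubic micrometers."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi / 6.0 * diameter_um**3


def copies_to_molar(molecules_per_cell: float, cell_volume_um3: float) -> float:
    """Convert molecules per cell to an intracellular concentration in nM.

    1 um^3 = 1e-15 L, so concentration = molecules / (N_A x V[L]), reported
    in nanomolar.  Example: ~1000 molecules in a ~1150 um^3 cell is ~1.4 nM.
    """
    if cell_volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    if molecules_per_cell < 0:
        raise ValueError("molecule count must be >= 0")
    volume_l = cell_volume_um3 * 1e-15
    return molecules_per_cell / (AVOGADRO * volume_l) * 1e9
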