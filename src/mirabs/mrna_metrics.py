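"""mRNA-side metrics: rRNA adjustment, mean mRNA length, absolute mRNA copies.

Total-RNA sequencing without rRNA depletion under-counts rRNA reads near
modified nucleotides; the rRNA adjustment coefficient (mean coverage divided
by maximum coverage, positions pooled across all rRNA genes) quantifies that
bias so raw rRNA counts can be inflated before computing the mRNA read
fraction.  Absolute mRNA copies come from ERCC-style mRNA spike-ins (the
preferred route) or from a mass-fraction calculation; dividing the total
miRNA abundance by the mRNA abundance on the same 10 pg basis gives the
miRNA-to-mRNA molar ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mirabs.absolute_quant import AVOGADRO

#: Average mass of one RNA nucleotide residue in a polymer, g/mol.  Used only
#: by the mass-fraction route; configurable because the effective value
#: depends on base composition and counterions.
RNA_RESIDUE_MASS_G_PER_MOL = 340.0


@dataclass
class MrnaAbundanceSummary:
    """Summary of the mRNA side of one sample."""

    mrna_reads: float
    rrna_reads_raw: float
    rrna_reads_adjusted: float
    mean_mrna_length: float
    mrna_molecules_per_10pg: float


def rrna_adjustment_coefficient(tracks: list[np.ndarray] | dict[str, np.ndarray]) -> float:
    """Mean coverage divided by maximum coverage, pooled over all rRNA genes.

    Coverage dips near modified nucleotides pull the mean below the maximum,
    so the coefficient is in (0, 1]; dividing observed rRNA read counts by it
    corrects for the sequencing bias against rRNA.
    """
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    if not tracks:
        raise ValueError("need at least one coverage track")
    pooled = np.concatenate([np.asarray(t, dtype=float) for t in tracks])
    if (pooled < 0).any():
        raise ValueError("coverage must be non-negative")
    peak = pooled.max()
    if peak <= 0:
        raise ValueError("all-zero coverage: coefficient undefined")
    # pairwise-summation rounding in mean() can land 1 ulp above peak for
    # constant tracks; the coefficient is defined on (0, 1]
    return min(1.0, float(pooled.mean() / peak))


def mean_mrna_length(lengths, fpkms) -> float:
    """FPKM-weighted arithmetic mean of transcript lengths (nt).

    FPKM weighting makes the mean reflect the molar composition of the mRNA
    pool rather than the annotation.
    """
    lengths = np.asarray(lengths, dtype=float)
    fpkms = np.asarray(fpkms, dtype=float)
    if lengths.shape != fpkms.shape:
        raise ValueError("lengths and fpkms must have the same shape")
    if (lengths < 1).any():
        raise ValueError("transcript lengths must be >= 1 nt")
    if (fpkms < 0).any():
        raise ValueError("FPKM values must be >= 0")
    total = fpkms.sum()
    if total <= 0:
        raise ValueError("sum of FPKM must be positive")
    return float((lengths * fpkms).sum() / total)


def mrna_molecules_from_spikein(
    transcript_reads,
    transcript_lengths,
    spike_reads,
    spike_lengths,
    spike_total_moles: float,
    total_rna_pg: float,
) -> np.ndarray | float:
    """Absolute mRNA copies per 10 pg, anchored on mRNA spike-ins.

    Long transcripts yield proportionally more fragments, so reads are
    length-normalized to densities (reads per kb) before pooling the spikes:

        molecules_t = density_t x spike_moles x N_A x 10
                      / (sum_s density_s x total_rna_pg)

    Scalar inputs give a scalar result; arrays are broadcast per transcript.
    """
    t_reads = np.asarray(transcript_reads, dtype=float)
    t_len = np.asarray(transcript_lengths, dtype=float)
    s_reads = np.asarray(spike_reads, dtype=float)
    s_len = np.asarray(spike_lengths, dtype=float)
    if spike_total_moles <= 0 or total_rna_pg <= 0:
        raise ValueError("spike_total_moles and total_rna_pg must be positive")
    if s_reads.sum() <= 0:
        raise ValueError("no spike-in reads: cannot anchor mRNA quantification")
    density_t = t_reads / (t_len / 1000.0)
    density_s_total = (s_reads / (s_len / 1000.0)).sum()
    out = density_t * spike_total_moles * AVOGADRO * 10.0 / (density_s_total * total_rna_pg)
    return float(out) if np.isscalar(transcript_reads) else out


def mrna_molecules_mass_fraction(
    mrna_reads: float,
    rrna_reads_raw: float,
    rrna_coefficient: float,
    mean_length_nt: float,
    other_reads: float = 0.0,
    residue_mass: float = RNA_RESIDUE_MASS_G_PER_MOL,
) -> float:
    """Absolute mRNA copies per 10 pg from the mRNA mass fraction.

    Raw rRNA reads are divided by the adjustment coefficient (inflating them,
    since the coefficient quantifies bias against rRNA reads) before
    computing the mRNA read fraction; the fraction of the 10 pg mass
    attributed to mRNA is then converted to molecules through the mean mRNA
    length and the per-nucleotide residue mass.
    """
    if not 0 < rrna_coefficient <= 1:
        raise ValueError("rRNA adjustment coefficient must be in (0, 1]")
    if mean_length_nt <= 0:
        raise ValueError("mean mRNA length must be positive")
    rrna_adjusted = rrna_reads_raw / rrna_coefficient
    denom = mrna_reads + rrna_adjusted + other_reads
    if denom <= 0:
        raise ValueError("no reads to compute the mRNA fraction from")
    fraction = mrna_reads / denom
    mass_g = fraction * 10.0e-12  # mRNA mass within the 10 pg basis
    return mass_g / (mean_length_nt * residue_mass) * AVOGADRO


def mirna_to_mrna_ratio(mirna_total_per_10pg: float, mrna_molecules_per_10pg: float) -> float:
    """Molar ratio of total miRNA to mRNA in the same 10 pg basis."""
    if mrna_molecules_per_10pg <= 0:
        raise ValueError("mRNA molecule count must be positive")
    if mirna_total_per_10pg < 0:
        raise ValueError("miRNA total must be >= 0")
    return mirna_total_per_10pg / mrna_molecules_per_10pg


def summarize_sample(
    mrna_reads: float,
    rrna_reads_raw: float,
    tracks,
    transcripts: pd.DataFrame,
    mrna_molecules_per_10pg: float,
) -> MrnaAbundanceSummary:
    """Bundle the mRNA metrics for one sample into a summary record."""
    coeff = rrna_adjustment_coefficient(tracks)
    return MrnaAbundanceSummary(
        mrna_reads=mrna_reads,
        rrna_reads_raw=rrna_reads_raw,
        rrna_reads_adjusted=rrna_reads_raw / coeff,
        mean_mrna_length=mean_mrna_length(transcripts["length"], transcripts["fpkm"]),
        mrna_molecules_per_10pg=mrna_molecules_per_10pg,
    )
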