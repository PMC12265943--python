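"""Ground-truth simulators for every input the quantification pipeline consumes.

The generators emit miRNA hairpin references with mature annotations,
equimolar spike-in pools, FASTQ small RNA libraries with split UMIs in both
adapters, per-sequence ligation bias, PCR duplicates, 5' isomiRs and single
non-templated 3' additions, logistic reporter-repression datasets, and
miRNA-by-tissue abundance matrices with planted tissue-specific patterns.
Every generator is deterministic for a fixed seed, and every library comes
with the true molecule counts it was sampled from, so downstream recovery can
be tested against known truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA = "ACGT"

# Adapter / UMI architecture: both adapters carry nine random nucleotides
# split into three NNN blocks interleaved with fixed 3-nt anchors.  Two 5'
# adapter variants (equimolar in the ligation) increase 5'-end nucleotide
# diversity; the 3' adapter has a single layout followed by the constant
# sequence targeted by trimming.
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
UMI5_PATTERNS = ("NNNCGANNNTACNNN", "NNNATCNNNAGTNNN")
UMI3_PATTERN = "NNNGTCNNNTAGNNN"


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA interval on its hairpin (0-based, half-open)."""

    name: str
    start: int
    end: int
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid mature interval {self.start}..{self.end}")
        if not 18 <= self.end - self.start <= 26:
            raise ValueError(f"mature length {self.end - self.start} outside 18-26 nt")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")


@dataclass(frozen=True)
class Hairpin:
    """A miRNA hairpin locus with 1-2 mature annotations."""

    hairpin_id: str
    sequence: str
    matures: tuple[MatureAnnotation, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.matures) <= 2:
            raise ValueError("hairpin must carry 1-2 mature annotations")
        names = [m.name for m in self.matures]
        if len(set(names)) != len(names):
            raise ValueError("mature names must be unique within a hairpin")
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ValueError(f"mature {m.name} extends past hairpin end")


@dataclass(frozen=True)
class SpikeInOligo:
    """A synthetic small RNA of known molar amount added to a library."""

    oligo_id: str
    sequence: str
    moles_added: float

    def __post_init__(self) -> None:
        if self.moles_added <= 0:
            raise ValueError("moles_added must be positive")


@dataclass(frozen=True)
class ReadStructure:
    """Layout of a sequencing read: 5'-UMI block + insert + 3'-UMI block + adapter."""

    umi5_patterns: tuple[str, ...] = UMI5_PATTERNS
    umi3_pattern: str = UMI3_PATTERN
    adapter3: str = ADAPTER3
    read_length: int = 79

    def __post_init__(self) -> None:
        for pat in (*self.umi5_patterns, self.umi3_pattern):
            if pat.count("N") != 9:
                raise ValueError(f"UMI pattern {pat} must contribute exactly 9 random nt")


DEFAULT_READ_STRUCTURE = ReadStructure()

# Default 5' isomiR offset distribution around the annotated mature start.
# Drosha/Dicer heterogeneity concentrates at the annotated position with rare
# +-1/+-2 shifts; the empirical distribution is not fixed by any reference
# value, so this default is configurable.
DEFAULT_ISOMIR_OFFSETS = {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}


@dataclass
class LibraryTruth:
    """Ground truth driving one simulated small RNA library.

    ``molecules`` maps feature names (mature miRNA names and spike-in oligo
    ids) to true molecule counts; ``ligation_efficiency`` maps features to a
    sequence-dependent adapter-ligation efficiency in (0, 1] (default 1.0),
    the mechanism behind read-count distortion in real libraries.
    """

    molecules: dict[str, float]
    ligation_efficiency: dict[str, float] = field(default_factory=dict)
    duplication_rate: float = 0.0
    nta_rate: float = 0.0
    isomir_offsets: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ISOMIR_OFFSETS))
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.molecules:
            raise ValueError("truth must cover at least one feature")
        for f, e in self.ligation_efficiency.items():
            if not 0 < e <= 1:
                raise ValueError(f"ligation efficiency for {f} outside (0, 1]")
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        if not 0 <= self.nta_rate <= 1:
            raise ValueError("nta_rate must be in [0, 1]")
        total = sum(self.isomir_offsets.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isomiR offset probabilities must sum to 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class SimulatedLibrary:
    """A simulated FASTQ library plus the bookkeeping tests need."""

    reads: list[tuple[str, str]]  # (read id, sequence)
    emitted_molecules: dict[str, int]  # reads drawn per feature, pre-duplication
    n_duplicates: int
    truth: LibraryTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def generate_hairpin_reference(
    n_hairpins: int,
    seed: int,
    out_dir: str | None = None,
) -> list[Hairpin]:
    """Generate ``n_hairpins`` random hairpins, each with 1-2 mature annotations.

    Mature intervals are 20-23 nt, non-overlapping, and end at least 2 nt
    before the hairpin 3' terminus so that a templated nucleotide always
    exists downstream of a mature (needed to define non-templated additions).
    When ``out_dir`` is given, writes ``hairpins.fa`` and ``matures.tsv``
    (0-based half-open coordinates).
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = np.random.default_rng(seed)
    hairpins: list[Hairpin] = []
    for i in range(n_hairpins):
        hid = f"mir-{i + 1:03d}"
        length = int(rng.integers(60, 121))
        seq = _random_seq(rng, length)
        arms = ["5p", "3p"] if rng.random() < 0.6 else [rng.choice(["5p", "3p"])]
        matures = []
        for arm in arms:
            mlen = int(rng.integers(20, 24))
            if arm == "5p":
                start = int(rng.integers(2, 9))
            else:
                end = length - 2 - int(rng.integers(0, 4))
                start = end - mlen
            end = start + mlen
            if matures and start < matures[-1].end + 4:
                continue  # skip a 3p that would collide with the 5p
            matures.append(MatureAnnotation(f"{hid}-{arm}", start, end, arm))
        hairpins.append(Hairpin(hid, seq, tuple(matures)))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_hairpin_fasta(hairpins, os.path.join(out_dir, "hairpins.fa"))
        write_mature_annotations(hairpins, os.path.join(out_dir, "matures.tsv"))
    return hairpins


def write_hairpin_fasta(hairpins: list[Hairpin], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(h.sequence), id=h.hairpin_id, description="") for h in hairpins]
    SeqIO.write(records, path, "fasta")


def write_mature_annotations(hairpins: list[Hairpin], path: str) -> None:
    rows = [
        {"hairpin_id": h.hairpin_id, "name": m.name, "start": m.start, "end": m.end, "arm": m.arm}
        for h in hairpins
        for m in h.matures
    ]
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open [start, end)\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_mature_annotations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def generate_spikein_pool(
    n_oligos: int,
    total_moles: float,
    seed: int,
    reference: list[Hairpin] | None = None,
    max_retries: int = 1000,
) -> list[SpikeInOligo]:
    """Generate an equimolar pool of 20-30 nt synthetic oligos.

    Each oligo receives ``total_moles / n_oligos``.  Sequences are unique and,
    when a hairpin reference is supplied, never a substring of any hairpin
    (the oligos must be distinguishable from genomic small RNAs).
    """
    if n_oligos < 1:
        raise ValueError("n_oligos must be >= 1")
    if total_moles <= 0:
        raise ValueError("total_moles must be positive")
    rng = np.random.default_rng(seed)
    hairpin_seqs = [h.sequence for h in reference] if reference else []
    per_oligo = total_moles / n_oligos
    oligos: list[SpikeInOligo] = []
    seen: set[str] = set()
    for i in range(n_oligos):
        for attempt in range(max_retries + 1):
            seq = _random_seq(rng, int(rng.integers(20, 31)))
            if seq in seen:
                continue
            if any(seq in hp for hp in hairpin_seqs):
                continue
            break
        else:
            raise RuntimeError("could not generate a spike-in distinct from the reference")
        seen.add(seq)
        oligos.append(SpikeInOligo(f"spike-{i + 1:02d}", seq, per_oligo))
    return oligos


def write_spikein_fasta(pool: list[SpikeInOligo], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(o.sequence), id=o.oligo_id, description=f"moles={o.moles_added:g}") for o in pool]
    SeqIO.write(records, path, "fasta")


def _fill_umi_pattern(pattern: str, rng: np.random.Generator) -> tuple[str, str]:
    """Fill the N positions of a UMI pattern; return (block, 9-nt UMI)."""
    block = []
    umi = []
    for c in pattern:
        if c == "N":
            nt = DNA[rng.integers(0, 4)]
            block.append(nt)
            umi.append(nt)
        else:
            block.append(c)
    return "".join(block), "".join(umi)


def simulate_small_rna_library(
    truth: LibraryTruth,
    reference: list[Hairpin],
    pool: list[SpikeInOligo],
    structure: ReadStructure = DEFAULT_READ_STRUCTURE,
    fastq_path: str | None = None,
) -> SimulatedLibrary:
    """Sample a small RNA library from ground truth.

    Each read is ``5'-UMI block + insert + 3'-UMI block + constant adapter``,
    truncated to the read length.  The insert is a mature miRNA shifted by a
    sampled 5' offset (a 5' isomiR), optionally extended by one random
    non-templated 3' nucleotide, or a spike-in oligo (spike inserts are
    emitted verbatim, since downstream matching is exact).  A feature's
    sampling probability is proportional to ``molecules x ligation
    efficiency``, the mechanism of ligation bias.  PCR duplicates replicate
    the complete read, UMIs included.
    """
    matures = {m.name: (h, m) for h in reference for m in h.matures}
    spikes = {o.oligo_id: o for o in pool}
    features = list(truth.molecules)
    for f in features:
        if f not in matures and f not in spikes:
            raise ValueError(f"truth feature {f!r} is neither a mature miRNA nor a spike-in")

    rng = np.random.default_rng(truth.seed)
    weights = np.array(
        [truth.molecules[f] * truth.ligation_efficiency.get(f, 1.0) for f in features],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise ValueError("total sampling weight is zero")
    counts = rng.multinomial(truth.depth, weights / weights.sum())

    offsets = sorted(truth.isomir_offsets)
    offset_p = np.array([truth.isomir_offsets[o] for o in offsets])

    reads: list[tuple[str, str]] = []
    emitted: dict[str, int] = {f: int(c) for f, c in zip(features, counts)}
    n_dup = 0
    serial = 0
    for f, n in zip(features, counts):
        for _ in range(int(n)):
            if f in spikes:
                insert = spikes[f].sequence
            else:
                hairpin, mat = matures[f]
                off = int(offsets[rng.choice(len(offsets), p=offset_p)])
                start = min(max(mat.start + off, 0), mat.end - 14)
                insert = hairpin.sequence[start:mat.end]
                if truth.nta_rate > 0 and rng.random() < truth.nta_rate:
                    templated = hairpin.sequence[mat.end]
                    choices = [c for c in DNA if c != templated]
                    insert += choices[rng.integers(0, 3)]
            umi5_block, _ = _fill_umi_pattern(
                structure.umi5_patterns[rng.integers(0, len(structure.umi5_patterns))], rng
            )
            umi3_block, _ = _fill_umi_pattern(structure.umi3_pattern, rng)
            full = (umi5_block + insert + umi3_block + structure.adapter3)[: structure.read_length]
            serial += 1
            reads.append((f"r{serial:07d}", full))
            if truth.duplication_rate > 0:
                for _ in range(int(rng.poisson(truth.duplication_rate))):
                    serial += 1
                    reads.append((f"r{serial:07d}", full))
                    n_dup += 1

    lib = SimulatedLibrary(reads=reads, emitted_molecules=emitted, n_duplicates=n_dup, truth=truth)
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return lib


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    """Write reads as Phred+33 FASTQ with placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_repression_dataset(
    ic50: float,
    slope: float,
    concentrations: list[float],
    noise_sd: float,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate reporter levels from the logistic repression model.

    Observed level = ``1 / (1 + exp(slope * (ic50 - conc)))`` plus Gaussian
    noise, clipped to [0, 1.5] (levels above the unrepressed control occur in
    noisy normalized data).  Columns: mirna_concentration, level, replicate,
    true_level.
    """
    if slope > 0:
        raise ValueError("slope must be <= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    from mirabs.dose_response import repression_model

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        true = repression_model(conc, ic50, slope)
        obs = np.clip(true + rng.normal(0.0, noise_sd, size=conc.shape), 0.0, 1.5)
        for c, o, t in zip(conc, obs, true):
            rows.append({"mirna_concentration": c, "level": o, "replicate": rep, "true_level": t})
    return pd.DataFrame(rows)


#: 17 mouse tissues profiled at desk scale: eight brain regions plus nine organs
#: (three intestinal segments among them).
MOUSE_TISSUES = (
    "cortex",
    "cerebellum",
    "hippocampus",
    "caudate_putamen",
    "thalamus",
    "hypothalamus",
    "brainstem",
    "olfactory_bulb",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "skeletal_muscle",
    "lung",
    "duodenum",
    "jejunum",
    "ileum",
)

BRAIN_REGIONS = MOUSE_TISSUES[:8]

#: Tissue -> group mapping that collapses the eight brain regions into "brain".
BRAIN_GROUPING = {t: ("brain" if t in BRAIN_REGIONS else t) for t in MOUSE_TISSUES}


def generate_tissue_abundance_matrix(
    n_tissues: int | None,
    n_mirnas: int,
    planted: list[tuple[str, set[str] | list[str], float, float]],
    seed: int,
    background_cap: float = 300.0,
    background_floor: float = 0.1,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Build a miRNA x tissue matrix of molecules per 10 pg with planted patterns.

    Background rows are drawn log-uniform in [background_floor, background_cap],
    emulating the low-abundance bulk of a tissue panel (most miRNAs sit well
    below screening thresholds in every tissue).  Each planted tuple
    ``(mirna, tissue_set, on_level, off_level)`` sets those cells literally:
    ``on_level`` in the listed tissues, ``off_level`` everywhere else.
    """
    if tissues is None:
        tissues = list(MOUSE_TISSUES if n_tissues is None else MOUSE_TISSUES[:n_tissues])
        if n_tissues is not None and n_tissues > len(MOUSE_TISSUES):
            tissues += [f"tissue_{i}" for i in range(len(MOUSE_TISSUES), n_tissues)]
    for _, tset, on, off in planted:
        if on < 0 or off < 0:
            raise ValueError("planted levels must be >= 0")
        unknown = set(tset) - set(tissues)
        if unknown:
            raise ValueError(f"planted tissues not in matrix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log10(background_floor), np.log10(background_cap)
    data = 10 ** rng.uniform(log_lo, log_hi, size=(n_mirnas, len(tissues)))
    index = [f"bg-miR-{i + 1:03d}" for i in range(n_mirnas)]
    mat = pd.DataFrame(data, index=index, columns=tissues)
    for mirna, tset, on, off in planted:
        row = pd.Series(off, index=tissues, dtype=float)
        row[list(tset)] = on
        mat.loc[mirna] = row
    mat.index.name = "mirna"
    return mat
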