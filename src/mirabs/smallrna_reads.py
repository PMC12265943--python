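"""Raw small RNA FASTQ -> deduplicated 5' isomiR and spike-in counts.

The processing contract: strip the constant 3' adapter (tolerating truncated
adapters at the read end), validate the fixed anchors inside both split-UMI
blocks and extract the combined 18-nt UMI, collapse PCR duplicates on exact
(insert, UMI) identity, discard rRNA-matching inserts (<=1 mismatch against a
decoy set, either strand), count exact spike-in matches, and map the
remaining inserts to hairpins in the sense orientation allowing either zero
mismatches or a single mismatch at the insert's final 3' position (a
non-templated addition).  Reads sharing a (hairpin, 5' start) are counted as
one 5' isomiR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from mirabs.synthetic_data import (
    DEFAULT_READ_STRUCTURE,
    Hairpin,
    ReadStructure,
    SpikeInOligo,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_INSERT = 14
MAX_INSERT = 54
MIN_ADAPTER_OVERLAP = 10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProcessedRead:
    """A trimmed read: insert plus the combined 18-nt UMI (9 nt per adapter)."""

    read_id: str
    insert: str
    umi: str


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_adapter | bad_umi | length


@dataclass(frozen=True)
class HairpinAssignment:
    """Sense-strand placement of an insert on a hairpin."""

    hairpin_id: str
    mature_name: str | None
    start5: int
    mismatch: str  # "none" | "terminal3p"


def _umi_from_block(block: str) -> str:
    return block[0:3] + block[6:9] + block[12:15]


def _anchors(pattern: str) -> tuple[str, str]:
    return pattern[3:6], pattern[9:12]


def trim_and_extract(
    read_id: str,
    sequence: str,
    structure: ReadStructure = DEFAULT_READ_STRUCTURE,
) -> ProcessedRead | Rejection:
    """Strip the 3' adapter and both UMI blocks from a raw read.

    The adapter is located as its leftmost full occurrence, or, for reads too
    short to hold it, as the longest adapter prefix (>= 10 nt) terminating
    the read.  The two fixed 3-nt anchors in each UMI block are validated;
    the 5' block must match one of the adapter variants.
    """
    sequence = sequence.upper()
    adapter = structure.adapter3
    pos = sequence.find(adapter)
    if pos < 0:
        for k in range(min(len(adapter) - 1, len(sequence)), MIN_ADAPTER_OVERLAP - 1, -1):
            if sequence.endswith(adapter[:k]):
                pos = len(sequence) - k
                break
        else:
            return Rejection(read_id, "no_adapter")
    trimmed = sequence[:pos]
    if len(trimmed) < 30 + MIN_INSERT:  # two 15-nt UMI blocks + minimal insert
        return Rejection(read_id, "length")
    block5, block3 = trimmed[:15], trimmed[-15:]
    if _anchors(block3) != _anchors(structure.umi3_pattern):
        return Rejection(read_id, "bad_umi")
    if _anchors(block5) not in {_anchors(p) for p in structure.umi5_patterns}:
        return Rejection(read_id, "bad_umi")
    insert = trimmed[15:-15]
    if not MIN_INSERT <= len(insert) <= MAX_INSERT:
        return Rejection(read_id, "length")
    return ProcessedRead(read_id, insert, _umi_from_block(block5) + _umi_from_block(block3))


def deduplicate(reads: list[ProcessedRead]) -> list[ProcessedRead]:
    """One representative per distinct (insert, UMI) pair, sorted lexicographically."""
    best: dict[tuple[str, str], ProcessedRead] = {}
    for r in reads:
        key = (r.insert, r.umi)
        if key not in best or r.read_id < best[key].read_id:
            best[key] = r
    return [best[key] for key in sorted(best)]


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def matches_decoy(insert: str, decoys: list[str], max_mismatches: int = 1) -> bool:
    """True if the insert aligns to any decoy window (either strand) with <= max_mismatches."""
    for strand_insert in (insert, reverse_complement(insert)):
        n = len(strand_insert)
        for decoy in decoys:
            for i in range(len(decoy) - n + 1):
                if _hamming_within(strand_insert, decoy[i:i + n], max_mismatches):
                    return True
    return False


def filter_rrna(
    reads: list[ProcessedRead],
    decoys: list[str],
    max_mismatches: int = 1,
) -> tuple[list[ProcessedRead], int]:
    """Remove reads whose insert matches an rRNA decoy; returns (kept, n_removed)."""
    if not decoys:
        raise ValueError("decoy set must be nonempty")
    verdict: dict[str, bool] = {}
    kept: list[ProcessedRead] = []
    removed = 0
    for r in reads:
        hit = verdict.get(r.insert)
        if hit is None:
            hit = verdict[r.insert] = matches_decoy(r.insert, decoys, max_mismatches)
        if hit:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def _candidate_hits(insert: str, hairpin: Hairpin) -> list[tuple[int, str]]:
    """All sense placements of insert on one hairpin: (start, mismatch flag)."""
    hits: list[tuple[int, str]] = []
    seq = hairpin.sequence
    n = len(insert)
    # exact hits
    i = seq.find(insert)
    while i >= 0:
        hits.append((i, "none"))
        i = seq.find(insert, i + 1)
    # single terminal 3' mismatch: all but the last nucleotide match exactly
    prefix = insert[:-1]
    i = seq.find(prefix)
    while i >= 0:
        j = i + n - 1
        if j < len(seq) and seq[j] != insert[-1]:
            hits.append((i, "terminal3p"))
        i = seq.find(prefix, i + 1)
    return hits


def map_to_hairpins(
    insert: str,
    reference: list[Hairpin],
) -> tuple[HairpinAssignment | None, int]:
    """Place an insert on the reference, sense strand only.

    Accepts zero-mismatch hits or hits whose sole mismatch is the insert's
    final 3' nucleotide (non-templated addition).  Ties break toward exact
    hits, then the lexicographically lowest hairpin id, then the lowest start,
    so every read is counted exactly once.  Returns the winning assignment (or
    None when unmapped) and the number of candidate hits, so callers can log
    multi-mapping ambiguity.
    """
    candidates: list[tuple[int, str, int, str]] = []  # (penalty, hairpin_id, start, flag)
    for h in reference:
        for start, flag in _candidate_hits(insert, h):
            candidates.append((0 if flag == "none" else 1, h.hairpin_id, start, flag))
    if not candidates:
        return None, 0
    penalty, hid, start, flag = min(candidates)
    hairpin = next(h for h in reference if h.hairpin_id == hid)
    mature_name = None
    for m in hairpin.matures:
        if m.start <= start < m.end:
            mature_name = m.name
            break
    return HairpinAssignment(hid, mature_name, start, flag), len(candidates)


def count_isomirs(
    assigned: list[tuple[ProcessedRead, HairpinAssignment]],
) -> pd.DataFrame:
    """Group deduplicated assignments by (hairpin, 5' start); count = group size.

    Reads sharing a 5' start but differing at the 3' end (trimming variants,
    non-templated additions) collapse into a single 5' isomiR row.  The
    representative sequence is the most frequent insert in the group
    (lexicographic tie-break).  Sum of counts equals the number of inputs.
    """
    groups: dict[tuple[str, int], dict] = {}
    for read, asn in assigned:
        key = (asn.hairpin_id, asn.start5)
        g = groups.setdefault(key, {"mature_name": asn.mature_name, "inserts": {}})
        g["inserts"][read.insert] = g["inserts"].get(read.insert, 0) + 1
    rows = []
    for (hid, start5), g in sorted(groups.items()):
        rep = min(g["inserts"], key=lambda s: (-g["inserts"][s], s))
        rows.append(
            {
                "hairpin_id": hid,
                "start5": start5,
                "mature_name": g["mature_name"],
                "sequence": rep,
                "count": sum(g["inserts"].values()),
            }
        )
    return pd.DataFrame(rows, columns=["hairpin_id", "start5", "mature_name", "sequence", "count"])


def count_spikeins(inserts: list[str], pool: list[SpikeInOligo]) -> pd.DataFrame:
    """Count exact full-length matches to spike-in oligos (no mismatches)."""
    if not pool:
        raise ValueError("spike-in pool must be nonempty")
    seqs = [o.sequence for o in pool]
    if len(set(seqs)) != len(seqs):
        raise ValueError("spike-in pool contains duplicate sequences")
    by_seq = {o.sequence: o.oligo_id for o in pool}
    counts = {o.oligo_id: 0 for o in pool}
    for ins in inserts:
        oid = by_seq.get(ins)
        if oid is not None:
            counts[oid] += 1
    return pd.DataFrame(
        {"oligo_id": list(counts), "count": list(counts.values())},
        columns=["oligo_id", "count"],
    )


@dataclass
class ProcessResult:
    """Per-sample outputs: isomiR counts, spike-in counts, processing statistics."""

    isomir_counts: pd.DataFrame
    spikein_counts: pd.DataFrame
    stats: dict[str, int] = field(default_factory=dict)


def process_reads(
    reads: list[tuple[str, str]],
    reference: list[Hairpin],
    pool: list[SpikeInOligo],
    rrna_decoys: list[str] | None = None,
    structure: ReadStructure = DEFAULT_READ_STRUCTURE,
) -> ProcessResult:
    """Run the full per-sample pipeline: trim -> dedup -> rRNA filter -> count.

    Statistics account for every raw read exactly once:
    ``raw = no_adapter + bad_umi + length + pcr_duplicates + rrna_removed +
    spikein + unmapped + assigned``.  A read matching both a spike-in and a
    hairpin is counted as spike-in (with a warning); mapping is memoized per
    distinct insert.
    """
    stats = {k: 0 for k in ("raw", "no_adapter", "bad_umi", "length", "pcr_duplicates",
                            "rrna_removed", "spikein", "unmapped", "assigned", "ambiguous")}
    stats["raw"] = len(reads)
    processed: list[ProcessedRead] = []
    for rid, seq in reads:
        out = trim_and_extract(rid, seq, structure)
        if isinstance(out, Rejection):
            stats[out.reason] += 1
        else:
            processed.append(out)

    deduped = deduplicate(processed)
    stats["pcr_duplicates"] = len(processed) - len(deduped)

    if rrna_decoys:
        deduped, removed = filter_rrna(deduped, rrna_decoys)
        stats["rrna_removed"] = removed

    spike_by_seq = {o.sequence: o.oligo_id for o in pool}
    if len(spike_by_seq) != len(pool):
        raise ValueError("spike-in pool contains duplicate sequences")
    spike_counts = {o.oligo_id: 0 for o in pool}
    assigned: list[tuple[ProcessedRead, HairpinAssignment]] = []
    map_cache: dict[str, tuple[HairpinAssignment | None, int]] = {}
    for r in deduped:
        oid = spike_by_seq.get(r.insert)
        if oid is not None:
            asn, _ = map_cache.get(r.insert) or map_to_hairpins(r.insert, reference)
            if asn is not None:
                logger.warning("insert matches both spike-in %s and hairpin %s; counted as spike-in",
                               oid, asn.hairpin_id)
            spike_counts[oid] += 1
            stats["spikein"] += 1
            continue
        if r.insert not in map_cache:
            map_cache[r.insert] = map_to_hairpins(r.insert, reference)
        asn, n_hits = map_cache[r.insert]
        if asn is None:
            stats["unmapped"] += 1
        else:
            if n_hits > 1:
                stats["ambiguous"] += 1
            assigned.append((r, asn))
            stats["assigned"] += 1

    isomirs = count_isomirs(assigned)
    spikes_df = pd.DataFrame(
        {"oligo_id": list(spike_counts), "count": list(spike_counts.values())},
        columns=["oligo_id", "count"],
    )
    return ProcessResult(isomir_counts=isomirs, spikein_counts=spikes_df, stats=stats)


def read_fastq(path: str) -> list[tuple[str, str]]:
    """Load a FASTQ file as (read id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")]
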