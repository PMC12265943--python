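"""Read processing: trimming, UMI handling, dedup, filtering, mapping, counting.

Each nontrivial operation is checked against an independent brute-force
oracle (exhaustive Hamming scans, set construction) on randomized inputs.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirabs.smallrna_reads import (
    HairpinAssignment,
    ProcessedRead,
    Rejection,
    count_isomirs,
    count_spikeins,
    deduplicate,
    filter_rrna,
    map_to_hairpins,
    matches_decoy,
    process_reads,
    reverse_complement,
    trim_and_extract,
)
from mirabs.synthetic_data import (
    ADAPTER3,
    LibraryTruth,
    SpikeInOligo,
    simulate_small_rna_library,
)

DNA = "ACGT"


def _rand_seq(rng, n):
    return "".join(rng.choice(list(DNA), size=n))


def build_read(insert, umi5="AAA", umi5b="CCC", umi5c="GGG", umi3a="TTT", umi3b="ACA", umi3c="GAG"):
    """Construct a raw read with valid anchors around the given insert."""
    block5 = umi5 + "CGA" + umi5b + "TAC" + umi5c
    block3 = umi3a + "GTC" + umi3b + "TAG" + umi3c
    return block5 + insert + block3 + ADAPTER3


class TestTrimAndExtract:
    def test_round_trip_recovers_insert_and_umi(self):
        insert = "TGGAGTGTGACAATGGTGTTT"
        read = build_read(insert)
        out = trim_and_extract("r1", read)
        assert isinstance(out, ProcessedRead)
        assert out.insert == insert
        assert out.umi == "AAACCCGGG" + "TTTACAGAG"

    def test_alternative_5prime_adapter_variant_accepted(self):
        insert = "TGGAGTGTGACAATGGTGTTT"
        read = "AAAATCCCCAGTGGG" + insert + "TTTGTCACATAGGAG" + ADAPTER3
        out = trim_and_extract("r1", read)
        assert isinstance(out, ProcessedRead)
        assert out.insert == insert

    def test_truncated_adapter_at_read_end(self):
        insert = "A" * 30
        full = build_read(insert)
        # keep only 12 nt of adapter, as a fixed-length sequencer would
        read = full[: 30 + 30 + 12]
        out = trim_and_extract("r1", read)
        assert isinstance(out, ProcessedRead)
        assert out.insert == insert

    def test_no_adapter_rejected(self):
        out = trim_and_extract("r1", "ACGT" * 20)
        assert out == Rejection("r1", "no_adapter")

    def test_bad_umi_anchor_rejected(self):
        insert = "TGGAGTGTGACAATGGTGTTT"
        read = build_read(insert)
        corrupted = read[:3] + "GGG" + read[6:]  # break the CGA anchor
        out = trim_and_extract("r1", corrupted)
        assert out == Rejection("r1", "bad_umi")

    @pytest.mark.parametrize("n, verdict", [(13, "length"), (14, "ok"), (54, "ok"), (55, "length")])
    def test_insert_length_boundaries(self, n, verdict):
        out = trim_and_extract("r1", build_read("A" * n))
        if verdict == "ok":
            assert isinstance(out, ProcessedRead)
        else:
            assert out == Rejection("r1", "length")


class TestDeduplicate:
    def test_collapses_identical_pairs(self):
        r = ProcessedRead("a", "ACGT" * 5, "A" * 18)
        assert len(deduplicate([r, r, r])) == 1

    def test_umi_distinguishes_molecules(self):
        a = ProcessedRead("a", "ACGT" * 5, "A" * 18)
        b = ProcessedRead("b", "ACGT" * 5, "C" * 18)
        assert len(deduplicate([a, b])) == 2

    @given(st.lists(st.tuples(st.sampled_from(["ACGTACGTACGTAC", "TTTTAAAACCCCGG"]),
                              st.sampled_from(["A" * 18, "C" * 18, "G" * 18])), max_size=50))
    @settings(deadline=None)
    def test_matches_set_oracle(self, pairs):
        reads = [ProcessedRead(f"r{i}", ins, umi) for i, (ins, umi) in enumerate(pairs)]
        out = deduplicate(reads)
        assert len(out) == len(set(pairs))
        assert [(r.insert, r.umi) for r in out] == sorted(set(pairs))


def oracle_decoy_match(insert, decoys, max_mm=1):
    """Brute-force Hamming scan over every decoy window and both strands."""
    for q in (insert, reverse_complement(insert)):
        for d in decoys:
            for i in range(len(d) - len(q) + 1):
                if sum(a != b for a, b in zip(q, d[i:i + len(q)])) <= max_mm:
                    return True
    return False


class TestRrnaFilter:
    DECOYS = None

    @pytest.fixture(autouse=True)
    def _decoys(self, rng):
        self.decoys = [_rand_seq(rng, 150), _rand_seq(rng, 120)]

    def test_exact_substring_removed(self):
        insert = self.decoys[0][10:32]
        kept, removed = filter_rrna([ProcessedRead("r", insert, "A" * 18)], self.decoys)
        assert removed == 1 and not kept

    def test_antisense_match_removed(self):
        insert = reverse_complement(self.decoys[0][10:32])
        kept, removed = filter_rrna([ProcessedRead("r", insert, "A" * 18)], self.decoys)
        assert removed == 1

    def test_two_mismatches_retained(self):
        w = list(self.decoys[0][10:32])
        w[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[w[3]]
        w[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[w[10]]
        insert = "".join(w)
        if oracle_decoy_match(insert, self.decoys):  # rare chance hit elsewhere
            pytest.skip("random insert matched another window")
        kept, removed = filter_rrna([ProcessedRead("r", insert, "A" * 18)], self.decoys)
        assert removed == 0 and len(kept) == 1

    def test_empty_input(self):
        kept, removed = filter_rrna([], self.decoys)
        assert kept == [] and removed == 0

    def test_empty_decoys_rejected(self):
        with pytest.raises(ValueError):
            filter_rrna([], [])

    def test_oracle_agreement_on_random_inserts(self, rng):
        for _ in range(150):
            if rng.random() < 0.5:
                ins = _rand_seq(rng, int(rng.integers(14, 30)))
            else:  # near-copies of decoy windows to exercise the boundary
                d = self.decoys[int(rng.integers(0, 2))]
                n = int(rng.integers(14, 30))
                i = int(rng.integers(0, len(d) - n + 1))
                w = list(d[i:i + n])
                for _ in range(int(rng.integers(0, 3))):
                    w[int(rng.integers(0, n))] = DNA[int(rng.integers(0, 4))]
                ins = "".join(w)
            assert matches_decoy(ins, self.decoys) == oracle_decoy_match(ins, self.decoys)


def oracle_map(insert, reference):
    """Exhaustive window scan on both strands with the documented tie-break."""
    candidates = []
    for h in reference:
        for strand, seq in (("sense", h.sequence),):
            for i in range(len(seq) - len(insert) + 1):
                window = seq[i:i + len(insert)]
                mism = [k for k, (a, b) in enumerate(zip(insert, window)) if a != b]
                if not mism:
                    candidates.append((0, h.hairpin_id, i, "none"))
                elif len(mism) == 1 and mism[0] == len(insert) - 1:
                    candidates.append((1, h.hairpin_id, i, "terminal3p"))
    if not candidates:
        return None, 0
    penalty, hid, start, flag = min(candidates)
    hp = next(h for h in reference if h.hairpin_id == hid)
    mature = next((m.name for m in hp.matures if m.start <= start < m.end), None)
    return HairpinAssignment(hid, mature, start, flag), len(candidates)


class TestHairpinMapping:
    def test_exact_mature_assigned(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        insert = h.sequence[m.start:m.end]
        asn, _ = map_to_hairpins(insert, small_reference)
        assert asn is not None and asn.mismatch == "none"
        assert asn.start5 == m.start or asn.hairpin_id == h.hairpin_id

    def test_terminal_mismatch_accepted_as_nta(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        insert = h.sequence[m.start:m.end]
        swapped = {"A": "C", "C": "G", "G": "T", "T": "A"}[insert[-1]]
        asn, _ = map_to_hairpins(insert[:-1] + swapped, small_reference)
        oracle, _ = oracle_map(insert[:-1] + swapped, small_reference)
        assert asn == oracle
        if asn is not None and asn.hairpin_id == h.hairpin_id and asn.start5 == m.start:
            assert asn.mismatch == "terminal3p"

    def test_reverse_complement_rejected(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        rc = reverse_complement(h.sequence[m.start:m.end])
        asn, _ = map_to_hairpins(rc, small_reference)
        assert asn == oracle_map(rc, small_reference)[0]  # sense-only rule

    def test_internal_mismatch_rejected(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        insert = list(h.sequence[m.start:m.end])
        insert[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[insert[5]]
        insert = "".join(insert)
        asn, _ = map_to_hairpins(insert, small_reference)
        assert asn == oracle_map(insert, small_reference)[0]

    def test_oracle_agreement_on_random_inserts(self, small_reference, rng):
        """Exhaustive Hamming-scan equivalence on >=100 random instances."""
        for _ in range(120):
            kind = rng.random()
            if kind < 0.3:
                ins = _rand_seq(rng, int(rng.integers(14, 27)))
            else:
                h = small_reference[int(rng.integers(0, len(small_reference)))]
                n = int(rng.integers(14, 27))
                i = int(rng.integers(0, len(h.sequence) - n + 1))
                w = list(h.sequence[i:i + n])
                for _ in range(int(rng.integers(0, 3))):
                    w[int(rng.integers(0, n))] = DNA[int(rng.integers(0, 4))]
                if rng.random() < 0.3:
                    w = list(reverse_complement("".join(w)))
                ins = "".join(w)
            got, _ = map_to_hairpins(ins, small_reference)
            expected, _ = oracle_map(ins, small_reference)
            assert got == expected


class TestCounting:
    def test_same_5prime_start_grouped(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        full = h.sequence[m.start:m.end]
        short = h.sequence[m.start:m.end - 1]  # 3' trimming variant
        reads = [ProcessedRead("a", full, "A" * 18), ProcessedRead("b", short, "C" * 18)]
        assigned = [(r, map_to_hairpins(r.insert, small_reference)[0]) for r in reads]
        table = count_isomirs(assigned)
        grp = table[(table.hairpin_id == h.hairpin_id) & (table.start5 == m.start)]
        assert len(grp) == 1 and grp["count"].iloc[0] == 2

    def test_distinct_starts_distinct_rows(self, small_reference):
        h = small_reference[0]
        m = h.matures[0]
        a = h.sequence[m.start:m.end]
        b = h.sequence[m.start + 1:m.end]
        assigned = [
            (ProcessedRead("a", a, "A" * 18), map_to_hairpins(a, small_reference)[0]),
            (ProcessedRead("b", b, "C" * 18), map_to_hairpins(b, small_reference)[0]),
        ]
        table = count_isomirs(assigned)
        assert len(table) >= 2

    def test_count_conservation(self, small_reference, rng):
        reads = []
        for i in range(200):
            h = small_reference[int(rng.integers(0, len(small_reference)))]
            m = h.matures[int(rng.integers(0, len(h.matures)))]
            off = int(rng.integers(-2, 3))
            start = max(0, min(m.start + off, m.end - 14))
            reads.append(ProcessedRead(f"r{i}", h.sequence[start:m.end], _rand_seq(rng, 18)))
        assigned = [(r, map_to_hairpins(r.insert, small_reference)[0]) for r in reads]
        assigned = [(r, a) for r, a in assigned if a is not None]
        table = count_isomirs(assigned)
        assert table["count"].sum() == len(assigned)

    def test_spikein_exact_matching(self, pool):
        oligo = pool[0]
        mut = ("A" if oligo.sequence[0] != "A" else "C") + oligo.sequence[1:]
        counts = count_spikeins([oligo.sequence, oligo.sequence, mut], pool)
        assert counts.set_index("oligo_id").loc[oligo.oligo_id, "count"] == 2
        assert counts["count"].sum() == 2  # the mutant matched nothing

    def test_spikein_oracle_equivalence(self, pool, rng):
        inserts = [o.sequence for o in pool for _ in range(int(rng.integers(0, 5)))]
        inserts += [_rand_seq(rng, 25) for _ in range(20)]
        rng.shuffle(inserts)
        counts = count_spikeins(inserts, pool).set_index("oligo_id")["count"]
        for o in pool:
            assert counts[o.oligo_id] == sum(1 for i in inserts if i == o.sequence)

    def test_duplicate_pool_sequences_rejected(self):
        dup = [SpikeInOligo("a", "ACGT" * 5, 1e-18), SpikeInOligo("b", "ACGT" * 5, 1e-18)]
        with pytest.raises(ValueError):
            count_spikeins(["ACGTACGT"], dup)


class TestPipelineConservation:
    def test_every_raw_read_accounted_once(self, reference, pool, rng):
        truth = LibraryTruth(
            molecules={m.name: 50 for h in reference for m in h.matures}
            | {o.oligo_id: 30 for o in pool},
            nta_rate=0.15,
            duplication_rate=0.4,
            depth=5000,
            seed=77,
        )
        lib = simulate_small_rna_library(truth, reference, pool)
        decoys = [_rand_seq(rng, 150)]
        res = process_reads(lib.reads, reference, pool, rrna_decoys=decoys)
        s = res.stats
        assert s["raw"] == len(lib.reads)
        assert s["raw"] == (
            s["no_adapter"] + s["bad_umi"] + s["length"] + s["pcr_duplicates"]
            + s["rrna_removed"] + s["spikein"] + s["unmapped"] + s["assigned"]
        )
        assert res.isomir_counts["count"].sum() == s["assigned"]
        assert res.spikein_counts["count"].sum() == s["spikein"]

    def test_round_trip_fractions_recovered_without_bias(self, reference, pool):
        """Zero bias, zero NTA, zero duplication: recovered isomiR fractions
        match truth fractions within 3 binomial SD."""
        names = [m.name for h in reference for m in h.matures]
        rng = np.random.default_rng(5)
        molecules = {n: float(rng.integers(200, 2000)) for n in names}
        depth = 100_000
        truth = LibraryTruth(
            molecules=molecules,
            isomir_offsets={0: 1.0},
            nta_rate=0.0,
            duplication_rate=0.0,
            depth=depth,
            seed=6,
        )
        lib = simulate_small_rna_library(truth, reference, pool)
        res = process_reads(lib.reads, reference, pool)
        mature_of = {(h.hairpin_id, m.start): m.name for h in reference for m in h.matures}
        counts = {}
        for row in res.isomir_counts.itertuples():
            name = mature_of.get((row.hairpin_id, row.start5))
            if name is not None:
                counts[name] = counts.get(name, 0) + row.count
        total_mol = sum(molecules.values())
        for n in names:
            p = molecules[n] / total_mol
            sd = np.sqrt(depth * p * (1 - p))
            assert abs(counts.get(n, 0) - depth * p) <= 3 * sd + 1
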