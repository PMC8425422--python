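import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from hla_cohort_qc import simulate
from hla_cohort_qc.genotyper import (
    GeneEvidence,
    GroupCounts,
    InvalidReadError,
    ReadAligner,
    align_read,
    call_locus_from_evidence,
    collect_evidence,
    compute_expression,
    count_group_hits,
    outlier_pvalue,
    revcomp,
    type_sample,
    TypingParams,
    LocusCall,
)
from hla_cohort_qc.reference import AlleleRecord, AlleleReference, select_genes
from hla_cohort_qc.samples import SampleSpec, discover_samples

from _oracles import brute_force_align


def _random_ref(rng, n_alleles=10, length=150, gene="A"):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    recs = []
    for i in range(n_alleles):
        seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
        recs.append(AlleleRecord(gene, f"{gene}*{i + 1:02d}:01:01",
                                 f"{gene}*{i + 1:02d}:01", seq))
    return AlleleReference(recs)


class TestAlignRead:
    def test_exact_substring_hit(self):
        rng = np.random.default_rng(0)
        ref = _random_ref(rng)
        seq = ref.records[3].sequence
        read = seq[40:90]
        hits = align_read(read, ref, max_mismatches=2)
        assert ref.records[3].allele_name in hits

    def test_three_mismatches_rejected(self):
        ref = AlleleReference([AlleleRecord("A", "A*01:01", "A*01:01", "A" * 60)])
        read = "A" * 10 + "C" + "A" * 10 + "C" + "A" * 10 + "C" + "A" * 7
        assert align_read(read, ref, max_mismatches=2) == set()
        assert align_read(read, ref, max_mismatches=3) == {"A*01:01"}

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(1)
        ref = _random_ref(rng)
        read = ref.records[0].sequence[10:60]
        fwd = align_read(read, ref, 2)
        rev = align_read(revcomp(read), ref, 2)
        assert fwd == rev and ref.records[0].allele_name in fwd

    def test_read_longer_than_allele_cannot_hit(self):
        ref = AlleleReference([AlleleRecord("A", "A*01:01", "A*01:01", "ACGTACGT")])
        assert align_read("ACGTACGTA", ref, 2) == set()

    def test_invalid_characters_raise(self):
        ref = AlleleReference([AlleleRecord("A", "A*01:01", "A*01:01", "ACGTACGT")])
        with pytest.raises(InvalidReadError):
            ReadAligner(ref, 2).align("ACGR")

    @pytest.mark.parametrize("max_mm", [0, 1, 2, 3])
    def test_brute_force_oracle_equivalence(self, max_mm):
        rng = np.random.default_rng(7 + max_mm)
        ref = _random_ref(rng, n_alleles=12, length=160)
        aligner = ReadAligner(ref, max_mm)
        bases = "ACGT"
        for _ in range(40):
            src = ref.records[rng.integers(len(ref.records))].sequence
            start = int(rng.integers(0, len(src) - 40))
            read = list(src[start:start + 40])
            for _ in range(int(rng.integers(0, 5))):  # 0-4 mutations
                p = int(rng.integers(0, 40))
                read[p] = bases[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.integers(0, 2):
                read = revcomp(read)
            assert aligner.align(read) == brute_force_align(
                read, ref.records, max_mm)
        # fully random reads too (mostly misses)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(15):
            read = arr[rng.integers(0, 4, size=40)].tobytes().decode()
            assert aligner.align(read) == brute_force_align(
                read, ref.records, max_mm)


def _write_single(tmp_path, reads, name="s"):
    p = tmp_path / f"{name}.fastq"
    p.write_text("".join(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n"
                         for i, r in enumerate(reads)))
    return SampleSpec(name, "single", (p,), len(reads[0]) if reads else 0)


def _write_paired(tmp_path, pairs, name="s"):
    p1 = tmp_path / f"{name}_R1.fastq"
    p2 = tmp_path / f"{name}_R2.fastq"
    p1.write_text("".join(f"@r{i}\n{a}\n+\n{'I' * len(a)}\n"
                          for i, (a, _) in enumerate(pairs)))
    p2.write_text("".join(f"@r{i}\n{b}\n+\n{'I' * len(b)}\n"
                          for i, (_, b) in enumerate(pairs)))
    return SampleSpec(name, "paired", (p1, p2), len(pairs[0][0]) if pairs else 0)


class TestCountGroupHits:
    def test_error_free_reads_from_one_allele(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = _random_ref(rng, n_alleles=8, length=200)
        src = ref.records[2]
        reads = []
        for _ in range(100):
            start = int(rng.integers(0, len(src.sequence) - 50))
            reads.append(src.sequence[start:start + 50])
        spec = _write_single(tmp_path, reads)
        counts = count_group_hits(spec, ref, 2)["A"]
        assert counts.counts[src.group4] == 100
        assert counts.total_sample_reads == 100
        # cross-check every group against the brute-force oracle
        expected = {g: 0 for g in ref.groups_by_gene["A"]}
        group_of = {r.allele_name: r.group4 for r in ref.records}
        for read in reads:
            for g in {group_of[n] for n in brute_force_align(read, ref.records, 2)}:
                expected[g] += 1
        assert counts.counts == expected

    def test_empty_sample_all_zero(self, tmp_path):
        ref = _random_ref(np.random.default_rng(4))
        p = tmp_path / "e.fastq"
        p.write_text("")
        counts = count_group_hits(SampleSpec("e", "single", (p,), 0), ref, 2)
        assert all(c == 0 for c in counts["A"].counts.values())

    def test_multi_group_read_counts_both(self, tmp_path):
        shared = "ACGTTGCAACGTTGCAACGTTGCA"  # 24 bp common core
        ref = AlleleReference([
            AlleleRecord("A", "A*01:01", "A*01:01", "AAAA" + shared + "TTTT"),
            AlleleRecord("A", "A*01:02", "A*01:02", "CCCC" + shared + "GGGG"),
        ])
        spec = _write_single(tmp_path, [shared])
        counts = count_group_hits(spec, ref, 0)["A"]
        assert counts.counts == {"A*01:01": 1, "A*01:02": 1}

    def test_paired_requires_both_mates_same_group(self, tmp_path):
        rng = np.random.default_rng(5)
        ref = _random_ref(rng, n_alleles=4, length=200)
        a, b = ref.records[0], ref.records[1]
        concordant = (a.sequence[0:50], revcomp(a.sequence[100:150]))
        discordant = (a.sequence[0:50], revcomp(b.sequence[100:150]))
        spec = _write_paired(tmp_path, [concordant, discordant])
        counts = count_group_hits(spec, ref, 2)["A"]
        assert counts.counts[a.group4] == 1
        assert counts.counts[b.group4] == 0

    def test_invalid_reads_skipped_with_counter(self, tmp_path):
        ref = _random_ref(np.random.default_rng(6))
        good = ref.records[0].sequence[:50]
        spec = _write_single(tmp_path, [good, "N" * 20 + "R" + "N" * 29])
        sev = collect_evidence(spec, ref)
        assert sev.skipped_reads == 1
        assert sev.total_units == 2


class TestOutlierPvalue:
    def test_derived_example(self):
        counts = GroupCounts("A", {"X": 100, "Y": 5, "Z": 4, "W": 3}, 112)
        p = outlier_pvalue(counts, "X")
        others = np.array([5.0, 4.0, 3.0])
        expected = float(norm.sf((100 - others.mean()) / others.std(ddof=0)))
        assert p == pytest.approx(expected)
        assert p < 0.05

    def test_all_equal_counts(self):
        counts = GroupCounts("A", {"X": 7, "Y": 7, "Z": 7}, 21)
        assert outlier_pvalue(counts, "X") >= 0.5

    def test_degenerate_all_zero(self):
        counts = GroupCounts("A", {"X": 0, "Y": 0, "Z": 0}, 0)
        assert outlier_pvalue(counts, "X") == 1.0

    def test_sigma_zero_candidate_above(self):
        counts = GroupCounts("A", {"X": 5, "Y": 2, "Z": 2}, 9)
        assert outlier_pvalue(counts, "X") == 0.0

    def test_single_reference_group(self):
        counts = GroupCounts("A", {"X": 10}, 10)
        assert outlier_pvalue(counts, "X") == 0.0

    def test_unknown_candidate_raises(self):
        with pytest.raises(KeyError):
            outlier_pvalue(GroupCounts("A", {"X": 1}, 1), "Q")

    @given(
        others=st.lists(st.integers(0, 50), min_size=2, max_size=8),
        c=st.integers(0, 200),
        bump=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_candidate_count(self, others, c, bump):
        base = {f"g{i}": v for i, v in enumerate(others)}
        lo = outlier_pvalue({**base, "cand": c}, "cand")
        hi = outlier_pvalue({**base, "cand": c + bump}, "cand")
        assert hi <= lo


def _evidence(gene, groupsets):
    ev = GeneEvidence(gene)
    for gs, c in groupsets.items():
        ev.groupset_counts[frozenset(gs)] = c
    return ev


def _two_group_ref():
    rng = np.random.default_rng(9)
    return _random_ref(rng, n_alleles=6, length=200)


class TestCallLocus:
    def test_het_recovery(self, tmp_path):
        rng = np.random.default_rng(10)
        ref = _two_group_ref()
        a, b = ref.records[0], ref.records[4]
        reads = []
        for src in (a, b):
            for _ in range(500):
                start = int(rng.integers(0, len(src.sequence) - 50))
                reads.append(src.sequence[start:start + 50])
        spec = _write_single(tmp_path, reads)
        sev = collect_evidence(spec, ref)
        call = call_locus_from_evidence(sev.evidence["A"], ref, sev.total_units)
        assert call.zygosity == "het"
        assert {call.allele1, call.allele2} == {a.group4, b.group4}
        assert call.p1 < 0.05 and call.p2 < 0.05

    def test_hom_call(self, tmp_path):
        rng = np.random.default_rng(11)
        ref = _two_group_ref()
        src = ref.records[1]
        reads = [src.sequence[int(s):int(s) + 50]
                 for s in rng.integers(0, len(src.sequence) - 50, size=400)]
        spec = _write_single(tmp_path, reads)
        sev = collect_evidence(spec, ref)
        call = call_locus_from_evidence(sev.evidence["A"], ref, sev.total_units)
        assert call.zygosity == "hom"
        assert call.allele1 == src.group4
        assert call.allele2 is None

    def test_nocall_on_zero_reads(self):
        ref = _two_group_ref()
        call = call_locus_from_evidence(GeneEvidence("A"), ref, 0)
        assert call.zygosity == "nocall"
        assert call.allele1 is None and call.rpkm == 0.0

    def test_tie_breaks_lexicographic(self):
        ref = _two_group_ref()
        g_lo = min(ref.groups_by_gene["A"])
        g_hi = max(ref.groups_by_gene["A"])
        ev = _evidence("A", {(g_hi,): 10, (g_lo,): 10})
        call = call_locus_from_evidence(ev, ref, 20)
        assert call.allele1 == g_lo

    def test_hom_ratio_boundary(self):
        ref = _two_group_ref()
        g1, g2 = sorted(ref.groups_by_gene["A"])[:2]
        ev = _evidence("A", {(g1,): 1000, (g2,): 49})
        call = call_locus_from_evidence(ev, ref, 1049,
                                        TypingParams(hom_ratio=0.05))
        assert call.zygosity == "hom"
        ev2 = _evidence("A", {(g1,): 1000, (g2,): 51})
        call2 = call_locus_from_evidence(ev2, ref, 1051,
                                         TypingParams(hom_ratio=0.05))
        assert call2.zygosity == "het"


class TestComputeExpression:
    def _call(self, zyg="hom", a1="A*01:01", a2=None):
        return LocusCall("A", a1, 0.0, a2, None, zyg, (0, 0), 0.0)

    def test_arithmetic(self):
        ref = AlleleReference(
            [AlleleRecord("A", "A*01:01", "A*01:01", "A" * 1100)])
        rpkm = compute_expression(self._call(), {"A*01:01": 1000}, 10 ** 6, ref)
        assert rpkm == pytest.approx(909.0909, rel=1e-4)

    def test_nocall_zero(self):
        ref = AlleleReference([AlleleRecord("A", "A*01:01", "A*01:01", "ACGT")])
        call = LocusCall("A", None, None, None, None, "nocall", (0, 0), 0.0)
        assert compute_expression(call, {}, 100, ref) == 0.0

    def test_doubling_total_reads_halves_rpkm(self):
        ref = AlleleReference(
            [AlleleRecord("A", "A*01:01", "A*01:01", "A" * 500)])
        r1 = compute_expression(self._call(), {"A*01:01": 100}, 1000, ref)
        r2 = compute_expression(self._call(), {"A*01:01": 100}, 2000, ref)
        assert r1 == pytest.approx(2 * r2)


@pytest.fixture(scope="module")
def recovery_setup():
    rng = np.random.default_rng(20)
    ref = simulate.synthetic_reference(rng, groups_per_gene=8, seq_len=300)
    ref5 = select_genes(ref, 5)
    table = simulate.synthetic_frequency_table(ref)
    gt = simulate.sample_genotype(simulate.adjust_frequencies(table, ref),
                                  ref, rng)
    return ref, ref5, gt


class TestTypeSample:
    def _simulate(self, gt, ref, layout, tmp_path, rng):
        params = simulate.SimParams(
            n_individuals=2, samples_min=1, samples_max=1, layout=layout,
            reads_min=8000, reads_max=8000, error_rate=0.0,
            expression_weights={g: 1.0 for g in gt.copies})
        simulate.simulate_sample(gt, ref, params, rng, tmp_path, "s", 8000)
        return discover_samples(tmp_path)[0]

    def test_paired_recovery_and_single_end_agreement(self, recovery_setup,
                                                      tmp_path):
        ref, ref5, gt = recovery_setup
        spec_p = self._simulate(gt, ref, "paired", tmp_path / "p",
                                np.random.default_rng(21))
        spec_s = self._simulate(gt, ref, "single", tmp_path / "s",
                                np.random.default_rng(22))
        ty_p = type_sample(spec_p, ref5)
        ty_s = type_sample(spec_s, ref5)
        for gene in ref5.genes:
            truth = set(gt.groups(gene))
            for ty in (ty_p, ty_s):
                call = ty.calls[gene]
                called = {call.allele1} if call.zygosity == "hom" \
                    else {call.allele1, call.allele2}
                assert called == truth, (gene, called, truth)

    def test_empty_sample_all_nocall(self, recovery_setup, tmp_path):
        ref, ref5, _ = recovery_setup
        p = tmp_path / "e.fastq"
        p.write_text("")
        ty = type_sample(SampleSpec("e", "single", (p,), 0), ref5)
        assert all(c.zygosity == "nocall" for c in ty.calls.values())

    def test_determinism(self, recovery_setup, tmp_path):
        ref, ref5, gt = recovery_setup
        spec = self._simulate(gt, ref, "paired", tmp_path,
                              np.random.default_rng(23))
        t1 = type_sample(spec, ref5)
        t2 = type_sample(spec, ref5)
        assert t1 == t2
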