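import math

import numpy as np
import pytest

import sagbin as sb
from sagbin.io_formats import SeqRecord, revcomp
from sagbin.homology_recruiter import (
    ScoringParams,
    SeqDatabase,
    recover_marker_reads,
    recruit_reads,
    seed_and_extend,
    solve_lambda,
)


def random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def bisection_lambda(match, mismatch, tol=1e-12):
    """Independent oracle: plain interval bisection on the defining equation
    for a uniform background."""

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestKarlinAltschul:
    def test_plus1_minus1_closed_form(self):
        # x/4 + 3/(4x) = 1 with x = e^lambda has roots x in {1, 3}
        assert abs(solve_lambda(1, -1) - math.log(3)) < 1e-9

    def test_plus2_minus3_matches_bisection_oracle(self):
        assert abs(solve_lambda(2, -3) - bisection_lambda(2, -3)) < 1e-9

    def test_non_negative_expected_score_refused(self):
        with pytest.raises(ValueError, match="expected score"):
            solve_lambda(1, 0)

    def test_params_lambda_verified_at_construction(self):
        p = ScoringParams(match=2, mismatch=-3)
        assert abs(p.lambda_ - bisection_lambda(2, -3)) < 1e-9

    def test_evalue_monotone_in_score(self):
        p = ScoringParams()
        evs = [p.evalue(s, 400, 10**7) for s in (20, 50, 100)]
        assert evs[0] > evs[1] > evs[2]

    def test_evalue_linear_in_database_length(self):
        p = ScoringParams()
        assert p.evalue(50, 400, 2 * 10**7) == pytest.approx(
            2 * p.evalue(50, 400, 10**7)
        )

    def test_perfect_100bp_match_passes_cutoff(self):
        # direct evaluation: E = K m n 3^(-S) for S=100 is astronomically small
        p = ScoringParams()
        e = p.evalue(100, 400, 10**7)
        expected = 0.1 * 400 * 10**7 * 3.0 ** (-100)
        assert e == pytest.approx(expected, rel=1e-9)
        assert e < 1e-15


class TestSeedAndExtend:
    def test_identical_sequences_single_full_hit(self):
        rng = np.random.default_rng(0)
        seq = random_dna(500, rng)
        hits = seed_and_extend(SeqRecord(id="q", seq=seq), SeqRecord(id="s", seq=seq))
        h = hits[0]
        assert h.percent_identity == 100.0 and h.aln_len == 500
        assert (h.qstart, h.qend, h.sstart, h.send) == (1, 500, 1, 500)
        # plus-strand hit and its mirror on the minus strand at most
        assert len([x for x in hits if not x.minus_strand]) == 1

    def test_reverse_complement_minus_strand_coordinates(self):
        rng = np.random.default_rng(1)
        seq = random_dna(300, rng)
        hits = seed_and_extend(
            SeqRecord(id="q", seq=revcomp(seq)), SeqRecord(id="s", seq=seq)
        )
        h = hits[0]
        assert h.minus_strand and (h.sstart, h.send) == (300, 1)
        assert (h.qstart, h.qend) == (1, 300)
        assert h.percent_identity == 100.0

    def test_no_shared_kmer_pair_yields_empty(self):
        # rejection-sample a pair verified (by direct k-mer set comparison,
        # both strands) to share no 11-mer
        rng = np.random.default_rng(2)
        k = 11
        while True:
            a, b = random_dna(1000, rng), random_dna(1000, rng)
            kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
            b_both = b + "N" + revcomp(b)
            kmers_b = {
                b_both[i : i + k]
                for i in range(len(b_both) - k + 1)
                if "N" not in b_both[i : i + k]
            }
            if not (kmers_a & kmers_b):
                break
        assert seed_and_extend(SeqRecord(id="a", seq=a), SeqRecord(id="b", seq=b)) == []

    def test_short_sequences_refused(self):
        with pytest.raises(ValueError):
            seed_and_extend(SeqRecord(id="a", seq="ACGT"), SeqRecord(id="b", seq="ACGT"))

    def test_best_raw_score_matches_brute_force_oracle(self):
        """On random pairs, the best hit's raw score equals the optimum over
        every seed's unbounded bidirectional extension (all diagonals)."""
        params = ScoringParams()
        k = params.seed_k
        rng = np.random.default_rng(3)

        def oracle_best(q, s):
            best = 0
            for sub, flip in ((s, False), (revcomp(s), True)):
                index = {}
                for j in range(len(sub) - k + 1):
                    index.setdefault(sub[j : j + k], []).append(j)
                for i in range(len(q) - k + 1):
                    for j in index.get(q[i : i + k], ()):
                        score = k
                        # optimal right extension: best prefix sum
                        run = score
                        qi, sj = i + k, j + k
                        while qi < len(q) and sj < len(sub):
                            run += 1 if q[qi] == sub[sj] else -1
                            score = max(score, run)
                            qi += 1
                            sj += 1
                        run = score
                        qi, sj = i - 1, j - 1
                        while qi >= 0 and sj >= 0:
                            run += 1 if q[qi] == sub[sj] else -1
                            score = max(score, run)
                            qi -= 1
                            sj -= 1
                        best = max(best, score)
            return best

        lam, lnK = params.lambda_, math.log(params.K)
        checked = 0
        for trial in range(40):
            n = int(rng.integers(200, 2000))
            q, s = random_dna(n, rng), random_dna(n, rng)
            if rng.random() < 0.5:
                # implant homology so some pairs have real alignments
                off = int(rng.integers(0, n - 150))
                s = s[:off] + q[off : off + 150] + s[off + 150 :]
            hits = seed_and_extend(
                SeqRecord(id="q", seq=q), SeqRecord(id="s", seq=s), params
            )
            got = 0
            if hits:
                got = round((hits[0].bitscore * math.log(2) + lnK) / lam)
            expected = oracle_best(q, s)
            assert got == expected
            checked += 1
        assert checked == 40


class TestRecruitment:
    @pytest.fixture()
    def scenario(self):
        rng = np.random.default_rng(5)
        genome = random_dna(30_000, rng)
        anchors = [
            SeqRecord(id=f"gene{i}", seq=genome[i * 3000 : i * 3000 + 1200])
            for i in range(4)
        ]
        reads = []
        for i in range(200):
            gi = i % 4
            off = int(rng.integers(0, 1000))
            seq = anchors[gi].seq[off : off + 200] + random_dna(50, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SeqRecord(id=f"r{i:03d}", seq=seq))
        unrelated = [
            SeqRecord(id=f"u{i:03d}", seq=random_dna(250, rng)) for i in range(200)
        ]
        return anchors, reads, unrelated

    def test_exact_substring_reads_recruited(self, scenario):
        anchors, reads, unrelated = scenario
        res = recruit_reads(anchors, reads + unrelated, anchor_labels="popA")
        hit_ids = {rid for rid in res.recruited if rid.startswith("r")}
        assert len(hit_ids) == len(reads)
        assert all(lab == "popA" for lab, _ in res.recruited.values())

    def test_unrelated_reads_not_recruited(self, scenario):
        anchors, reads, unrelated = scenario
        res = recruit_reads(anchors, unrelated)
        assert res.recruited == {}

    def test_empty_anchor_set_recruits_nothing(self, scenario):
        _, reads, _ = scenario
        assert recruit_reads([], reads).recruited == {}

    def test_monotone_in_evalue_cutoff(self, scenario):
        anchors, reads, unrelated = scenario
        pool = reads + unrelated
        sets = [
            set(recruit_reads(anchors, pool, evalue_max=e).recruited)
            for e in (1e-20, 1e-15, 1e-5)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_strand_closure(self, scenario):
        anchors, reads, _ = scenario
        flipped = [SeqRecord(id=r.id, seq=revcomp(r.seq)) for r in reads]
        a = set(recruit_reads(anchors, reads).recruited)
        b = set(recruit_reads(anchors, flipped).recruited)
        assert a == b

    def test_marker_mode_is_recruitment_with_marker_anchors(self, scenario):
        anchors, reads, _ = scenario
        markers = anchors[:1]
        via_marker = set(recover_marker_reads(markers, reads).recruited)
        via_recruit = set(recruit_reads(markers, reads).recruited)
        assert via_marker == via_recruit
        assert via_marker <= set(recruit_reads(anchors, reads).recruited)
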