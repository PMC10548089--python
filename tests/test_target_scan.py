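"""Duplex scoring and site scanning against hand scores and a
brute-force alignment oracle."""

import numpy as np
import pytest

from cnidomir.core_io import derive_rng
from cnidomir.synthetic_data import SiteSpec, random_mirna, simulate_transcripts_with_sites
from cnidomir.target_scan import (
    DuplexHit,
    ScanParams,
    reverse_complement,
    scan_targets,
    score_duplex,
)

P = ScanParams()
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

# 21-nt miRNA with a G at position 15 (for the wobble example); the
# perfect target below is its positionwise complement (3'->5')
MIR = "AAAAAAAAAAAAAAGAAAAAA"
PERFECT = "".join(COMP[c] for c in MIR)


def brute_force_min_expectation(mirna: str, transcript: str, params: ScanParams):
    """Independent enumeration of every ungapped and single-gap-run
    placement of the miRNA on the transcript; returns the minimal
    expectation among placements passing the seed and HSP filters, or
    None. Written with plain per-column loops, separately from the
    scanner's vectorized dynamic program."""

    def pair_pen(m, t):
        if COMP.get(m) == t:
            return 0.0, False
        if (m, t) in (("G", "U"), ("U", "G")):
            return params.gu_penalty, True
        return params.mismatch_penalty, True

    def w(pos):
        return params.seed_weight if params.seed_start <= pos <= params.seed_end else 1.0

    rt = transcript[::-1]
    M, N = len(mirna), len(rt)
    best = None

    def consider(score, seedmm, span):
        nonlocal best
        if score > params.max_expectation + 1e-9:
            return
        if seedmm > params.max_seed_mismatches or span < params.hsp_size:
            return
        if best is None or score < best:
            best = score

    def run_pairs(q, istart, iend, offset):
        score, seedmm = 0.0, 0
        for i in range(istart, iend):
            pen, mm = pair_pen(mirna[i], rt[q + offset + i])
            score += pen * w(i + 1)
            if mm and params.seed_start <= i + 1 <= params.seed_end:
                seedmm += 1
        return score, seedmm

    for q in range(0, N - M + 1):  # ungapped
        s, mm = run_pairs(q, 0, M, 0)
        consider(s, mm, M)
    for L in (1, 2):
        if L > params.max_gaps:
            continue
        gap_run = params.gap_open + (L - 1) * params.gap_extend
        for k in range(1, M):  # target bulge after miRNA position k
            for q in range(0, N - M - L + 1):
                s1, m1 = run_pairs(q, 0, k, 0)
                s2, m2 = run_pairs(q, k, M, L)
                gcost = gap_run * w(k + 1)
                gmm = L if params.seed_start <= k + 1 <= params.seed_end else 0
                consider(s1 + gcost + s2, m1 + m2 + gmm, M)
        for k in range(1, M - L):  # miRNA bulge at positions k+1..k+L
            for q in range(0, N - (M - L) + 1):
                s1, m1 = run_pairs(q, 0, k, 0)
                s2, m2 = run_pairs(q, k + L, M, -L)
                gcost = params.gap_open * w(k + 1) + sum(
                    params.gap_extend * w(k + 1 + j) for j in range(1, L)
                )
                gmm = sum(1 for j in range(1, L + 1) if params.seed_start <= k + j <= params.seed_end)
                consider(s1 + gcost + s2, m1 + m2 + gmm, M - L)
    return best


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        e, mm, trace = score_duplex(MIR, PERFECT, P)
        assert e == 0.0 and mm == 0
        assert trace == [0.0] * 21

    def test_single_gu_outside_seed(self):
        t = list(PERFECT)
        t[14] = "U"  # miRNA G15 : target U -> wobble, unweighted
        e, mm, _ = score_duplex(MIR, "".join(t), P)
        assert e == pytest.approx(0.5)
        assert mm == 0

    def test_single_seed_mismatch_weighted(self):
        t = list(PERFECT)
        t[4] = MIR[4]  # A:A at position 5 (seed)
        e, mm, _ = score_duplex(MIR, "".join(t), P)
        assert e == pytest.approx(1.5)
        assert mm == 1

    def test_two_seed_mismatches_exceed_max_expectation(self):
        t = list(PERFECT)
        t[4] = MIR[4]
        t[7] = MIR[7]
        e, mm, _ = score_duplex(MIR, "".join(t), P)
        assert e == pytest.approx(3.0)
        assert mm == 2  # scored, but scan would never emit it

    def test_one_nt_bulge_outside_seed_costs_gap_open(self):
        mir = MIR[:15] + "-" + MIR[15:]
        tgt = PERFECT[:15] + "A" + PERFECT[15:]
        e, mm, _ = score_duplex(mir, tgt, P)
        assert e == pytest.approx(2.0)
        assert mm == 0

    def test_gap_extension_in_a_run(self):
        mir = MIR[:15] + "--" + MIR[15:]
        tgt = PERFECT[:15] + "AA" + PERFECT[15:]
        e, _, _ = score_duplex(mir, tgt, P)
        assert e == pytest.approx(2.5)  # open 2 + extend 0.5, outside seed

    def test_t_and_u_are_interchangeable(self):
        e1, _, _ = score_duplex(MIR.replace("U", "T"), PERFECT.replace("U", "T"), P)
        assert e1 == 0.0

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            score_duplex("AXG", "UAC", P)

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("---", "AAA", P)


class TestScanTargets:
    def test_embedded_perfect_site_found_exactly_once(self):
        rng = np.random.default_rng(1)
        mir = random_mirna(rng)[1]
        site = reverse_complement(mir)
        flank = lambda n: "".join(rng.choice(list("ACGU"), size=n))
        tx = flank(40) + site + flank(40)
        hits = scan_targets([("m", mir)], [("t", tx)], P)
        # resolution keeps only the perfect placement among overlaps
        perfect_hits = [h for h in hits if h.target_start == 41]
        assert len(perfect_hits) == 1
        h = perfect_hits[0]
        assert h.expectation == 0.0
        assert (h.target_start, h.target_end) == (41, 40 + len(mir))
        assert "\n" in h.alignment and "|" * len(mir) in h.alignment

    def test_boundary_expectation_exactly_two_is_emitted(self):
        rng = derive_rng(3, "boundary")
        mir = random_mirna(rng)
        recs, truth = simulate_transcripts_with_sites(
            mir, SiteSpec(sites_per_class={"bulge": 1}, n_transcripts=1), rng
        )
        hits = scan_targets([mir], recs, P)
        assert len(hits) == 1
        assert hits[0].expectation == pytest.approx(2.0)
        assert hits[0].gaps == 1

    def test_synthetic_truth_recovered(self):
        rng = derive_rng(11, "truth")
        mir = random_mirna(rng)
        recs, truth = simulate_transcripts_with_sites(mir, SiteSpec(), rng)
        hits = scan_targets([mir], recs, P)
        planted = truth.dropna(subset=["expected_expectation"])
        assert len(hits) == len(planted)
        by_tx = {h.transcript_id: h for h in hits}
        for _, row in planted.iterrows():
            h = by_tx[row.transcript]
            assert h.expectation == pytest.approx(row.expected_expectation)
            assert h.target_start <= row.end and h.target_end >= row.start
        decoy_tx = set(truth[truth.expected_expectation.isna()].transcript)
        assert not decoy_tx & {h.transcript_id for h in hits if h.transcript_id not in by_tx}

    @pytest.mark.parametrize("n_mut", [0, 1, 2, 3])
    def test_toy_transcripts_agree_with_brute_force_oracle(self, n_mut):
        # <=30-nt toys built from a perfect site with 0-3 point mutations
        rng = np.random.default_rng(100 + n_mut)
        for trial in range(8):
            mir = random_mirna(rng)[1]
            site = list(reverse_complement(mir))
            for i in rng.choice(len(site), size=n_mut, replace=False):
                site[int(i)] = str(rng.choice(list("ACGU")))
            pad = 30 - len(site)
            tx = "".join(rng.choice(list("ACGU"), size=pad // 2)) + "".join(site)
            tx += "".join(rng.choice(list("ACGU"), size=30 - len(tx)))
            oracle = brute_force_min_expectation(mir, tx, P)
            hits = scan_targets([("m", mir)], [("t", tx)], P)
            scanner = min((h.expectation for h in hits), default=None)
            if oracle is None:
                assert scanner is None
            else:
                assert scanner == pytest.approx(oracle)

    def test_mutating_an_emitted_site_never_lowers_expectation(self):
        rng = np.random.default_rng(42)
        mir = random_mirna(rng)[1]
        site = reverse_complement(mir)
        flanks = "".join(rng.choice(list("ACGU"), size=40))
        base_tx = flanks[:20] + site + flanks[20:]
        base = min(h.expectation for h in scan_targets([("m", mir)], [("t", base_tx)], P))
        for i in range(20, 20 + len(site), 3):
            mutated = base_tx[:i] + ("A" if base_tx[i] != "A" else "G") + base_tx[i + 1 :]
            hits = scan_targets([("m", mir)], [("t", mutated)], P)
            worst = min((h.expectation for h in hits), default=float("inf"))
            assert worst >= base

    def test_deterministic_hit_order(self):
        rng = derive_rng(5, "det")
        mir = random_mirna(rng)
        recs, _ = simulate_transcripts_with_sites(mir, SiteSpec(), rng)
        h1 = scan_targets([mir], recs, P)
        h2 = scan_targets([mir], recs, P)
        assert h1 == h2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="no miRNA"):
            scan_targets([], [("t", "ACGU" * 10)], P)
        with pytest.raises(ValueError, match="no transcript"):
            scan_targets([("m", "A" * 21)], [], P)

    def test_mirna_shorter_than_hsp_rejected(self):
        with pytest.raises(ValueError, match="hsp_size"):
            scan_targets([("m", "ACGUACGUACGU")], [("t", "ACGU" * 20)], P)

    def test_best_per_transcript_keeps_minimum(self):
        rng = np.random.default_rng(7)
        mir = random_mirna(rng)[1]
        perfect = reverse_complement(mir)
        degraded = list(perfect)
        degraded[len(degraded) - 5] = mir[4]  # one seed mismatch
        spacer = "".join(rng.choice(list("ACGU"), size=15))
        tx = spacer + perfect + spacer + "".join(degraded) + spacer
        all_hits = scan_targets([("m", mir)], [("t", tx)], P)
        best = scan_targets([("m", mir)], [("t", tx)], P, best_per_transcript=True)
        assert len(all_hits) >= 2
        assert len(best) == 1 and best[0].expectation == 0.0
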