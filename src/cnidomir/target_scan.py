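"""Plant-style miRNA target-site scanning by weighted complementarity.

A miRNA is aligned antiparallel against every candidate window of a
transcript and the duplex is scored with a cumulative *expectation*
penalty: Watson-Crick pairs are free, G:U wobbles cost 0.5, other
mismatches 1, gaps 2 to open and 0.5 to extend, and every penalty
falling in the seed region (miRNA positions 2-13, 5'->3', 1-based) is
multiplied by 1.5. Sites are reported when the expectation is at most
the maximum (2 by default, boundary inclusive), the seed region holds
at most 2 mismatches (G:U counts as a mismatch for this cap), and the
aligned complementary span reaches the minimum HSP size (19 nt).

The alignment search is a bounded dynamic program over each window:
optimal placement among the ungapped alignment and all single-run
gapped alignments with at most ``max_gaps`` total gap positions, with
gaps forbidden opposite the first and last miRNA positions (standard
duplex geometry). This is a precise, self-contained re-specification
of the scoring contract implied by the parameter set of web-based
plant-target predictors; bit-compatibility with any web service is not
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["ScanParams", "DuplexHit", "score_duplex", "scan_targets", "reverse_complement"]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_PAD = 5  # sentinel beyond transcript ends
_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

# penalty lookup, rows = miRNA base, cols = target base (both 5'->3'
# symbols; pairing is antiparallel so complementarity is checked
# directly between the symbols)
_PAIR_PENALTY = np.ones((6, 6))
_MISMATCH = np.ones((6, 6), dtype=np.int64)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_PENALTY[_CODE[_m], _CODE[_t]] = 0.0
    _MISMATCH[_CODE[_m], _CODE[_t]] = 0
for _m, _t in (("G", "U"), ("U", "G")):
    _PAIR_PENALTY[_CODE[_m], _CODE[_t]] = 0.5  # overwritten by gu_penalty at runtime
_PAIR_PENALTY[_PAD, :] = np.inf
_PAIR_PENALTY[:, _PAD] = np.inf

_EPS = 1e-9


def reverse_complement(seq: str) -> str:
    seq = normalize_rna(seq)
    return "".join(_RNA_COMPLEMENT[c] for c in reversed(seq))


def normalize_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal sequence character(s): {''.join(sorted(bad))!r}")
    return seq


@dataclass(frozen=True)
class ScanParams:
    """Scoring configuration for the complementarity scanner.

    Defaults are the published plant-style parameterization: maximum
    expectation 2, G:U penalty 0.5, seed extra weight 1.5, at most 2
    seed mismatches, other mismatches 1, gap open 2, gap extend 0.5,
    HSP size 19, seed region miRNA positions 2-13.
    """

    max_expectation: float = 2.0
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    seed_weight: float = 1.5
    max_seed_mismatches: int = 2
    gap_open: float = 2.0
    gap_extend: float = 0.5
    hsp_size: int = 19
    seed_start: int = 2
    seed_end: int = 13
    max_gaps: int = 2

    def __post_init__(self) -> None:
        if self.seed_start < 1 or self.seed_end < self.seed_start:
            raise ValueError("require 1 <= seed_start <= seed_end")
        for name in ("gu_penalty", "mismatch_penalty", "gap_open", "gap_extend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_expectation < 0 or self.seed_weight < 0:
            raise ValueError("max_expectation and seed_weight must be >= 0")
        if self.hsp_size < 1:
            raise ValueError("hsp_size must be >= 1")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")

    def validate_mirna_length(self, length: int) -> None:
        if length < self.hsp_size:
            raise ValueError(
                f"miRNA of length {length} is shorter than hsp_size {self.hsp_size}"
            )
        if self.seed_end > length:
            raise ValueError(
                f"seed region {self.seed_start}-{self.seed_end} exceeds miRNA length {length}"
            )

    def in_seed(self, position: int) -> bool:
        """1-based miRNA position, counted 5'->3'."""
        return self.seed_start <= position <= self.seed_end

    def position_weight(self, position: int) -> float:
        return self.seed_weight if self.in_seed(position) else 1.0


@dataclass(frozen=True)
class DuplexHit:
    """One scored miRNA-target site.

    Coordinates are 1-based inclusive on the transcript (5'->3').
    ``alignment`` is the three-line duplex: miRNA printed 3'->5' on
    top, pairing row ('|' Watson-Crick, 'o' G:U, '.' mismatch, ' '
    gap), target site printed 5'->3' underneath.
    """

    mirna_id: str
    transcript_id: str
    target_start: int
    target_end: int
    expectation: float
    alignment: str
    seed_mismatches: int
    gaps: int


def _pair_penalty_table(params: ScanParams) -> np.ndarray:
    table = np.full((6, 6), params.mismatch_penalty)
    for m, t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        table[_CODE[m], _CODE[t]] = 0.0
    for m, t in (("G", "U"), ("U", "G")):
        table[_CODE[m], _CODE[t]] = params.gu_penalty
    table[_PAD, :] = np.inf
    table[:, _PAD] = np.inf
    return table


def score_duplex(
    mirna_aligned: str, target_aligned: str, params: ScanParams | None = None
) -> tuple[float, int, list[float]]:
    """Score an explicitly aligned duplex.

    Both strings must be the same length and index-aligned: the miRNA
    runs 5'->3' and the target site runs 3'->5', so column *i* of one
    pairs with column *i* of the other. ``-`` marks a gap. Returns the
    expectation penalty, the seed-mismatch count (G:U wobbles and gap
    columns in the seed count toward it), and the per-column penalty
    trace.
    """
    params = params or ScanParams()
    if len(mirna_aligned) != len(target_aligned):
        raise ValueError("aligned strings must have equal length")
    mir = mirna_aligned.upper().replace("T", "U")
    tgt = target_aligned.upper().replace("T", "U")
    for s in (mir, tgt):
        bad = set(s) - set("ACGUN-")
        if bad:
            raise ValueError(f"illegal sequence character(s): {''.join(sorted(bad))!r}")
    table = _pair_penalty_table(params)

    expectation = 0.0
    seed_mm = 0
    trace: list[float] = []
    mir_pos = 0  # 1-based position of the last consumed miRNA base
    in_gap_run = False
    n_paired = 0
    for cm, ct in zip(mir, tgt):
        if cm == "-" and ct == "-":
            raise ValueError("alignment column with gaps in both strands")
        if cm == "-" or ct == "-":
            if cm == "-":
                pos = mir_pos + 1  # target bulge: next miRNA position to align
            else:
                mir_pos += 1
                pos = mir_pos  # miRNA bulge: the unpaired miRNA position
            raw = params.gap_extend if in_gap_run else params.gap_open
            in_gap_run = True
            penalty = raw * params.position_weight(pos)
            if params.in_seed(pos):
                seed_mm += 1
        else:
            in_gap_run = False
            mir_pos += 1
            n_paired += 1
            raw = table[_CODE[cm], _CODE[ct]]
            penalty = raw * params.position_weight(mir_pos)
            if params.in_seed(mir_pos) and raw > 0:
                seed_mm += 1
        expectation += penalty
        trace.append(float(penalty))
    if n_paired == 0:
        raise ValueError("all-gap alignment")
    return float(expectation), seed_mm, trace


def _as_records(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, Mapping):
        return [(str(k), normalize_rna(str(v))) for k, v in seqs.items()]
    out = []
    for item in seqs:
        if isinstance(item, tuple):
            name, seq = item
        else:  # Biopython SeqRecord or similar
            name, seq = item.id, str(item.seq)
        out.append((str(name), normalize_rna(str(seq))))
    return out


def _candidate_arrays(m_codes: np.ndarray, rt_codes: np.ndarray, params: ScanParams):
    """All alignment placements of the miRNA against the reversed
    transcript, scored by diagonal prefix sums.

    Returns a list of candidate tuples
    (expectation, q, window_len, kind, k, L, seed_mm, gaps).
    """
    M = len(m_codes)
    N = len(rt_codes)
    table = _pair_penalty_table(params)
    weights = np.array([params.position_weight(i + 1) for i in range(M)])
    seed_mask = np.array([params.in_seed(i + 1) for i in range(M)], dtype=np.int64)

    pad = np.full(M + params.max_gaps + 1, _PAD, dtype=np.int64)
    rtp = np.concatenate([rt_codes, pad])
    Np = len(rtp)

    P = table[m_codes[:, None], rtp[None, :]] * weights[:, None]
    Mm = _MISMATCH[m_codes[:, None], rtp[None, :]] * seed_mask[:, None]

    # C[k, q] = sum_{i<k} P[i, q+i]  (prefix of the diagonal starting at q)
    C = np.zeros((M + 1, Np))
    MC = np.zeros((M + 1, Np), dtype=np.int64)
    for k in range(1, M + 1):
        n_valid = Np - (k - 1)
        C[k, :n_valid] = C[k - 1, :n_valid] + P[k - 1, k - 1 :]
        MC[k, :n_valid] = MC[k - 1, :n_valid] + Mm[k - 1, k - 1 :]

    emax = params.max_expectation + _EPS
    candidates: list[tuple] = []

    def collect(scores, seedmm, W, kind, k, L, q_lo, q_hi):
        if q_hi < q_lo:
            return
        qs = np.arange(q_lo, q_hi + 1)
        sc = scores[q_lo : q_hi + 1]
        ok = np.nonzero(sc <= emax)[0]
        for idx in ok:
            q = int(qs[idx])
            candidates.append(
                (float(sc[idx]), q, W, kind, k, L, int(seedmm[q]), L if kind != "u" else 0)
            )

    # ungapped
    if N >= M:
        collect(C[M], MC[M], M, "u", 0, 0, 0, N - M)

    max_run = min(params.max_gaps, 2)
    if params.max_gaps > 0 and M >= params.hsp_size:
        # inf-inf at pad-overlapping placements yields nan, which the
        # <= max_expectation filter discards
        with np.errstate(invalid="ignore"):
            for L in range(1, max_run + 1):
                gcost_run = params.gap_open + (L - 1) * params.gap_extend
                # target bulge: L extra target nts between miRNA positions k and k+1
                if N >= M + L:
                    for k in range(1, M):
                        wg = params.position_weight(k + 1)
                        extra_mm = L if params.in_seed(k + 1) else 0
                        scores = (
                            C[k, : N + 1]
                            + gcost_run * wg
                            + (C[M, L : N + L + 1] - C[k, L : N + L + 1])
                        )
                        seedmm = (
                            MC[k, : N + 1]
                            + (MC[M, L : N + L + 1] - MC[k, L : N + L + 1])
                            + extra_mm
                        )
                        collect(scores, seedmm, M + L, "tb", k, L, 0, N - M - L)
                # miRNA bulge: miRNA positions k+1..k+L unpaired
                if M - L >= params.hsp_size and N >= M - L:
                    for k in range(1, M - L):
                        gcost = params.gap_open * params.position_weight(k + 1) + sum(
                            params.gap_extend * params.position_weight(k + 1 + j)
                            for j in range(1, L)
                        )
                        extra_mm = sum(1 for j in range(1, L + 1) if params.in_seed(k + j))
                        q_lo, q_hi = L, N - M + L
                        qs = np.arange(q_lo, q_hi + 1)
                        scores_v = C[k, qs] + gcost + (C[M, qs - L] - C[k + L, qs - L])
                        seedmm_v = MC[k, qs] + (MC[M, qs - L] - MC[k + L, qs - L]) + extra_mm
                        full_scores = np.full(N + 1, np.inf)
                        full_seedmm = np.zeros(N + 1, dtype=np.int64)
                        full_scores[qs] = scores_v
                        full_seedmm[qs] = seedmm_v
                        collect(full_scores, full_seedmm, M - L, "mb", k, L, q_lo, q_hi)
    return candidates


def _build_alignment(mirna: str, rt_window: str, kind: str, k: int, L: int) -> tuple[str, str, str]:
    """Reconstruct the internal aligned strings (miRNA 5'->3' order)."""
    if kind == "u":
        mir_cols, tgt_cols = mirna, rt_window
    elif kind == "tb":
        mir_cols = mirna[:k] + "-" * L + mirna[k:]
        tgt_cols = rt_window
    else:  # mb
        mir_cols = mirna
        tgt_cols = rt_window[:k] + "-" * L + rt_window[k:]
    pairing = []
    for cm, ct in zip(mir_cols, tgt_cols):
        if cm == "-" or ct == "-":
            pairing.append(" ")
        elif _PAIR_PENALTY[_CODE[cm], _CODE[ct]] == 0.0 and cm != "N":
            pairing.append("|")
        elif (cm, ct) in (("G", "U"), ("U", "G")):
            pairing.append("o")
        else:
            pairing.append(".")
    return mir_cols, "".join(pairing), tgt_cols


def scan_targets(
    mirnas,
    transcripts,
    params: ScanParams | None = None,
    best_per_transcript: bool = False,
) -> list[DuplexHit]:
    """Scan transcripts for complementary sites of each miRNA.

    ``mirnas`` and ``transcripts`` may be Biopython SeqRecords,
    (id, sequence) tuples, or id->sequence mappings; T and U are
    interchangeable on input. Overlapping candidate placements are
    resolved by keeping the locally minimal-expectation placement
    (ties broken leftmost on the transcript); pass
    ``best_per_transcript=True`` to keep only the single best site per
    transcript per miRNA.
    """
    params = params or ScanParams()
    mirna_recs = _as_records(mirnas)
    transcript_recs = _as_records(transcripts)
    if not mirna_recs:
        raise ValueError("no miRNA sequences supplied")
    if not transcript_recs:
        raise ValueError("no transcript sequences supplied")
    for name, seq in mirna_recs:
        params.validate_mirna_length(len(seq))

    hits: list[DuplexHit] = []
    for mid, mseq in mirna_recs:
        m_codes = np.array([_CODE[c] for c in mseq], dtype=np.int64)
        for tid, tseq in transcript_recs:
            rt = tseq[::-1]
            rt_codes = np.array([_CODE[c] for c in rt], dtype=np.int64)
            N = len(rt_codes)
            cands = _candidate_arrays(m_codes, rt_codes, params)
            # filters: seed-mismatch cap and minimum aligned span
            cands = [
                c
                for c in cands
                if c[6] <= params.max_seed_mismatches
                and (len(mseq) - (c[5] if c[3] == "mb" else 0)) >= params.hsp_size
            ]
            # transcript coordinates (1-based inclusive)
            placed = []
            for e, q, W, kind, k, L, seedmm, gaps in cands:
                start = N - q - W + 1
                end = N - q
                placed.append((round(e, 9), start, end, q, W, kind, k, L, seedmm, gaps))
            placed.sort(key=lambda c: (c[0], c[1], c[2]))
            taken: list[tuple[int, int]] = []
            kept = []
            for cand in placed:
                s, t = cand[1], cand[2]
                if any(not (t < s0 or s > t0) for s0, t0 in taken):
                    continue
                taken.append((s, t))
                kept.append(cand)
            if best_per_transcript and kept:
                kept = [min(kept, key=lambda c: (c[0], c[1]))]
            kept.sort(key=lambda c: c[1])
            for e, start, end, q, W, kind, k, L, seedmm, gaps in kept:
                rt_window = rt[q : q + W]
                mir_cols, pairing, tgt_cols = _build_alignment(mseq, rt_window, kind, k, L)
                # display: miRNA 3'->5' on top, target 5'->3' underneath
                alignment = "\n".join(
                    [mir_cols[::-1], pairing[::-1], tgt_cols[::-1]]
                )
                hits.append(
                    DuplexHit(
                        mirna_id=mid,
                        transcript_id=tid,
                        target_start=start,
                        target_end=end,
                        expectation=float(e),
                        alignment=alignment,
                        seed_mismatches=int(seedmm),
                        gaps=int(gaps),
                    )
                )
    return hits


def hits_to_rows(hits: Sequence[DuplexHit]) -> list[dict]:
    """Flatten hits for TSV output (alignment newline-escaped)."""
    return [
        {
            "mirna": h.mirna_id,
            "transcript": h.transcript_id,
            "start": h.target_start,
            "end": h.target_end,
            "expectation": h.expectation,
            "seed_mismatches": h.seed_mismatches,
            "gaps": h.gaps,
            "alignment": h.alignment.replace("\n", "\\n"),
        }
        for h in hits
    ]
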