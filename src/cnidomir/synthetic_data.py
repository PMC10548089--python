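"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs of this analysis (morphant RNA-seq counts, a cnidocyte
gene catalogue, single-cell cluster markers, transcript FASTA, qPCR Ct
tables) live in external repositories; these generators emulate their
statistical structure so every stage is testable offline:

* negative-binomial count matrices in which a known gene subset is
  constructed to fail the counts-per-million background rule;
* gene-set pairs with an exactly planted overlap against a background,
  emulating the DEG-vs-cnidocyte-catalogue configuration;
* a 12-cluster marker catalogue with cluster-unique genes;
* transcripts carrying miRNA sites of known duplex classes (perfect,
  one non-seed G:U, one seed mismatch, one-nt bulge, rejected decoy)
  whose expectation scores are fixed by construction, in flanks
  rejection-sampled to be free of accidental sites;
* DE result-table pairs with per-gene truth categories, including
  threshold-boundary rows;
* Ct tables whose planted fold change is recovered exactly at zero
  noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneSet
from .deg_filtering import DEResultTable, GeneUniverse, cpm_filter
from .target_scan import ScanParams, scan_targets

logger = logging.getLogger("cnidomir")

__all__ = [
    "UniverseSpec",
    "EnrichmentSpec",
    "SiteSpec",
    "simulate_universe",
    "plant_enrichment",
    "simulate_marker_table",
    "DEFAULT_CLUSTER_SIZES",
    "simulate_transcripts_with_sites",
    "simulate_qpcr",
    "simulate_de_tables",
    "random_mirna",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}
_BASES = "ACGU"

# 12 clusters summing to 2,168 markers, the catalogue size the
# single-cell overlap stage consumes; clusters 1-2 (cnidocytes) carry
# the largest shares.
DEFAULT_CLUSTER_SIZES = (300, 450, 150, 200, 180, 160, 140, 130, 120, 118, 110, 110)


# ---------------------------------------------------------------------------
# count universe


@dataclass
class UniverseSpec:
    """Shape and noise of the synthetic count matrix."""

    B: int = 1000
    libraries: int = 6  # 3 control + 3 morphant
    nb_mean: float = 150.0
    nb_dispersion: float = 0.25
    zero_gene_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.libraries < 1:
            raise ValueError("libraries must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.zero_gene_fraction < 1):
            raise ValueError("zero_gene_fraction must be in [0, 1)")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    # NB parameterized by mean mu and dispersion alpha: var = mu + alpha*mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_universe(
    spec: UniverseSpec,
    rng: np.random.Generator,
    cpm_threshold: float = 1.0,
    cpm_min_libraries: int = 2,
) -> tuple[GeneUniverse, pd.DataFrame]:
    """Negative-binomial counts with a planted background truth.

    Exactly ``round(zero_gene_fraction * B)`` genes are constructed to
    fail the CPM rule (zero counts in ``cpm_min_libraries`` randomly
    chosen libraries); all other genes are floored so they pass it.
    The construction is verified against :func:`cpm_filter` before
    returning. Truth column ``in_background`` lists which genes must
    survive the filter.
    """
    if spec.B * spec.libraries > 10**8:
        raise ValueError("universe too large: B x libraries exceeds 1e8 cells")
    if cpm_min_libraries > spec.libraries:
        raise ValueError("cpm_min_libraries exceeds the number of libraries")
    genes = [f"g{i:06d}" for i in range(spec.B)]
    n_cond = spec.libraries // 2
    labels = [f"control_{i + 1}" for i in range(n_cond)] + [
        f"morphant_{i + 1}" for i in range(spec.libraries - n_cond)
    ]
    counts = _nb_draw(rng, spec.nb_mean, spec.nb_dispersion, (spec.B, spec.libraries)).astype(
        np.int64
    )

    n_fail = int(round(spec.zero_gene_fraction * spec.B))
    fail_idx = rng.choice(spec.B, size=n_fail, replace=False)
    fail_mask = np.zeros(spec.B, dtype=bool)
    fail_mask[fail_idx] = True
    # force failure: zero counts in cpm_min_libraries random libraries
    for i in fail_idx:
        libs = rng.choice(spec.libraries, size=cpm_min_libraries, replace=False)
        counts[i, libs] = 0

    # floor the keep genes so no library drops below the CPM threshold
    keep = ~fail_mask
    for _ in range(50):
        totals = counts.sum(axis=0)
        needed = np.ceil(cpm_threshold * totals * 1.05 / 1e6).astype(np.int64) + 1
        low = counts[keep] < needed[None, :]
        if not low.any():
            break
        sub = counts[keep]
        sub[low] = np.broadcast_to(needed, sub.shape)[low]
        counts[keep] = sub
    universe = GeneUniverse(genes=genes, counts=counts, library_labels=labels)
    background, _ = cpm_filter(universe, threshold=cpm_threshold, min_libraries=cpm_min_libraries)
    expected = {g for g, k in zip(genes, keep) if k}
    if background.members != frozenset(expected):
        raise RuntimeError("universe construction failed to satisfy the CPM rule")
    truth = pd.DataFrame({"gene": genes, "in_background": keep})
    return universe, truth


# ---------------------------------------------------------------------------
# planted enrichment


@dataclass
class EnrichmentSpec:
    """Sizes of the planted target/DEG sets and their overlap."""

    K: int  # planted cnidocyte-style catalogue size
    n: int  # planted DEG list size
    x_target: int  # planted overlap

    def feasible_range(self, B: int) -> tuple[int, int]:
        return max(0, self.n + self.K - B), min(self.n, self.K)

    def validate(self, B: int) -> None:
        if self.K > B or self.n > B:
            raise ValueError(f"K={self.K} and n={self.n} must not exceed B={B}")
        lo, hi = self.feasible_range(B)
        if not (lo <= self.x_target <= hi):
            raise ValueError(
                f"x_target={self.x_target} infeasible; feasible range is [{lo}, {hi}] "
                f"for B={B}, K={self.K}, n={self.n}"
            )


def plant_enrichment(
    background: GeneSet | Sequence[str],
    spec: EnrichmentSpec,
    rng: np.random.Generator,
) -> tuple[GeneSet, GeneSet, dict]:
    """Draw a target set (size K) and a query/DEG set (size n) from
    the background with |target ∩ DEG| exactly ``x_target``; membership
    is otherwise uniform at random."""
    genes = sorted(background.members) if isinstance(background, GeneSet) else list(background)
    B = len(genes)
    spec.validate(B)
    order = rng.permutation(B)
    shared = [genes[i] for i in order[: spec.x_target]]
    target_only = [genes[i] for i in order[spec.x_target : spec.K]]
    deg_only = [genes[i] for i in order[spec.K : spec.K + spec.n - spec.x_target]]
    target = GeneSet(name="planted_target", members=frozenset(shared + target_only))
    degs = GeneSet(name="planted_degs", members=frozenset(shared + deg_only))
    truth = {
        "B": B,
        "K": spec.K,
        "n": spec.n,
        "x_target": spec.x_target,
        "shared_genes": sorted(shared),
    }
    assert len(target.members & degs.members) == spec.x_target
    return target, degs, truth


# ---------------------------------------------------------------------------
# marker table


def simulate_marker_table(
    background: GeneSet | Sequence[str],
    rng: np.random.Generator,
    n_clusters: int = 12,
    sizes: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cluster-unique marker genes drawn from the background.

    Each marker gene belongs to exactly one cluster (the generator's
    convention; consumers must still tolerate duplicated genes in real
    tables). Cluster ids are the labels "1".."n_clusters".
    """
    genes = sorted(background.members) if isinstance(background, GeneSet) else list(background)
    if sizes is None:
        sizes = DEFAULT_CLUSTER_SIZES if n_clusters == 12 else None
    if sizes is None:
        raise ValueError("sizes must be given when n_clusters != 12")
    if len(sizes) != n_clusters:
        raise ValueError(f"{len(sizes)} sizes given for {n_clusters} clusters")
    if any(s < 0 for s in sizes):
        raise ValueError("cluster sizes must be non-negative")
    total = int(sum(sizes))
    if total > len(genes):
        raise ValueError(
            f"requested {total} marker genes but the background holds only {len(genes)}"
        )
    order = rng.permutation(len(genes))
    rows = []
    pos = 0
    truth: dict[str, list[str]] = {}
    for c, size in enumerate(sizes, start=1):
        members = [genes[i] for i in order[pos : pos + size]]
        pos += size
        truth[str(c)] = sorted(members)
        rows.extend({"gene": g, "cluster": str(c)} for g in members)
    table = pd.DataFrame(rows, columns=["gene", "cluster"])
    return table, truth


# ---------------------------------------------------------------------------
# transcripts with planted miRNA sites

SITE_CLASSES = ("perfect", "gu", "seed_mismatch", "bulge", "decoy")
_CLASS_SCORE = {"perfect": 0.0, "gu": 0.5, "seed_mismatch": 1.5, "bulge": 2.0}


@dataclass
class SiteSpec:
    """How many transcripts and which duplex classes to plant."""

    n_transcripts: int = 5
    transcript_length: int = 240
    sites_per_class: dict = field(
        default_factory=lambda: {c: 1 for c in SITE_CLASSES}
    )
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        unknown = set(self.sites_per_class) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site class(es): {sorted(unknown)}")


def random_mirna(
    rng: np.random.Generator,
    length: int = 21,
    name: str = "synthetic-mir",
    params: ScanParams | None = None,
) -> tuple[str, str]:
    """A synthetic mature miRNA (the real sequence is not required by
    any stage; the scanner is sequence-agnostic).

    Resampled until the sequence carries a G or U at a non-terminal
    position outside the seed, so every plantable site class
    (including the G:U wobble class) is constructible.
    """
    params = params or ScanParams()
    for _ in range(1000):
        seq = "".join(rng.choice(list(_BASES), size=length))
        if any(
            seq[i] in _WOBBLE and not params.in_seed(i + 1)
            for i in range(1, length - 1)
        ):
            return name, seq
    raise RuntimeError("failed to draw a wobble-compatible miRNA")  # pragma: no cover


def _pairs_with(base: str, other: str) -> bool:
    return _COMPLEMENT[base] == other or _WOBBLE.get(base) == other


def _perfect_rt_window(mirna: str) -> list[str]:
    # rt window: target read 3'->5', index-aligned with the miRNA 5'->3'
    return [_COMPLEMENT[c] for c in mirna]


def _site_for_class(
    mirna: str, site_class: str, params: ScanParams, rng: np.random.Generator
) -> tuple[str, float | None]:
    """Target site sequence (5'->3') for one duplex class."""
    M = len(mirna)
    rt = _perfect_rt_window(mirna)
    if site_class == "perfect":
        pass
    elif site_class == "gu":
        candidates = [
            i
            for i in range(1, M - 1)
            if not params.in_seed(i + 1) and mirna[i] in _WOBBLE
        ]
        if not candidates:
            raise ValueError("miRNA has no non-seed G/U position for a G:U site")
        i = int(rng.choice(candidates))
        rt[i] = _WOBBLE[mirna[i]]
    elif site_class == "seed_mismatch":
        seed_positions = [i for i in range(M) if params.in_seed(i + 1)]
        i = int(rng.choice(seed_positions))
        rt[i] = mirna[i]  # self-pairing is never Watson-Crick nor G:U
    elif site_class == "decoy":
        seed_positions = [i for i in range(M) if params.in_seed(i + 1)]
        for i in rng.choice(seed_positions, size=3, replace=False):
            rt[int(i)] = mirna[int(i)]
    elif site_class == "bulge":
        # one extra target nt between miRNA positions k and k+1, outside
        # the seed, pairing with neither neighbour
        for k in range(max(params.seed_end, 1), M - 1):
            avoid = {
                b
                for b in _BASES
                if _pairs_with(mirna[k - 1], b) or _pairs_with(mirna[k], b)
            }
            choices = [b for b in _BASES if b not in avoid]
            if choices:
                x = str(rng.choice(choices))
                rt = rt[:k] + [x] + rt[k:]
                break
        else:
            raise ValueError("no feasible bulge position outside the seed")
    else:
        raise ValueError(f"unknown site class {site_class!r}")
    site = "".join(reversed(rt))  # transcript orientation, 5'->3'
    return site, _CLASS_SCORE.get(site_class)


def simulate_transcripts_with_sites(
    mirna: tuple[str, str],
    spec: SiteSpec,
    rng: np.random.Generator,
    params: ScanParams | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Transcripts carrying planted miRNA sites of known classes.

    Sites are distributed round-robin over the transcripts and
    separated by random flanks; flanks are rejection-sampled (up to
    ``max_attempts`` per transcript, then an error) so the scanner
    finds exactly the planted non-decoy sites and nothing else. The
    truth table records, per planted site, transcript, 1-based
    coordinates, class, and the expectation score the scanner must
    report (NaN for decoys, which must not be reported at all).
    """
    params = params or ScanParams()
    mid, mseq = mirna
    mseq = mseq.upper().replace("T", "U")
    if not (19 <= len(mseq) <= 24):
        raise ValueError(f"miRNA length {len(mseq)} outside 19-24 nt")
    params.validate_mirna_length(len(mseq))

    queue = [c for c in SITE_CLASSES for _ in range(int(spec.sites_per_class.get(c, 0)))]
    per_transcript: list[list[str]] = [[] for _ in range(spec.n_transcripts)]
    for i, site_class in enumerate(queue):
        per_transcript[i % spec.n_transcripts].append(site_class)

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for t_idx, classes in enumerate(per_transcript):
        tid = f"tx{t_idx + 1:03d}"
        sites = [_site_for_class(mseq, c, params, rng) for c in classes]
        total_site_len = sum(len(s) for s, _ in sites)
        min_len = total_site_len + 2 * (len(classes) + 1)
        if spec.transcript_length < min_len:
            raise ValueError(
                f"transcript length {spec.transcript_length} too short for "
                f"{len(classes)} site(s); need >= {min_len}"
            )
        for attempt in range(spec.max_attempts):
            seq, rows = _assemble_transcript(tid, classes, sites, spec.transcript_length, rng)
            if _flanks_clean(mid, mseq, tid, seq, rows, params):
                records.append((tid, seq))
                truth_rows.extend(rows)
                break
        else:
            raise RuntimeError(
                f"{tid}: no accidental-site-free flank found in {spec.max_attempts} attempts"
            )
    truth = pd.DataFrame(
        truth_rows, columns=["transcript", "site_class", "start", "end", "expected_expectation"]
    )
    return records, truth


def _assemble_transcript(
    tid: str,
    classes: list[str],
    sites: list[tuple[str, float | None]],
    length: int,
    rng: np.random.Generator,
) -> tuple[str, list[dict]]:
    n_gaps = len(sites) + 1
    flank_total = length - sum(len(s) for s, _ in sites)
    # at least 2 nt between/around sites so placements cannot merge
    cuts = rng.multinomial(flank_total - 2 * n_gaps, np.ones(n_gaps) / n_gaps) + 2
    parts: list[str] = []
    rows: list[dict] = []
    pos = 0
    for i, ((site, score), site_class) in enumerate(zip(sites, classes)):
        flank = "".join(rng.choice(list(_BASES), size=cuts[i]))
        parts.append(flank)
        pos += len(flank)
        parts.append(site)
        rows.append(
            {
                "transcript": tid,
                "site_class": site_class,
                "start": pos + 1,
                "end": pos + len(site),
                "expected_expectation": score if score is not None else float("nan"),
            }
        )
        pos += len(site)
    parts.append("".join(rng.choice(list(_BASES), size=cuts[-1])))
    return "".join(parts), rows


def _flanks_clean(
    mid: str,
    mseq: str,
    tid: str,
    seq: str,
    rows: list[dict],
    params: ScanParams,
) -> bool:
    """True iff the scanner reports exactly the planted non-decoy sites
    at their class scores and nothing in the flanks or decoys."""
    hits = scan_targets([(mid, mseq)], [(tid, seq)], params)
    expected = [r for r in rows if not math.isnan(r["expected_expectation"])]
    if len(hits) != len(expected):
        return False
    used = set()
    for hit in hits:
        matched = False
        for i, r in enumerate(expected):
            if i in used:
                continue
            if hit.target_start <= r["end"] and hit.target_end >= r["start"]:
                if abs(hit.expectation - r["expected_expectation"]) > 1e-9:
                    return False
                used.add(i)
                matched = True
                break
        if not matched:
            return False
    return len(used) == len(expected)


# ---------------------------------------------------------------------------
# DE result tables with planted truth


def simulate_de_tables(
    background: GeneSet | Sequence[str],
    rng: np.random.Generator,
    n_degs: int = 60,
    frac_down: float = 0.85,
    fdr: float = 0.05,
    fc: float = 2.0,
    methods: tuple[str, str] = ("deseq2", "edger"),
) -> tuple[list[DEResultTable], pd.DataFrame]:
    """Two DE result tables in which a planted subset — and only it —
    passes the intersection DEG rule.

    Non-DEG genes are spread over failure categories, including
    threshold-boundary rows: ``boundary_fdr`` sits exactly AT the FDR
    cutoff (excluded, the comparison being strict) and part of the
    planted DEGs sit exactly AT |log2fc| = log2(fc) (included, the
    comparison being inclusive). ``discordant`` genes pass both
    thresholds with opposite signs and must be excluded.
    """
    genes = sorted(background.members) if isinstance(background, GeneSet) else list(background)
    B = len(genes)
    log2_cut = math.log2(fc)
    categories = ["sig_only", "fc_only", "one_method_only", "discordant", "boundary_fdr", "missing"]
    n_special = min(len(categories) * 3, max(0, B - n_degs))
    if n_degs + n_special > B:
        raise ValueError(f"background of {B} genes too small for {n_degs} DEGs")
    order = [genes[i] for i in rng.permutation(B)]
    deg_genes = order[:n_degs]
    special = order[n_degs : n_degs + n_special]
    null_genes = order[n_degs + n_special :]

    down = rng.random(n_degs) < frac_down
    truth_rows = []
    table_rows: dict[str, list[dict]] = {m: [] for m in methods}

    def pass_padj() -> float:
        return float(rng.uniform(1e-4, 0.8 * fdr))

    def fail_padj() -> float:
        return float(rng.uniform(1.5 * fdr, 1.0))

    def pass_l2fc(sign: float, at_boundary: bool = False) -> float:
        return sign * (log2_cut if at_boundary else float(rng.uniform(log2_cut + 0.1, 4.0)))

    def fail_l2fc() -> float:
        return float(rng.uniform(-0.9, 0.9) * log2_cut)

    for i, g in enumerate(deg_genes):
        sign = -1.0 if down[i] else 1.0
        at_boundary = i < max(1, n_degs // 10)  # some DEGs exactly at |log2fc| = log2(fc)
        for m in methods:
            table_rows[m].append(
                {"gene": g, "log2fc": pass_l2fc(sign, at_boundary), "padj": pass_padj()}
            )
        truth_rows.append(
            {"gene": g, "category": "deg", "is_deg": True, "direction": "down" if down[i] else "up"}
        )

    for j, g in enumerate(special):
        cat = categories[j % len(categories)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if cat == "sig_only":
            rows = {m: {"log2fc": fail_l2fc(), "padj": pass_padj()} for m in methods}
        elif cat == "fc_only":
            rows = {m: {"log2fc": pass_l2fc(sign), "padj": fail_padj()} for m in methods}
        elif cat == "one_method_only":
            rows = {
                methods[0]: {"log2fc": pass_l2fc(sign), "padj": pass_padj()},
                methods[1]: {"log2fc": fail_l2fc(), "padj": fail_padj()},
            }
        elif cat == "discordant":
            rows = {
                methods[0]: {"log2fc": pass_l2fc(1.0), "padj": pass_padj()},
                methods[1]: {"log2fc": pass_l2fc(-1.0), "padj": pass_padj()},
            }
        elif cat == "boundary_fdr":
            rows = {m: {"log2fc": pass_l2fc(sign), "padj": fdr} for m in methods}
        else:  # missing from the second table
            rows = {methods[0]: {"log2fc": pass_l2fc(sign), "padj": pass_padj()}}
        for m, r in rows.items():
            table_rows[m].append({"gene": g, **r})
        truth_rows.append({"gene": g, "category": cat, "is_deg": False, "direction": None})

    for g in null_genes:
        for m in methods:
            table_rows[m].append({"gene": g, "log2fc": fail_l2fc(), "padj": fail_padj()})
        truth_rows.append({"gene": g, "category": "null", "is_deg": False, "direction": None})

    tables = []
    for m in methods:
        df = pd.DataFrame(table_rows[m]).set_index("gene")
        df["pvalue"] = df["padj"] * rng.uniform(0.1, 1.0, size=len(df))
        tables.append(DEResultTable(method=m, table=df[["log2fc", "pvalue", "padj"]]))
    truth = pd.DataFrame(truth_rows)
    return tables, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    effect: float,
    noise_sd: float,
    rng: np.random.Generator,
    replicates: int = 3,
    tech_replicates: int = 2,
    target_gene: str = "mir-target",
    reference_gene: str = "5sRNA",
    base_reference_ct: float = 15.0,
    base_delta_ct: float = 7.0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table for one target and one reference gene, control vs
    treatment, with a planted treatment/control fold change.

    At ``noise_sd = 0`` the 2^-ddCt analysis recovers ``effect``
    exactly in every treatment replicate.
    """
    if effect <= 0:
        raise ValueError("effect (fold change) must be > 0")
    if replicates < 2:
        raise ValueError("need >= 2 biological replicates (no variance estimate otherwise)")
    if tech_replicates < 1:
        raise ValueError("need >= 1 technical replicate")
    ddct_shift = -math.log2(effect)
    rows = []
    for condition in ("control", "treatment"):
        for rep in range(1, replicates + 1):
            sample = f"{condition}_{rep}"
            for gene in (reference_gene, target_gene):
                base = base_reference_ct
                if gene == target_gene:
                    base += base_delta_ct + (ddct_shift if condition == "treatment" else 0.0)
                for tech in range(1, tech_replicates + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "condition": condition,
                            "gene": gene,
                            "bio_rep": rep,
                            "tech_rep": tech,
                            "ct": base + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else base,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "effect": effect,
        "target_gene": target_gene,
        "reference_gene": reference_gene,
        "noise_sd": noise_sd,
        "replicates": replicates,
    }
    return table, truth
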