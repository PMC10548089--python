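"""Permutation set-overlap enrichment with a hypergeometric oracle.

The question: is the overlap between a query gene list (e.g., the
morphant DEGs) and a fixed target catalogue (e.g., genes enriched in
cnidocytes) larger than expected for a random list of the same size
drawn from the background universe? Each permutation replicate samples
``n`` genes uniformly WITHOUT replacement from the background and
records the overlap with the target; the empirical p-value is the
fraction of replicates at least as extreme as the observed overlap.

Because uniform sampling without replacement makes the null overlap
exactly hypergeometric, the closed-form tail P[X >= x] with
X ~ Hypergeom(B, K, n) is computed alongside as an oracle; the two
must agree up to Monte-Carlo error, and tests enforce this.

Both the raw empirical p (the convention under which a never-exceeded
observation prints "p = 0") and the pseudocount version
(#{null >= x} + 1) / (R + 1) are reported; the latter is recommended,
since a true permutation p-value cannot be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSet

logger = logging.getLogger("cnidomir")

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "observed_overlap",
    "sample_null_overlaps",
    "permutation_overlap_test",
    "hypergeometric_tail",
    "hypergeometric_mean",
    "null_histogram",
    "plot_null_histogram",
]


@dataclass
class PermutationConfig:
    """Replicates, randomness and sidedness of the permutation test."""

    R: int = 10_000
    seed: int = 0
    alternative: str = "greater"
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.alternative not in ("greater", "less"):
            raise ValueError("alternative must be 'greater' or 'less'")

    def generator(self) -> np.random.Generator:
        return self.rng if self.rng is not None else np.random.default_rng(self.seed)


@dataclass
class PermutationResult:
    """Observed overlap, the permutation null, and summaries."""

    observed_overlap: int
    null_overlaps: np.ndarray
    n: int  # query size actually tested (after background intersection)
    K: int  # target size within the background
    B: int  # background size
    alternative: str = "greater"
    n_dropped_query: int = 0

    @property
    def R(self) -> int:
        return len(self.null_overlaps)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_overlaps))

    @property
    def null_max(self) -> int:
        return int(np.max(self.null_overlaps))

    @property
    def p_raw(self) -> float:
        return float(np.mean(self._extreme()))

    @property
    def p_pseudo(self) -> float:
        return (int(np.sum(self._extreme())) + 1) / (self.R + 1)

    def _extreme(self) -> np.ndarray:
        if self.alternative == "greater":
            return self.null_overlaps >= self.observed_overlap
        return self.null_overlaps <= self.observed_overlap

    @property
    def hypergeometric_p(self) -> float:
        if self.alternative == "greater":
            return hypergeometric_tail(self.observed_overlap, self.n, self.K, self.B)
        return float(stats.hypergeom.cdf(self.observed_overlap, self.B, self.K, self.n))

    def to_dict(self) -> dict:
        return {
            "observed_overlap": self.observed_overlap,
            "n": self.n,
            "K": self.K,
            "B": self.B,
            "R": self.R,
            "alternative": self.alternative,
            "n_dropped_query": self.n_dropped_query,
            "null_mean": self.null_mean,
            "null_max": self.null_max,
            "expected_overlap": hypergeometric_mean(self.n, self.K, self.B),
            "p_raw": self.p_raw,
            "p_pseudo": self.p_pseudo,
            "hypergeometric_p": self.hypergeometric_p,
        }


def observed_overlap(query: GeneSet | set, target: GeneSet | set) -> int:
    """|query ∩ target|."""
    q = query.members if isinstance(query, GeneSet) else frozenset(query)
    t = target.members if isinstance(target, GeneSet) else frozenset(target)
    return len(q & t)


def sample_null_overlaps(
    B: int, K: int, n: int, R: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw R permutation-null overlaps: sample n of B genes without
    replacement and count how many fall in a fixed K-gene target.

    Implemented by row-wise permutation of a 0/1 target-membership
    indicator (exchangeability makes gene identities irrelevant);
    chunked so memory stays bounded for large backgrounds.
    """
    if not (0 <= K <= B):
        raise ValueError("require 0 <= K <= B")
    if not (0 <= n <= B):
        raise ValueError(f"query size n={n} exceeds background size B={B}")
    if R < 1:
        raise ValueError("R must be >= 1")
    if n == 0 or K == 0:
        return np.zeros(R, dtype=np.int64)
    indicator = np.zeros(B, dtype=np.uint8)
    indicator[:K] = 1
    out = np.empty(R, dtype=np.int64)
    chunk = max(1, min(R, int(5e6) // max(B, 1)))
    done = 0
    while done < R:
        r = min(chunk, R - done)
        block = np.tile(indicator, (r, 1))
        rng.permuted(block, axis=1, out=block)
        out[done : done + r] = block[:, :n].sum(axis=1)
        done += r
    return out


def permutation_overlap_test(
    query: GeneSet,
    target: GeneSet,
    background: GeneSet,
    cfg: PermutationConfig | None = None,
) -> PermutationResult:
    """The permutation overlap test.

    Query genes outside the background are dropped with a warning (n
    adjusted accordingly); the target is intersected with the
    background. The observed query is not injected into the null
    ensemble.
    """
    cfg = cfg or PermutationConfig()
    bg = background.members if isinstance(background, GeneSet) else frozenset(background)
    q_all = query.members if isinstance(query, GeneSet) else frozenset(query)
    t_all = target.members if isinstance(target, GeneSet) else frozenset(target)

    q = q_all & bg
    dropped = len(q_all) - len(q)
    if dropped:
        logger.warning(
            "permutation_overlap_test: dropped %d query gene(s) outside the background",
            dropped,
        )
    t = t_all & bg
    if not t:
        raise ValueError("target is empty after intersection with the background")
    B, K, n = len(bg), len(t), len(q)
    if n > B:
        raise ValueError(f"query size {n} exceeds background size {B}")
    x = len(q & t)
    null = sample_null_overlaps(B, K, n, cfg.R, cfg.generator())
    return PermutationResult(
        observed_overlap=x,
        null_overlaps=null,
        n=n,
        K=K,
        B=B,
        alternative=cfg.alternative,
        n_dropped_query=dropped,
    )


def hypergeometric_tail(x: int, n: int, K: int, B: int) -> float:
    """P[X >= x] for X ~ Hypergeom(B, K, n), stable for B up to 1e6.

    Infeasible x resolves to 0 or 1 by convention (logged).
    """
    if not (0 <= K <= B and 0 <= n <= B):
        raise ValueError("require 0 <= K <= B and 0 <= n <= B")
    lo = max(0, n + K - B)
    hi = min(n, K)
    if x <= lo:
        if x < lo:
            logger.info("hypergeometric_tail: x=%d below support [%d, %d] -> 1", x, lo, hi)
        return 1.0
    if x > hi:
        logger.info("hypergeometric_tail: x=%d above support [%d, %d] -> 0", x, lo, hi)
        return 0.0
    return float(stats.hypergeom.sf(x - 1, B, K, n))


def hypergeometric_mean(n: int, K: int, B: int) -> float:
    """Expected overlap n*K/B."""
    if B == 0:
        raise ValueError("background size B must be positive")
    return n * K / B


def null_total_variation_sweep(
    B: int, R: int, rng: np.random.Generator
) -> dict[tuple[int, int], float]:
    """Total-variation distance between the permutation null and the
    exact hypergeometric pmf, for every feasible (K, n) of a size-B
    background.

    All (K, n) pairs share one R-replicate permutation ensemble per
    background size (each replicate is a full random permutation of
    the background, so its first n elements are a uniform
    without-replacement sample for every n at once), which keeps a
    full small-universe validation sweep affordable.
    """
    perms = np.tile(np.arange(B, dtype=np.int64), (R, 1))
    rng.permuted(perms, axis=1, out=perms)
    out: dict[tuple[int, int], float] = {}
    xs = np.arange(B + 1)
    for K in range(B + 1):
        in_target = np.cumsum(perms < K, axis=1)  # overlap after n draws, all n
        for n in range(B + 1):
            overlaps = in_target[:, n - 1] if n > 0 else np.zeros(R, dtype=np.int64)
            emp = np.bincount(overlaps, minlength=B + 1) / R
            exact = stats.hypergeom.pmf(xs, B, K, n)
            out[(K, n)] = 0.5 * float(np.abs(emp - exact).sum())
    return out


def null_histogram(result: PermutationResult) -> pd.DataFrame:
    """Integer-binned null frequencies with the observed overlap marked
    (the frequency-curve view of the figures; no smoothing)."""
    values, counts = np.unique(result.null_overlaps, return_counts=True)
    df = pd.DataFrame({"overlap": values.astype(int), "frequency": counts.astype(int)})
    df["is_observed"] = df["overlap"] == result.observed_overlap
    return df


def plot_null_histogram(result: PermutationResult, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = null_histogram(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(hist["overlap"], hist["frequency"], color="black", lw=1.5)
    ax.axvline(result.null_mean, color="black", ls="--", lw=1, label=f"null mean {result.null_mean:.2f}")
    ax.axvline(result.observed_overlap, color="red", lw=1.5, label=f"observed {result.observed_overlap}")
    ax.set_xlabel("overlapping genes per random list")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
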