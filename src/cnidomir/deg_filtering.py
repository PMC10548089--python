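"""Background construction and DEG calling.

The background gene universe is the set of genes that pass a
counts-per-million filter on the raw count matrix: a gene is removed
iff its CPM falls below the threshold (1 by default) in at least
``min_libraries`` libraries (2 by default), pooled across conditions.
DEGs are the intersection of two differential-expression method
outputs: a gene is differentially expressed iff every method reports
adjusted p < 0.05 (strict) and |log2 fold change| >= 1 (i.e., linear
fold change >= 2, inclusive, two-sided) with concordant direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSet

logger = logging.getLogger("cnidomir")

__all__ = [
    "GeneUniverse",
    "DEResultTable",
    "cpm",
    "cpm_filter",
    "benjamini_hochberg",
    "call_degs",
    "read_de_table",
]


@dataclass
class GeneUniverse:
    """A count matrix (genes x libraries) with condition labels."""

    genes: list[str]
    counts: np.ndarray
    library_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x libraries matrix")
        if len(self.genes) != self.counts.shape[0]:
            raise ValueError("gene list length does not match count rows")
        if len(self.library_labels) != self.counts.shape[1]:
            raise ValueError("library labels do not match count columns")
        if self.counts.shape[1] < 1:
            raise ValueError("at least one library is required")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in universe")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.library_labels)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneUniverse":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            counts=df.to_numpy(),
            library_labels=[str(c) for c in df.columns],
        )

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class DEResultTable:
    """Per-gene effect size and significance from one DE method."""

    method: str
    table: pd.DataFrame  # index: gene; columns: log2fc, pvalue, padj

    def __post_init__(self) -> None:
        required = {"log2fc", "pvalue", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table {self.method!r} missing column(s) {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError(f"DE table {self.method!r} has duplicate gene rows")
        for col in ("pvalue", "padj"):
            vals = self.table[col]
            bad = vals.dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise ValueError(f"DE table {self.method!r}: {col} outside [0, 1]")


def read_de_table(path: str | Path, method: str) -> DEResultTable:
    """Read a DE result TSV (columns gene, log2fc|fc, pvalue, padj).

    If the table carries a linear ``fc`` column instead of ``log2fc``
    the values are log2-transformed; the choice is logged.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "gene" not in df.columns:
        raise ValueError(f"{path}: missing 'gene' column")
    df = df.set_index("gene")
    if "log2fc" not in df.columns:
        if "fc" in df.columns:
            logger.info("%s: converting linear 'fc' column to log2fc", path)
            df["log2fc"] = np.log2(df["fc"].astype(float))
        else:
            raise ValueError(f"{path}: need a 'log2fc' or 'fc' column")
    return DEResultTable(method=method, table=df[["log2fc", "pvalue", "padj"]])


def cpm(counts: np.ndarray, library_labels: Sequence[str] | None = None) -> np.ndarray:
    """Counts-per-million: counts * 1e6 / library total, per library."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        names = (
            [library_labels[i] for i in zero]
            if library_labels is not None
            else [str(i) for i in zero]
        )
        raise ValueError(f"library with zero total counts: {', '.join(names)}")
    return counts * 1e6 / totals


def cpm_filter(
    universe: GeneUniverse,
    threshold: float = 1.0,
    min_libraries: int = 2,
) -> tuple[GeneSet, pd.DataFrame]:
    """Apply the background CPM rule.

    A gene is REMOVED iff the number of libraries in which its CPM is
    strictly below ``threshold`` is at least ``min_libraries``; the
    retained genes form the background. Also returns a per-gene report
    (n_low_libraries, retained) for audit.
    """
    if min_libraries > universe.n_libraries:
        raise ValueError(
            f"min_libraries={min_libraries} exceeds the {universe.n_libraries} libraries present"
        )
    mat = cpm(universe.counts, universe.library_labels)
    n_low = (mat < threshold).sum(axis=1)
    retained = n_low < min_libraries
    report = pd.DataFrame(
        {"gene": universe.genes, "n_low_libraries": n_low, "retained": retained}
    ).set_index("gene")
    background = GeneSet(
        name="background",
        members=frozenset(g for g, keep in zip(universe.genes, retained) if keep),
    )
    logger.info(
        "cpm_filter: retained %d / %d genes (threshold %g CPM, min %d libraries)",
        len(background),
        universe.n_genes,
        threshold,
        min_libraries,
    )
    return background, report


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment (used only for synthetic DE tables; real
    tables carry their method's own adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DegCall:
    gene: str
    direction: str  # "up" | "down"
    passed_methods: frozenset[str]


def call_degs(
    tables: Sequence[DEResultTable],
    fdr: float = 0.05,
    fc: float = 2.0,
) -> tuple[list[DegCall], dict]:
    """Intersect DE method calls into the final DEG set.

    A gene is a DEG iff in EVERY table adjusted p < ``fdr`` (strict)
    and |log2fc| >= log2(``fc``) (inclusive), and the fold-change sign
    agrees across tables. Genes passing both thresholds with
    discordant directions are excluded and logged. Genes absent from
    any table are not DEGs; NA adjusted p is treated as 1 with a
    warning.
    """
    if len(tables) < 1:
        raise ValueError("need at least one DE result table")
    log2_cut = math.log2(fc)
    per_method: dict[str, pd.DataFrame] = {}
    for t in tables:
        df = t.table.copy()
        if df["padj"].isna().any():
            logger.warning(
                "DE table %s: %d NA adjusted p-values treated as 1",
                t.method,
                int(df["padj"].isna().sum()),
            )
        df["padj"] = df["padj"].fillna(1.0)
        df["pass"] = (df["padj"] < fdr) & (df["log2fc"].abs() >= log2_cut)
        per_method[t.method] = df

    common = set.intersection(*(set(df.index[df["pass"]]) for df in per_method.values()))
    calls: list[DegCall] = []
    discordant: list[str] = []
    for gene in sorted(common):
        signs = {np.sign(per_method[m].at[gene, "log2fc"]) for m in per_method}
        if len(signs) > 1 or 0 in signs:
            discordant.append(gene)
            continue
        direction = "up" if signs.pop() > 0 else "down"
        calls.append(
            DegCall(gene=gene, direction=direction, passed_methods=frozenset(per_method))
        )
    if discordant:
        logger.warning(
            "call_degs: excluded %d gene(s) with discordant fold-change signs: %s",
            len(discordant),
            ", ".join(discordant[:10]),
        )
    n_up = sum(c.direction == "up" for c in calls)
    n_down = sum(c.direction == "down" for c in calls)
    summary = {
        "n_degs": len(calls),
        "n_up": n_up,
        "n_down": n_down,
        "n_discordant_excluded": len(discordant),
        "fdr_threshold": fdr,
        "fold_change_threshold": fc,
        "methods": sorted(per_method),
    }
    return calls, summary


def degs_to_frame(calls: Sequence[DegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "direction": [c.direction for c in calls],
            "passed_methods": [",".join(sorted(c.passed_methods)) for c in calls],
        }
    )
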