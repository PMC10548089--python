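"""Distribution of DEGs across single-cell cluster marker sets.

Consumes a published marker table (gene, cluster) — clustering and
marker calling themselves are upstream of this package — and answers
two questions: how are the DEGs spread across clusters, and is their
concentration in a designated focal cluster set (e.g., the cnidocyte
clusters) larger than chance, by the same permutation machinery as the
catalogue-overlap test.

Counting convention: a DEG that is a marker of several clusters
contributes to each cluster's count but only once to the distinct-gene
totals, which keeps fractions of the form 110/168 well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_io import GeneSet
from .set_enrichment import PermutationConfig, PermutationResult, permutation_overlap_test

logger = logging.getLogger("cnidomir")

__all__ = [
    "read_marker_table",
    "ClusterDistribution",
    "assign_degs_to_clusters",
    "cluster_enrichment_test",
]


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a (gene, cluster) marker TSV; duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if not {"gene", "cluster"} <= set(df.columns):
        raise ValueError(f"{path}: need 'gene' and 'cluster' columns")
    df = df[["gene", "cluster"]].dropna()
    if (df["cluster"].str.strip() == "").any():
        raise ValueError(f"{path}: empty cluster id")
    before = len(df)
    df = df.drop_duplicates()
    if len(df) < before:
        logger.warning("%s: collapsed %d duplicate (gene, cluster) rows", path, before - len(df))
    return df.reset_index(drop=True)


@dataclass
class ClusterDistribution:
    """Per-cluster DEG counts and the focal-cluster share."""

    per_cluster: dict[str, int]
    total_overlapping: int
    focal_count: int
    focal_clusters: frozenset[str]
    focal_fraction: float | None  # None when no DEG overlaps any marker

    @property
    def focal_fraction_defined(self) -> bool:
        return self.focal_fraction is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_cluster.items()), columns=["cluster", "deg_count"]
        )


def assign_degs_to_clusters(
    degs: GeneSet | Iterable[str],
    markers: pd.DataFrame,
    focal_clusters: Sequence[str] | set[str],
) -> ClusterDistribution:
    """Count DEGs per marker cluster and the focal-cluster fraction.

    ``focal_fraction`` is the share of distinct marker-overlapping
    DEGs whose marker cluster set intersects ``focal_clusters``; it is
    flagged undefined (None) rather than 0 when no DEG overlaps the
    marker table at all.
    """
    deg_set = degs.members if isinstance(degs, GeneSet) else frozenset(degs)
    clusters_present = set(markers["cluster"].unique())
    focal = {str(c) for c in focal_clusters}
    missing = focal - clusters_present
    if missing:
        raise ValueError(
            f"focal cluster(s) {sorted(missing)} absent from the marker table "
            f"(present: {sorted(clusters_present)})"
        )
    hits = markers[markers["gene"].isin(deg_set)]
    per_cluster = {c: 0 for c in clusters_present}
    counts = hits.groupby("cluster")["gene"].nunique()
    per_cluster.update({str(c): int(v) for c, v in counts.items()})
    overlapping_genes = set(hits["gene"])
    focal_genes = set(hits.loc[hits["cluster"].isin(focal), "gene"])
    total = len(overlapping_genes)
    fraction = (len(focal_genes) / total) if total > 0 else None
    if fraction is None:
        logger.warning("assign_degs_to_clusters: no DEG overlaps any marker; focal fraction undefined")
    return ClusterDistribution(
        per_cluster=per_cluster,
        total_overlapping=total,
        focal_count=len(focal_genes),
        focal_clusters=frozenset(focal),
        focal_fraction=fraction,
    )


def cluster_enrichment_test(
    degs: GeneSet,
    markers: pd.DataFrame,
    focal_clusters: Sequence[str] | set[str],
    background: GeneSet,
    cfg: PermutationConfig | None = None,
) -> PermutationResult:
    """Permutation enrichment of DEGs in the focal clusters.

    The target is the union of the focal clusters' marker genes;
    everything else delegates to the catalogue-overlap permutation
    test.
    """
    focal = {str(c) for c in focal_clusters}
    missing = focal - set(markers["cluster"].unique())
    if missing:
        raise ValueError(f"focal cluster(s) {sorted(missing)} absent from the marker table")
    target_genes = frozenset(markers.loc[markers["cluster"].isin(focal), "gene"])
    if not target_genes:
        raise ValueError("focal clusters have no marker genes")
    target = GeneSet(name="focal_markers", members=target_genes)
    return permutation_overlap_test(degs, target, background, cfg)
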