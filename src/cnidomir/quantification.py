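"""Stem-loop qPCR relative quantification (2^-ddCt) and two-group tests.

The Livak 2^-ddCt convention: technical replicates are averaged first;
dCt per biological replicate is mean Ct(target) - mean Ct(reference);
ddCt anchors each replicate's dCt to the MEAN control dCt; relative
quantity is 2^-ddCt, so the control group's geometric mean RQ is 1 by
construction. Amplification efficiency is fixed at 2 (the method's
assumption); no standard-curve correction.

Group comparisons are the classical two-sample t test (equal-variance
Student by default, matching how such assays are usually reported;
Welch by flag), applicable to RQ values, paralysis percentages or
sorted-cell percentages alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_ct_table",
    "validate_ct_table",
    "RelativeQuantity",
    "ddct",
    "TTestResult",
    "two_group_ttest",
]

_CT_COLUMNS = ["sample", "condition", "gene", "bio_rep", "tech_rep", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV with columns sample, condition, gene, bio_rep,
    tech_rep, ct."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    missing = set(_CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df[_CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


@dataclass
class RelativeQuantity:
    """Per-replicate dCt/ddCt/RQ plus per-condition summaries."""

    gene: str
    reference_gene: str
    control_condition: str
    per_replicate: pd.DataFrame  # condition, bio_rep, delta_ct, delta_delta_ct, rq
    summary: pd.DataFrame  # per condition: mean/sd of rq, geometric mean rq, mean ddCt

    def rq_values(self, condition: str) -> np.ndarray:
        sel = self.per_replicate["condition"] == condition
        return self.per_replicate.loc[sel, "rq"].to_numpy()

    def ddct_values(self, condition: str) -> np.ndarray:
        sel = self.per_replicate["condition"] == condition
        return self.per_replicate.loc[sel, "delta_delta_ct"].to_numpy()


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> dict[str, RelativeQuantity]:
    """2^-ddCt relative quantification, one result per target gene.

    Requires the reference gene in every (condition, biological
    replicate) and at least 2 biological replicates per condition.
    """
    validate_ct_table(table)
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from the Ct table")
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from the Ct table")

    # technical replicates average first
    tech_mean = (
        table.groupby(["condition", "bio_rep", "gene"], sort=True)["ct"]
        .mean()
        .rename("ct")
        .reset_index()
    )
    ref = tech_mean[tech_mean["gene"] == reference_gene].set_index(["condition", "bio_rep"])["ct"]
    results: dict[str, RelativeQuantity] = {}
    targets = sorted(g for g in tech_mean["gene"].unique() if g != reference_gene)
    for gene in targets:
        sub = tech_mean[tech_mean["gene"] == gene].copy()
        key = list(zip(sub["condition"], sub["bio_rep"]))
        missing_ref = [k for k in key if k not in ref.index]
        if missing_ref:
            cond, rep = missing_ref[0]
            raise ValueError(
                f"missing reference gene {reference_gene!r} for sample "
                f"(condition={cond!r}, bio_rep={rep!r})"
            )
        sub["delta_ct"] = sub["ct"].to_numpy() - ref.loc[key].to_numpy()
        counts = sub.groupby("condition")["bio_rep"].nunique()
        if (counts < 2).any():
            few = counts[counts < 2].index.tolist()
            raise ValueError(
                f"gene {gene!r}: need >= 2 biological replicates per condition, "
                f"found fewer in {few}"
            )
        control_mean_dct = sub.loc[sub["condition"] == control_condition, "delta_ct"].mean()
        sub["delta_delta_ct"] = sub["delta_ct"] - control_mean_dct
        sub["rq"] = np.power(2.0, -sub["delta_delta_ct"])
        per_rep = sub[["condition", "bio_rep", "delta_ct", "delta_delta_ct", "rq"]].reset_index(
            drop=True
        )
        summary = (
            per_rep.groupby("condition")
            .agg(
                rq_mean=("rq", "mean"),
                rq_sd=("rq", "std"),
                rq_geometric_mean=("rq", lambda v: float(np.exp(np.mean(np.log(v))))),
                ddct_mean=("delta_delta_ct", "mean"),
                n_replicates=("rq", "size"),
            )
            .reset_index()
        )
        results[gene] = RelativeQuantity(
            gene=gene,
            reference_gene=reference_gene,
            control_condition=control_condition,
            per_replicate=per_rep,
            summary=summary,
        )
    return results


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    degenerate: bool = False


def two_group_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "student",
) -> TTestResult:
    """Classical two-sided two-sample t test, computed closed-form.

    ``student`` pools the variance (equal-variance assumption);
    ``welch`` uses the Welch-Satterthwaite degrees of freedom. Zero
    variance in both groups degenerates to p = 1 for equal means and a
    flagged p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return TTestResult(t=0.0, df=float(na + nb - 2), p=1.0, variant=variant, degenerate=True)
        return TTestResult(
            t=math.copysign(math.inf, ma - mb),
            df=float(na + nb - 2),
            p=0.0,
            variant=variant,
            degenerate=True,
        )

    if variant == "student":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se2a, se2b = va / na, vb / nb
        se = math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (na - 1) + se2b**2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=min(p, 1.0), variant=variant)
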