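#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/synthetic/: a negative-binomial count matrix
with its background truth, a planted DEG/catalogue gene-set pair at
the study geometry (944 vs 2,615, overlap 268, background 22,500), a
12-cluster / 2,168-gene marker catalogue, transcripts with planted
miRNA sites, DE result tables with planted truth, and a qPCR Ct table
with a planted 4-fold knockdown.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cnidomir import core_io
from cnidomir.synthetic_data import (
    EnrichmentSpec,
    SiteSpec,
    UniverseSpec,
    plant_enrichment,
    random_mirna,
    simulate_de_tables,
    simulate_marker_table,
    simulate_qpcr,
    simulate_transcripts_with_sites,
    simulate_universe,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rng = core_io.derive_rng(args.seed, "01-universe")
    universe, truth = simulate_universe(UniverseSpec(B=2000, zero_gene_fraction=0.12), rng)
    universe.to_tsv(out / "counts.tsv")
    truth.to_csv(out / "universe_truth.tsv", sep="\t", index=False)
    print(f"count matrix: {universe.n_genes} genes x {universe.n_libraries} libraries, "
          f"{int(truth.in_background.sum())} constructed to survive the CPM rule")

    rng = core_io.derive_rng(args.seed, "01-enrichment")
    genes = [f"g{i:05d}" for i in range(22_500)]
    (out / "background.txt").write_text("\n".join(genes) + "\n")
    target, degs, etruth = plant_enrichment(
        genes, EnrichmentSpec(K=2615, n=944, x_target=268), rng
    )
    core_io.write_gene_set(target, out / "cnidocyte_catalogue.txt")
    core_io.write_gene_set(degs, out / "degs.txt")
    (out / "enrichment_truth.json").write_text(json.dumps(
        {k: v for k, v in etruth.items() if k != "shared_genes"}, indent=2) + "\n")
    print(f"planted sets: |target|={len(target)}, |degs|={len(degs)}, overlap={etruth['x_target']}")

    # cnidocyte-style marker catalogue: clusters 1-2 (the cnidocyte
    # clusters) draw their markers from the cnidocyte catalogue, the
    # other ten clusters from the rest of the background, so the DEG
    # list concentrates in the focal clusters as in the real data
    rng = core_io.derive_rng(args.seed, "01-markers")
    from cnidomir.synthetic_data import DEFAULT_CLUSTER_SIZES

    cnido, _ = simulate_marker_table(
        sorted(target.members), rng, n_clusters=2, sizes=DEFAULT_CLUSTER_SIZES[:2]
    )
    rest_genes = sorted(set(genes) - target.members)
    rest, _ = simulate_marker_table(
        rest_genes, rng, n_clusters=10, sizes=DEFAULT_CLUSTER_SIZES[2:]
    )
    rest["cluster"] = (rest["cluster"].astype(int) + 2).astype(str)
    markers = pd.concat([cnido, rest], ignore_index=True)
    markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    print(f"marker catalogue: {len(markers)} genes in {markers.cluster.nunique()} clusters "
          f"(clusters 1-2 drawn from the cnidocyte catalogue)")

    rng = core_io.derive_rng(args.seed, "01-transcripts")
    mirna = random_mirna(rng)
    records, struth = simulate_transcripts_with_sites(mirna, SiteSpec(), rng)
    core_io.write_fasta([mirna], out / "mirna.fa")
    core_io.write_fasta(records, out / "transcripts.fa")
    struth.to_csv(out / "sites_truth.tsv", sep="\t", index=False)
    print(f"transcripts: {len(records)} sequences, {len(struth)} planted sites")

    rng = core_io.derive_rng(args.seed, "01-detables")
    tables, dtruth = simulate_de_tables(genes[:2000], rng, n_degs=120)
    for t in tables:
        t.table.to_csv(out / f"de_{t.method}.tsv", sep="\t")
    dtruth.to_csv(out / "de_truth.tsv", sep="\t", index=False)
    print(f"DE tables: {len(tables)} methods, {int(dtruth.is_deg.sum())} planted DEGs")

    rng = core_io.derive_rng(args.seed, "01-qpcr")
    ct, qtruth = simulate_qpcr(effect=0.25, noise_sd=0.3, rng=rng)
    ct.to_csv(out / "ct.csv", index=False)
    (out / "qpcr_truth.json").write_text(json.dumps(qtruth, indent=2) + "\n")
    print(f"qPCR: planted fold change {qtruth['effect']} at Ct noise SD {qtruth['noise_sd']}")


if __name__ == "__main__":
    main()
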