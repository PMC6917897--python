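#!/usr/bin/env python
"""Pre-ranked enrichment, leading-edge candidates and compartment overlap.

Scores every gene set against each ranked list (weighted running sum,
1,000 gene-tag permutations, sign-stratified FDR), extracts the top-10
candidate genes per sign from the significant leading edges, and summarises
the cortical/subcortical overlap of significant sets and their member
genes. Writes per-list tables under results/enrichment/ and overlap.tsv.
"""

from pathlib import Path

import pandas as pd

from brainsig import enrich, io

ROOT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 1000
SEED = 7


def main() -> None:
    gene_sets = io.read_gmt(ROOT / "data" / "gene_sets.gmt")
    member_unions: dict[tuple[str, str], set] = {}
    sig_ids: dict[tuple[str, str], set] = {}
    for list_path in sorted((ROOT / "ranked").glob("L_*.tsv")):
        function, comp = list_path.stem.removeprefix("L_").rsplit("_", 1)
        ranked = io.read_ranked_list(list_path)
        report = enrich.score_gene_sets(ranked, gene_sets, n_perm=N_PERM,
                                        seed=SEED)
        outdir = ROOT / "enrichment" / f"{function}_{comp}"
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_enrichment(report, outdir / "enrichment.tsv")
        for sign, tag in ((+1, "pos"), (-1, "neg")):
            cl = enrich.candidate_ranking(report, ranked, sign)
            io.write_candidates(cl, outdir / f"candidates_{tag}.tsv")
        nodes, edges = enrich.network_table(report)
        nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        member_unions[(function, comp)] = report.member_gene_union()
        sig_ids[(function, comp)] = set(
            pd.concat([report.s_plus, report.s_minus])["set_id"])
        print(f"{function} {comp}: {len(report.s_plus)}+ / "
              f"{len(report.s_minus)}- sets at FDR q < 0.05")

    rows = []
    for function in sorted({f for (f, _) in member_unions}):
        ov = enrich.overlap_analysis(
            member_unions[(function, "cortical")],
            member_unions[(function, "subcortical")],
            sig_ids[(function, "cortical")],
            sig_ids[(function, "subcortical")])
        rows.append({"function": function,
                     "shared_sets": len(ov.shared_sets),
                     "set_pct": ov.set_pct,
                     "shared_genes": len(ov.shared_genes),
                     "gene_pct": ov.gene_pct})
        print(f"{function} cortical/subcortical overlap: "
              f"{len(ov.shared_sets)} sets ({ov.set_pct}%), "
              f"{len(ov.shared_genes)} genes ({ov.gene_pct}%)")
    pd.DataFrame(rows).to_csv(ROOT / "enrichment" / "overlap.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
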