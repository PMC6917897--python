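#!/usr/bin/env python
"""Validation statistics for every candidate list.

Per (function x compartment x sign): the chance probability that the
candidate list's known-gene hits arise by drawing without replacement from
the pool, the evidence-weighted precision scores, and the bootstrapped
memory-minus-motor correlation-difference test over the genes of the
significant sets (10,000 iterations, central 95% interval). Writes
results/validation_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from brainsig import io, validate

ROOT = Path(__file__).resolve().parent.parent / "results"
N_ITER = 10000
SEED = 7
SIGN_TAG = {+1: ("pos", "+"), -1: ("neg", "-")}


def main() -> None:
    evidence = io.read_evidence(ROOT / "data" / "evidence.tsv")
    pools = io.read_pools(ROOT / "data" / "pools.tsv")
    ranked = {p.stem.removeprefix("L_"): io.read_ranked_list(p)
              for p in (ROOT / "ranked").glob("L_*.tsv")}
    functions = sorted({k.rsplit("_", 1)[0] for k in ranked})
    report: dict = {"lists": {}, "bootstrap": {}}

    members: dict[tuple[str, str, int], set] = {}
    for key, rl in ranked.items():
        function, comp = key.rsplit("_", 1)
        enr = io.read_enrichment(ROOT / "enrichment" / key / "enrichment.tsv")
        control = next(f for f in functions if f != function)
        mean_r = pd.Series(rl.scores, index=rl.genes)
        pool = set(pools.get(function, [])) & set(rl.genes)
        for sign, (tag, symbol) in SIGN_TAG.items():
            label = f"{function}_{comp}_{symbol}"
            sig = enr[(enr["fdr_q"] < 0.05) & (enr["es"] * sign > 0)]
            if len(sig):
                members[(function, comp, sign)] = set(
                    g for ms in sig["members"] for g in ms)
            cl = pd.read_csv(ROOT / "enrichment" / key /
                             f"candidates_{tag}.tsv", sep="\t")
            if cl.empty:
                report["lists"][label] = {"candidates": None}
                print(f"{label}: no sets survived FDR; no candidate list")
                continue
            genes = cl["gene_id"].tolist()
            n_hits = sum(g in pool for g in genes)
            prob = validate.chance_probability(n_hits, len(pool), len(rl))
            prec = validate.precision_scores(genes, evidence, list_id=label,
                                             target=function, control=control)
            report["lists"][label] = {
                "candidates": genes,
                "chance": {"N": n_hits, "K": len(pool), "M": len(rl),
                           "probability": prob},
                "precision": {"target_score": prec.memory_score,
                              "control_score": prec.motor_score,
                              "difference": prec.difference,
                              "defined": prec.defined}}
            print(f"{label}: {n_hits}/10 pool genes (p = {prob:.2e}), "
                  f"precision {prec.memory_score:.3f}" if prec.defined
                  else f"{label}: no evidence")

    sizes = {f: min(len(m) for (ff, _, _), m in members.items() if ff == f)
             for f in functions
             if any(ff == f for (ff, _, _) in members)}
    for (function, comp, sign), mem in members.items():
        control = next(f for f in functions if f != function)
        key_t, key_c = f"{function}_{comp}", f"{control}_{comp}"
        if key_c not in ranked:
            continue
        t = pd.Series(ranked[key_t].scores, index=ranked[key_t].genes)
        c = pd.Series(ranked[key_c].scores, index=ranked[key_c].genes)
        d = validate.correlation_differences(t, c, sorted(mem), sign)
        label = f"{function}_{comp}_{SIGN_TAG[sign][1]}"
        boot = validate.bootstrap_difference(
            d, n_sub=min(sizes[function], len(d)), n_iter=N_ITER, seed=SEED,
            set_id=label)
        report["bootstrap"][label] = {
            "n_genes": len(d), "n_sub": boot.n_sub,
            "boot_mean": boot.boot_mean, "pct_2_5": boot.pct_2_5,
            "pct_97_5": boot.pct_97_5, "significant": boot.significant}
        star = "*" if boot.significant else " "
        print(f"{label}: boot mean diff {boot.boot_mean:+.3f} "
              f"[{boot.pct_2_5:+.3f}, {boot.pct_97_5:+.3f}] {star}")

    out = ROOT / "validation_report.json"
    out.write_text(json.dumps(report, indent=1))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
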