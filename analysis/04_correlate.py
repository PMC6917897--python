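#!/usr/bin/env python
"""Spatial correlation per gene and the four ranked lists L.

For every (function x compartment): per-donor OLS fits of smoothed
expression on map z, the unweighted mean of valid per-donor Pearson r as
the random-effects summary, and the descending ranked list. Writes
results/ranked/L_<function>_<compartment>.tsv.
"""

from pathlib import Path

from brainsig import correlate, io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "ranked"
    out.mkdir(parents=True, exist_ok=True)
    for func_dir in sorted((ROOT / "coregistered").iterdir()):
        paired = io.read_paired(func_dir)
        for comp in sorted({c for (_, c) in paired}):
            ranked = correlate.ranked_list_for(paired, comp)
            path = out / f"L_{func_dir.name}_{comp}.tsv"
            io.write_ranked_list(ranked, path)
            top = ranked.table.iloc[0]
            print(f"{path.name}: {len(ranked)} genes, "
                  f"{ranked.n_positive}+ / {ranked.n_negative}-, "
                  f"top gene {top.gene_id} (mean r = {top.mean_r:.2f})")


if __name__ == "__main__":
    main()
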