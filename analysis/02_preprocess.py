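#!/usr/bin/env python
"""Probe-level preprocessing: background filter, probe selection, z-scores.

Reads the per-donor probe matrices from results/data/, keeps probes above
background in at least half of every donor's samples, collapses each gene
to its most differentially stable probe, and z-scores per donor separately
for the cortical and subcortical compartments. Writes gene x sample TSVs
and a QC log to results/preprocessed/.
"""

from pathlib import Path

from brainsig import io, preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pms = io.read_probe_matrices(ROOT / "data")
    samples = io.read_samples(ROOT / "data" / "samples.tsv")
    gms, qc = preprocess.preprocess(pms, samples)
    io.write_gene_matrices(gms, qc, ROOT / "preprocessed")
    print(f"probes: {qc['n_probes_in']} -> "
          f"{qc['n_probes_after_background']} after background filter")
    print(f"genes retained: {qc['n_genes']} "
          f"({len(qc['dropped_genes'])} dropped)")
    print(f"wrote {ROOT / 'preprocessed'}")


if __name__ == "__main__":
    main()
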