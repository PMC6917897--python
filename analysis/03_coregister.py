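#!/usr/bin/env python
"""Pair expression samples with term-map z scores, per function.

Each sample is snapped to its nearest voxel, kept only when the voxel z is
strictly positive (the map masks the transcriptome), and expression is
smoothed over a 6 mm sphere of the donor's retained samples. Writes one
paired TSV per donor-compartment under results/coregistered/<function>/.
"""

from pathlib import Path

from brainsig import coregister, io
from brainsig.maps import TermMap

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gms = io.read_gene_matrices(ROOT / "preprocessed")
    samples = io.read_samples(ROOT / "data" / "samples.tsv")
    for map_path in sorted((ROOT / "data").glob("map_*.nii.gz")):
        function = map_path.name.removeprefix("map_").removesuffix(".nii.gz")
        tmap = TermMap.load(map_path)
        paired = coregister.pair_samples(gms, samples, tmap, radius_mm=6.0)
        io.write_paired(paired, ROOT / "coregistered" / function)
        counts = {f"{d}/{c}": len(ps.z) for (d, c), ps in paired.items()}
        print(f"{function}: retained samples per donor-compartment {counts}")
    print(f"wrote {ROOT / 'coregistered'}")


if __name__ == "__main__":
    main()
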