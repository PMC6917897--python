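"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text apart from the term maps, which are NIfTI volumes:
probe matrices and above-background flags as CSV (probes x samples), sample
annotations / evidence / pools / ranked lists / enrichment tables as TSV,
gene sets as GMT, ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlate import RankedList
from .maps import TermMap
from .preprocess import GeneMatrix, ProbeMatrix


# ---------------------------------------------------------------------------
# GMT

def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in gene_sets:
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *gene_sets[set_id]]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# synthetic dataset

def write_dataset(ds, outdir: Path) -> None:
    """Serialise a SyntheticDataset; gene/probe order is shuffled on write."""
    from .synth import stage_rng
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    rng = stage_rng(ds.cfg.seed, "write")
    for donor, pm in ds.probes.items():
        order = rng.permutation(len(pm.values))
        pm.values.iloc[order].to_csv(outdir / f"expr_{donor}.csv")
        pm.above_background.iloc[order].to_csv(outdir / f"flags_{donor}.csv")
    any_pm = next(iter(ds.probes.values()))
    any_pm.probe_to_gene.rename("gene_id").rename_axis("probe_id") \
        .to_csv(outdir / "probe2gene.tsv", sep="\t")
    for function, tmap in ds.maps.items():
        tmap.save(outdir / f"map_{function}.nii.gz")
    write_gmt(ds.gene_sets, outdir / "gene_sets.gmt")
    ds.evidence.to_csv(outdir / "evidence.tsv", sep="\t")
    pools = pd.DataFrame([(f, g) for f, genes in ds.truth.pools.items()
                          for g in genes], columns=["function", "gene_id"])
    pools.to_csv(outdir / "pools.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(ds.truth.to_json())


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_probe_matrices(indir: str | Path) -> dict[str, ProbeMatrix]:
    indir = Path(indir)
    p2g = pd.read_csv(indir / "probe2gene.tsv", sep="\t",
                      index_col="probe_id")["gene_id"]
    out: dict[str, ProbeMatrix] = {}
    for f in sorted(indir.glob("expr_*.csv")):
        donor = f.stem.removeprefix("expr_")
        values = pd.read_csv(f, index_col=0)
        flags = pd.read_csv(indir / f"flags_{donor}.csv", index_col=0)
        out[donor] = ProbeMatrix(donor_id=donor, values=values,
                                 probe_to_gene=p2g.loc[values.index],
                                 above_background=flags)
    return out


def read_pools(path: str | Path) -> dict[str, list[str]]:
    tab = pd.read_csv(path, sep="\t")
    return {f: sorted(sub["gene_id"]) for f, sub in tab.groupby("function")}


def read_evidence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# preprocessed matrices

def write_gene_matrices(gms: Mapping[tuple[str, str], GeneMatrix], qc: dict,
                        outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (donor, comp), gm in gms.items():
        gm.values.rename_axis("gene_id") \
            .to_csv(outdir / f"genes_{donor}_{comp}.tsv", sep="\t")
    (outdir / "qc.json").write_text(json.dumps(qc, indent=1, default=str))


def read_gene_matrices(indir: str | Path) -> dict[tuple[str, str], GeneMatrix]:
    indir = Path(indir)
    out: dict[tuple[str, str], GeneMatrix] = {}
    for f in sorted(indir.glob("genes_*.tsv")):
        donor, comp = f.stem.removeprefix("genes_").rsplit("_", 1)
        out[(donor, comp)] = GeneMatrix(
            donor_id=donor, compartment=comp,
            values=pd.read_csv(f, sep="\t", index_col="gene_id"))
    return out


# ---------------------------------------------------------------------------
# paired samples and ranked lists

def write_paired(paired, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (donor, comp), ps in paired.items():
        tab = pd.concat([ps.z.rename("z"), ps.values.T], axis=1)
        tab.rename_axis("sample_id") \
            .to_csv(outdir / f"paired_{donor}_{comp}.tsv", sep="\t")


def read_paired(indir: str | Path):
    from .coregister import PairedSampleSet
    indir = Path(indir)
    out = {}
    for f in sorted(indir.glob("paired_*.tsv")):
        donor, comp = f.stem.removeprefix("paired_").rsplit("_", 1)
        tab = pd.read_csv(f, sep="\t", index_col="sample_id")
        out[(donor, comp)] = PairedSampleSet(
            donor_id=donor, compartment=comp,
            values=tab.drop(columns="z").T, z=tab["z"],
            coords=pd.DataFrame(index=tab.index))
    return out


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    tab = ranked.table.copy()
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    tab.to_csv(path, sep="\t", index=False)


def read_ranked_list(path: str | Path) -> RankedList:
    tab = pd.read_csv(path, sep="\t").drop(columns="rank")
    return RankedList(table=tab,
                      n_positive=int((tab["mean_r"] > 0).sum()),
                      n_negative=int((tab["mean_r"] < 0).sum()))


# ---------------------------------------------------------------------------
# enrichment outputs

def write_enrichment(report, path: str | Path) -> None:
    tab = report.results.copy()
    for col in ("members", "leading_edge"):
        tab[col] = tab[col].map(";".join)
    tab.to_csv(path, sep="\t", index=False)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    for col in ("members", "leading_edge"):
        tab[col] = tab[col].fillna("").map(
            lambda s: [g for g in s.split(";") if g])
    return tab


def write_candidates(cl: pd.DataFrame | None, path: str | Path) -> None:
    if cl is None:
        Path(path).write_text("gene_id\tn_leading_edge_sets\tmean_r\n")
    else:
        cl.to_csv(path, sep="\t", index=False)
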