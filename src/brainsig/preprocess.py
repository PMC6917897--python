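"""Probe-level preprocessing of donor transcriptomes.

The microarray data arrive as one probe x sample intensity matrix per donor,
with several probes per gene and a per-measurement above-background flag.
Preprocessing turns these into a single gene x sample matrix per donor and
compartment:

1. drop probes that exceed background in fewer than half of a donor's
   samples (a probe must pass in every donor to be kept at all);
2. for each gene keep the probe whose spatial pattern is most reproducible
   across donors (highest differential stability);
3. z-score each gene within donor, separately for the cortical and
   subcortical compartments, since their expression baselines differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cortical", "subcortical")


@dataclass
class ProbeMatrix:
    """Probe-level intensities for one donor.

    ``values`` and ``above_background`` are probe x sample frames sharing
    index (probe_id) and columns (sample_id); ``probe_to_gene`` maps each
    probe to exactly one gene.
    """

    donor_id: str
    values: pd.DataFrame
    probe_to_gene: pd.Series
    above_background: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.above_background.shape:
            raise ValueError("values and above_background must share shape")
        if not self.values.index.equals(self.above_background.index):
            raise ValueError("values and above_background must share probes")
        missing = self.values.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(f"probes without gene mapping: {list(missing)[:5]}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index


@dataclass
class GeneMatrix:
    """Gene x sample z-scores for one donor-compartment."""

    donor_id: str
    compartment: str
    values: pd.DataFrame
    zero_variance: list[str] = field(default_factory=list)


def background_fraction(pm: ProbeMatrix) -> pd.Series:
    """Per-probe fraction of this donor's samples above background."""
    return pm.above_background.mean(axis=1)


def filter_probes(pms: Mapping[str, ProbeMatrix] | ProbeMatrix,
                  threshold: float = 0.5) -> dict[str, ProbeMatrix]:
    """Drop probes below background in too many samples.

    A probe is retained only if its above-background fraction is >= the
    threshold (default 0.5, i.e. not fewer than half the samples) in *every*
    donor, so that all donors share one probe universe afterwards.
    """
    if isinstance(pms, ProbeMatrix):
        pms = {pms.donor_id: pms}
    if not pms or any(p.values.empty for p in pms.values()):
        raise ValueError("no probes")
    keep: pd.Index | None = None
    for pm in pms.values():
        ok = background_fraction(pm) >= threshold
        passing = pm.probes[ok.reindex(pm.probes).to_numpy()]
        keep = passing if keep is None else keep.intersection(passing)
    assert keep is not None
    dropped = next(iter(pms.values())).probes.difference(keep)
    if len(dropped):
        logger.info("background filter dropped %d probes", len(dropped))
    out = {}
    for donor, pm in pms.items():
        kept = pm.probes.intersection(keep)
        out[donor] = ProbeMatrix(
            donor_id=pm.donor_id,
            values=pm.values.loc[kept],
            probe_to_gene=pm.probe_to_gene.loc[kept],
            above_background=pm.above_background.loc[kept],
        )
    return out


def _region_means(pm: ProbeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Average each probe within region_label over this donor's samples."""
    ann = samples.set_index("sample_id").loc[pm.values.columns]
    return pm.values.T.groupby(ann["region_label"]).mean().T


def _rowwise_pearson(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Pearson r between matching rows of two aligned frames."""
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    ac = av - av.mean(axis=1, keepdims=True)
    bc = bv - bv.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return pd.Series(r, index=a.index)


def differential_stability(pms: Mapping[str, ProbeMatrix],
                           samples: pd.DataFrame) -> pd.Series:
    """Differential stability per probe.

    Expression is averaged within region per donor; DS is the mean over all
    donor pairs of the Pearson correlation between the two donors' region-
    mean vectors, restricted to regions sampled by both. Pairs sharing fewer
    than two regions are skipped; probes with no valid pair get NaN.
    """
    if len(pms) < 2:
        raise ValueError("differential stability needs at least 2 donors")
    means = {d: _region_means(pm, samples) for d, pm in pms.items()}
    probes = next(iter(means.values())).index
    acc = pd.DataFrame(index=probes)
    for i, (da, db) in enumerate(combinations(sorted(means), 2)):
        shared = means[da].columns.intersection(means[db].columns)
        if len(shared) < 2:
            logger.info("donor pair (%s, %s) shares <2 regions; skipped", da, db)
            continue
        acc[i] = _rowwise_pearson(means[da][shared], means[db][shared])
    if acc.empty:
        raise ValueError("no donor pair shares enough regions")
    return acc.mean(axis=1)


def select_probes(probe_to_gene: pd.Series,
                  ds: pd.Series) -> tuple[pd.Series, list[str]]:
    """Pick, per gene, the surviving probe with the highest DS.

    Ties break to the lexicographically smallest probe_id. Genes whose
    probes all have undefined DS are dropped (returned separately).
    """
    tab = pd.DataFrame({"gene": probe_to_gene, "ds": ds.reindex(probe_to_gene.index)})
    tab = tab.rename_axis("probe").reset_index()
    valid = tab.dropna(subset=["ds"])
    valid = valid.sort_values(["gene", "ds", "probe"],
                              ascending=[True, False, True], kind="mergesort")
    winners = valid.groupby("gene", sort=True).first()["probe"]
    dropped = sorted(set(tab["gene"]) - set(winners.index))
    if dropped:
        logger.info("dropped %d genes with no DS-scorable probe", len(dropped))
    return winners, dropped


def collapse_to_genes(pms: Mapping[str, ProbeMatrix],
                      winners: pd.Series) -> dict[str, pd.DataFrame]:
    """Reduce each donor's probe matrix to one row per gene via the winners."""
    out = {}
    for donor, pm in pms.items():
        sub = pm.values.loc[winners.to_numpy()]
        sub.index = winners.index  # gene ids
        out[donor] = sub
    return out


def zscore_by_donor(gene_values: pd.DataFrame, samples: pd.DataFrame,
                    donor_id: str) -> dict[str, GeneMatrix]:
    """z-score genes within one donor, separately per compartment.

    Uses the sample standard deviation (n-1). Zero-variance genes become
    all-zero and are flagged rather than NaN. A compartment represented by a
    single sample cannot be normalised and is an error.
    """
    ann = samples.set_index("sample_id").loc[gene_values.columns]
    out: dict[str, GeneMatrix] = {}
    for comp in COMPARTMENTS:
        cols = gene_values.columns[(ann["compartment"] == comp).to_numpy()]
        if len(cols) == 0:
            continue
        if len(cols) == 1:
            raise ValueError(
                f"cannot normalize: donor {donor_id} has one {comp} sample")
        block = gene_values[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        flat = sd == 0
        sd_safe = sd.mask(flat, 1.0)
        z = block.sub(mu, axis=0).div(sd_safe, axis=0)
        z[flat] = 0.0
        out[comp] = GeneMatrix(donor_id=donor_id, compartment=comp, values=z,
                               zero_variance=sorted(block.index[flat]))
    return out


def preprocess(pms: Mapping[str, ProbeMatrix],
               samples: pd.DataFrame,
               threshold: float = 0.5,
               ) -> tuple[dict[tuple[str, str], GeneMatrix], dict]:
    """Full probe->gene pipeline; returns matrices keyed (donor, compartment).

    The QC dict records dropped probes/genes, the chosen probe per gene and
    zero-variance flags.
    """
    filtered = filter_probes(pms, threshold=threshold)
    ds = differential_stability(filtered, samples)
    any_pm = next(iter(filtered.values()))
    winners, dropped_genes = select_probes(any_pm.probe_to_gene, ds)
    per_gene = collapse_to_genes(filtered, winners)
    out: dict[tuple[str, str], GeneMatrix] = {}
    zero_var: dict[str, list[str]] = {}
    for donor, gv in per_gene.items():
        for comp, gm in zscore_by_donor(gv, samples, donor).items():
            out[(donor, comp)] = gm
            if gm.zero_variance:
                zero_var[f"{donor}/{comp}"] = gm.zero_variance
    n0 = len(next(iter(pms.values())).probes)
    qc = {
        "n_probes_in": n0,
        "n_probes_after_background": len(any_pm.probes),
        "n_genes": len(winners),
        "dropped_genes": dropped_genes,
        "chosen_probe": winners.to_dict(),
        "zero_variance": zero_var,
    }
    return out, qc
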