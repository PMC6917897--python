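"""End-to-end orchestration of the gene-signature discovery pipeline.

simulate -> preprocess -> co-register -> correlate -> enrich -> validate,
entirely in memory. The numbered scripts under analysis/ drive the same
functions stage by stage against files on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coregister, correlate, enrich, preprocess, validate
from .correlate import RankedList
from .enrich import EnrichmentReport, OverlapSummary
from .synth import SyntheticDataset

SIGN_LABEL = {+1: "+", -1: "-"}


@dataclass
class AnalysisResult:
    """Ranked list, enrichment and candidate lists for one (function, compartment)."""

    function: str
    compartment: str
    ranked: RankedList
    report: EnrichmentReport
    candidates: dict[int, pd.DataFrame | None]

    @property
    def label(self) -> str:
        return f"{self.function}_{self.compartment}"


@dataclass
class StudyResult:
    analyses: dict[tuple[str, str], AnalysisResult]
    overlaps: dict[str, OverlapSummary] = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    def get(self, function: str, compartment: str) -> AnalysisResult:
        return self.analyses[(function, compartment)]


def run_discovery(ds: SyntheticDataset, n_perm: int = 1000, seed: int = 7,
                  fdr: float = enrich.DEFAULT_FDR_THRESHOLD,
                  radius_mm: float = coregister.DEFAULT_SMOOTHING_RADIUS_MM,
                  p_exp: float = 1.0,
                  size_bounds: tuple[int, int] = enrich.DEFAULT_SET_SIZE_BOUNDS,
                  ) -> StudyResult:
    """Run every (function x compartment) analysis of a synthetic study."""
    gms, _qc = preprocess.preprocess(ds.probes, ds.samples)
    analyses: dict[tuple[str, str], AnalysisResult] = {}
    for function, tmap in ds.maps.items():
        paired = coregister.pair_samples(gms, ds.samples, tmap,
                                         radius_mm=radius_mm)
        compartments = sorted({c for (_, c) in paired})
        for comp in compartments:
            ranked = correlate.ranked_list_for(paired, comp)
            report = enrich.score_gene_sets(
                ranked, ds.gene_sets, p=p_exp, n_perm=n_perm, seed=seed,
                size_bounds=size_bounds, fdr_threshold=fdr)
            cls = {s: enrich.candidate_ranking(report, ranked, s)
                   for s in (+1, -1)}
            analyses[(function, comp)] = AnalysisResult(
                function=function, compartment=comp, ranked=ranked,
                report=report, candidates=cls)
    result = StudyResult(analyses=analyses)
    for function in ds.maps:
        comps = [c for (f, c) in analyses if f == function]
        if {"cortical", "subcortical"} <= set(comps):
            a = analyses[(function, "cortical")]
            b = analyses[(function, "subcortical")]
            result.overlaps[function] = enrich.overlap_analysis(
                a.report.member_gene_union(), b.report.member_gene_union(),
                pd.concat([a.report.s_plus, a.report.s_minus])["set_id"],
                pd.concat([b.report.s_plus, b.report.s_minus])["set_id"])
    result.validation = validation_report(result, ds, seed=seed)
    return result


def _mean_r_series(ranked: RankedList) -> pd.Series:
    return pd.Series(ranked.scores, index=ranked.genes)


def validation_report(study: StudyResult, ds: SyntheticDataset,
                      n_iter: int = 10000, seed: int = 7) -> dict:
    """Chance probability and precision per candidate list, plus the
    bootstrapped correlation-difference test when two functions are present."""
    functions = sorted({f for (f, _) in study.analyses})
    report: dict = {"lists": {}, "bootstrap": {}, "overlap": {}}
    universe_sizes = {key: len(ar.ranked) for key, ar in study.analyses.items()}

    for (function, comp), ar in study.analyses.items():
        pool = set(ds.truth.pools.get(function, []))
        pool_in_universe = pool & set(ar.ranked.genes)
        control = next((f for f in functions if f != function), "motor")
        for sign, cl in ar.candidates.items():
            label = f"{function}_{comp}_{SIGN_LABEL[sign]}"
            if cl is None:
                report["lists"][label] = {"candidates": None}
                continue
            genes = cl["gene_id"].tolist()
            n_hits = sum(g in pool for g in genes)
            prob = validate.chance_probability(
                n_hits, len(pool_in_universe), universe_sizes[(function, comp)])
            prec = validate.precision_scores(genes, ds.evidence, list_id=label,
                                             target=function, control=control)
            report["lists"][label] = {
                "candidates": genes,
                "chance": {"N": n_hits, "K": len(pool_in_universe),
                           "M": universe_sizes[(function, comp)],
                           "probability": prob},
                "precision": {"target_score": prec.memory_score,
                              "control_score": prec.motor_score,
                              "difference": prec.difference,
                              "defined": prec.defined},
            }

    if len(functions) >= 2:
        # subsample size per function: smallest significant-set gene union
        sizes: dict[str, int] = {}
        members: dict[tuple[str, str, int], set[str]] = {}
        for (function, comp), ar in study.analyses.items():
            for sign in (+1, -1):
                mem = ar.report.member_gene_union(sign)
                if mem:
                    members[(function, comp, sign)] = mem
        for function in functions:
            ns = [len(m) for (f, _, _), m in members.items() if f == function]
            if ns:
                sizes[function] = min(ns)
        for (function, comp, sign), mem in members.items():
            control = next(f for f in functions if f != function)
            if (control, comp) not in study.analyses:
                continue
            d = validate.correlation_differences(
                _mean_r_series(study.get(function, comp).ranked),
                _mean_r_series(study.get(control, comp).ranked),
                sorted(mem), sign)
            label = f"{function}_{comp}_{SIGN_LABEL[sign]}"
            boot = validate.bootstrap_difference(
                d, n_sub=min(sizes[function], len(d)), n_iter=n_iter,
                seed=seed, set_id=label)
            report["bootstrap"][label] = {
                "n_genes": len(d), "n_sub": boot.n_sub,
                "boot_mean": boot.boot_mean, "pct_2_5": boot.pct_2_5,
                "pct_97_5": boot.pct_97_5, "significant": boot.significant}

    for function, ov in study.overlaps.items():
        union_sets = (len(ov.shared_sets) + len(ov.sets_only_a)
                      + len(ov.sets_only_b))
        union_genes = (len(ov.shared_genes) + len(ov.genes_only_a)
                       + len(ov.genes_only_b))
        report["overlap"][function] = {
            "shared_sets": len(ov.shared_sets), "union_sets": union_sets,
            "set_pct": ov.set_pct,
            "shared_genes": len(ov.shared_genes), "union_genes": union_genes,
            "gene_pct": ov.gene_pct}
    return report
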