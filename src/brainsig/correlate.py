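"""Per-gene spatial correlation and the random-effects ranked list.

Every retained sample is a point in space carrying a normalized expression
value and a map z score. For each gene, expression is regressed on z per
donor (ordinary least squares; Pearson r is the statistic of interest),
and donors are combined by an approximate random-effects summary: the
unweighted arithmetic mean of the valid per-donor correlations. Genes are
then ranked by this mean correlation in descending order.

Fisher z-averaging before the mean is available as an option but is off by
default; the plain average of r is the documented behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coregister import PairedSampleSet

logger = logging.getLogger(__name__)

MIN_POINTS_PER_FIT = 3


@dataclass
class DonorFit:
    donor_id: str
    gene_id: str
    slope: float
    intercept: float
    r: float
    n_points: int
    valid: bool = True


@dataclass
class RankedList:
    """Genes in descending mean-correlation order (ties by gene id)."""

    table: pd.DataFrame       # columns: gene_id, mean_r, n_donors_used
    n_positive: int
    n_negative: int

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.table["mean_r"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


def donor_fit(expr: np.ndarray, z: np.ndarray, donor_id: str = "",
              gene_id: str = "") -> DonorFit:
    """OLS fit of expression on map z for one donor and gene."""
    expr = np.asarray(expr, float)
    z = np.asarray(z, float)
    if expr.shape != z.shape:
        raise ValueError("expression and z vectors must share length")
    n = len(expr)
    if n < MIN_POINTS_PER_FIT:
        raise ValueError(f"need at least {MIN_POINTS_PER_FIT} points")
    zc = z - z.mean()
    ec = expr - expr.mean()
    szz = (zc ** 2).sum()
    see = (ec ** 2).sum()
    if szz == 0 or see == 0:
        return DonorFit(donor_id, gene_id, np.nan, np.nan, np.nan, n, False)
    sez = (zc * ec).sum()
    slope = sez / szz
    return DonorFit(donor_id, gene_id, slope, expr.mean() - slope * z.mean(),
                    sez / np.sqrt(szz * see), n)


def fit_compartment(paired: Mapping[tuple[str, str], PairedSampleSet],
                    compartment: str) -> pd.DataFrame:
    """Per-donor Pearson r for every gene in one compartment (genes x donors)."""
    cols = {}
    for (donor, comp), ps in paired.items():
        if comp != compartment:
            continue
        X = ps.values.to_numpy(float)
        z = ps.z.to_numpy(float)
        if len(z) < MIN_POINTS_PER_FIT:
            logger.info("donor %s %s: fewer than %d points; excluded",
                        donor, comp, MIN_POINTS_PER_FIT)
            continue
        zc = z - z.mean()
        xc = X - X.mean(axis=1, keepdims=True)
        szz = (zc ** 2).sum()
        see = (xc ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ zc) / np.sqrt(szz * see)
        r[(see == 0) | (szz == 0)] = np.nan
        cols[donor] = pd.Series(r, index=ps.values.index)
    if not cols:
        raise ValueError(f"no donor usable for compartment {compartment}")
    return pd.DataFrame(cols)


def random_effects_mean(donor_r: pd.DataFrame, min_donors: int = 2,
                        fisher: bool = False) -> pd.DataFrame:
    """Unweighted mean of valid per-donor correlations per gene.

    Genes with fewer than ``min_donors`` valid donor fits are excluded — a
    one-donor mean is not a random-effects statistic. With ``fisher`` the
    correlations are averaged on the arctanh scale and transformed back.
    """
    n_valid = donor_r.notna().sum(axis=1)
    if fisher:
        mean_r = np.tanh(np.arctanh(donor_r.clip(-1 + 1e-15, 1 - 1e-15))
                         .mean(axis=1))
    else:
        mean_r = donor_r.mean(axis=1)
    out = pd.DataFrame({"gene_id": donor_r.index, "mean_r": mean_r,
                        "n_donors_used": n_valid})
    excluded = out[n_valid < min_donors]
    if len(excluded):
        logger.info("excluded %d genes with <%d valid donors",
                    len(excluded), min_donors)
    return out[n_valid >= min_donors].reset_index(drop=True)


def rank_list(correlations: pd.DataFrame) -> RankedList:
    """Order genes by mean_r descending, ties broken by gene id."""
    tab = correlations.sort_values(["mean_r", "gene_id"],
                                   ascending=[False, True], kind="mergesort")
    tab = tab.reset_index(drop=True)
    return RankedList(table=tab,
                      n_positive=int((tab["mean_r"] > 0).sum()),
                      n_negative=int((tab["mean_r"] < 0).sum()))


def ranked_list_for(paired: Mapping[tuple[str, str], PairedSampleSet],
                    compartment: str, fisher: bool = False) -> RankedList:
    """Donor fits -> random-effects mean -> ranked list, one compartment."""
    donor_r = fit_compartment(paired, compartment)
    return rank_list(random_effects_mean(donor_r, fisher=fisher))
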