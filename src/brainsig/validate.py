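"""Performance assessment: chance probability, precision, bootstrap.

Three checks of the discovery framework:

* chance probability — how likely a candidate list of 10 genes would
  contain its observed number N of known-function genes if genes were drawn
  without replacement from the analysed universe: the product over
  i = 0..N-1 of (K - i)/(M - i) for a pool of K known genes among M
  analysed, equivalently C(K, N)/C(M, N);
* precision scores — evidence-weighted true positives over all
  evidence-weighted hits, where strong literature evidence counts one point
  and weak evidence half a point;
* bootstrapped correlation differences — for genes of the significant
  sets, the memory-minus-motor difference of ranked-list correlations
  (sign-flipped for negative lists so an effect in the expected direction is
  positive), repeatedly subsampled to a fixed size; the effect is deemed
  significant when the central 95% interval of subsample means excludes 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def chance_probability(N: int, K: int, M: int) -> float:
    """P(all N draws without replacement land in a K-gene pool of M genes)."""
    if N < 0 or K < 0 or M < 1:
        raise ValueError("N and K must be non-negative and M positive")
    if N > 10:
        raise ValueError("candidate lists hold at most 10 genes")
    if K > M:
        raise ValueError("pool cannot exceed the universe")
    if N > K:
        return 0.0
    prob = 1.0
    for i in range(N):
        prob *= (K - i) / (M - i)
    return prob


@dataclass
class PrecisionResult:
    list_id: str
    memory_score: float | None
    motor_score: float | None
    defined: bool

    @property
    def difference(self) -> float | None:
        if not self.defined:
            return None
        return self.memory_score - self.motor_score  # type: ignore[operator]


def precision_scores(genes: list[str], evidence: pd.DataFrame,
                     list_id: str = "",
                     target: str = "memory", control: str = "motor"
                     ) -> PrecisionResult:
    """Evidence-weighted precision of a candidate list.

    ``evidence`` holds binary columns ``<function>_strong`` and
    ``<function>_weak`` per gene; genes absent from the table count as
    all-zero. With no evidence at all the scores are undefined (flagged),
    not zero.
    """
    cols = [f"{f}_{w}" for f in (target, control) for w in ("strong", "weak")]
    ev = evidence.reindex(genes)[cols].fillna(0)
    t = ev[f"{target}_strong"].sum() + 0.5 * ev[f"{target}_weak"].sum()
    c = ev[f"{control}_strong"].sum() + 0.5 * ev[f"{control}_weak"].sum()
    if t + c == 0:
        return PrecisionResult(list_id, None, None, defined=False)
    return PrecisionResult(list_id, float(t / (t + c)), float(c / (t + c)),
                           defined=True)


def correlation_differences(target_r: pd.Series, control_r: pd.Series,
                            genes: list[str], sign: int) -> pd.Series:
    """Per-gene target-minus-control correlation differences.

    For genes from a positively enriched list the difference is
    r_target - r_control; for a negatively enriched list it is negated, so
    an effect in the planted direction is always positive. Genes missing
    from either list are excluded (logged).
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    genes = list(genes)
    present = [g for g in genes if g in target_r.index and g in control_r.index]
    missing = len(genes) - len(present)
    if missing:
        logger.info("correlation_differences: %d genes absent from a list",
                    missing)
    d = target_r.loc[present] - control_r.loc[present]
    return sign * d


@dataclass
class BootstrapResult:
    set_id: str
    n_sub: int
    n_iter: int
    boot_mean: float
    pct_2_5: float
    pct_97_5: float

    @property
    def significant(self) -> bool:
        """Interval strictly excludes zero (touching zero is not enough)."""
        return self.pct_2_5 > 0 or self.pct_97_5 < 0


def bootstrap_difference(differences: pd.Series | np.ndarray, n_sub: int,
                         n_iter: int = 10000, seed: int = 0,
                         replace: bool = False,
                         set_id: str = "") -> BootstrapResult:
    """Subsample the differences and summarise the mean's distribution.

    Each iteration draws ``n_sub`` values (without replacement by default)
    and records their mean; the summary is the mean of iteration means and
    the empirical central 95% interval (linear-interpolated percentiles).
    """
    vals = np.asarray(differences, float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_sub > len(vals):
        raise ValueError("n_sub exceeds the number of differences")
    rng = np.random.default_rng(seed)
    if replace:
        draws = rng.choice(vals, size=(n_iter, n_sub), replace=True)
        means = draws.mean(axis=1)
    elif n_sub == len(vals):
        means = np.full(n_iter, vals.mean())
    else:
        u = rng.random((n_iter, len(vals)))
        idx = np.argpartition(u, n_sub, axis=1)[:, :n_sub]
        means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5], method="linear")
    return BootstrapResult(set_id=set_id, n_sub=n_sub, n_iter=n_iter,
                           boot_mean=float(means.mean()),
                           pct_2_5=float(lo), pct_97_5=float(hi))
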