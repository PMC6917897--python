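"""Pair expression samples with term-map z scores.

Each sample's mm coordinate is snapped to its nearest voxel through the map
affine, samples landing on non-positive z voxels are discarded (the map
acts as a mask), and expression is smoothed by replacing each retained
sample's value with the unweighted mean over that donor's retained samples
within a 6 mm Euclidean sphere (including itself). Smoothing operates on
the sparse sample points directly rather than on a rasterized grid, and is
applied after masking so that excluded voxels contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .maps import TermMap
from .preprocess import GeneMatrix

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_RADIUS_MM = 6.0


@dataclass
class PairedSampleSet:
    """Smoothed expression and map z per retained sample, one donor-compartment."""

    donor_id: str
    compartment: str
    values: pd.DataFrame     # gene x retained-sample smoothed expression
    z: pd.Series             # sample -> map z score (all > 0)
    coords: pd.DataFrame     # sample -> x_mm, y_mm, z_mm


def sample_to_voxel(coords_mm: np.ndarray, tmap: TermMap,
                    sample_ids: list[str] | None = None) -> np.ndarray:
    """Nearest voxel index for each mm coordinate.

    Rounds the affine-inverse image half-away-from-zero for platform
    determinism. Out-of-volume samples are an error naming the offenders.
    """
    v = tmap.mm_to_voxel_float(coords_mm)
    ijk = np.trunc(v + np.copysign(0.5, v)).astype(int)
    shape = np.array(tmap.shape)
    bad = np.any((ijk < 0) | (ijk >= shape), axis=1)
    if bad.any():
        ids = ([sample_ids[i] for i in np.flatnonzero(bad)]
               if sample_ids else np.flatnonzero(bad).tolist())
        raise ValueError(f"samples outside the map volume: {ids[:10]}")
    return ijk


def mask_positive(samples: pd.DataFrame, tmap: TermMap) -> pd.DataFrame:
    """Keep samples whose voxel z is strictly positive; attach the z."""
    coords = samples[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    ijk = sample_to_voxel(coords, tmap, samples["sample_id"].tolist())
    z = tmap.values[ijk[:, 0], ijk[:, 1], ijk[:, 2]].astype(float)
    out = samples.copy()
    out["z"] = z
    return out[out["z"] > 0].reset_index(drop=True)


def smoothing_weights(coords_mm: np.ndarray,
                      radius_mm: float) -> np.ndarray:
    """Row-stochastic neighbourhood-mean operator over sample points."""
    if radius_mm < 0:
        raise ValueError("smoothing radius must be non-negative")
    d = np.linalg.norm(coords_mm[:, None, :] - coords_mm[None, :, :], axis=-1)
    w = (d <= radius_mm).astype(float)
    return w / w.sum(axis=1, keepdims=True)


def smooth_expression(values: pd.DataFrame, coords_mm: np.ndarray,
                      radius_mm: float = DEFAULT_SMOOTHING_RADIUS_MM
                      ) -> pd.DataFrame:
    """Average each sample's expression over its <= radius neighbours."""
    w = smoothing_weights(np.asarray(coords_mm, float), radius_mm)
    return pd.DataFrame(values.to_numpy(float) @ w.T,
                        index=values.index, columns=values.columns)


def pair_samples(gene_matrices: Mapping[tuple[str, str], GeneMatrix],
                 samples: pd.DataFrame, tmap: TermMap,
                 radius_mm: float = DEFAULT_SMOOTHING_RADIUS_MM
                 ) -> dict[tuple[str, str], PairedSampleSet]:
    """Mask then smooth every donor-compartment against one term map.

    Donor-compartments retaining zero positive-z samples are excluded from
    the correlation stage (logged), mirroring variable per-donor counts.
    """
    out: dict[tuple[str, str], PairedSampleSet] = {}
    for (donor, comp), gm in gene_matrices.items():
        ann = samples[samples["sample_id"].isin(gm.values.columns)]
        ann = ann[(ann["donor_id"] == donor) & (ann["compartment"] == comp)]
        kept = mask_positive(ann, tmap)
        if kept.empty:
            logger.info("donor %s %s: no samples in positive voxels; excluded",
                        donor, comp)
            continue
        ids = kept["sample_id"].tolist()
        coords = kept[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        smoothed = smooth_expression(gm.values[ids], coords, radius_mm)
        out[(donor, comp)] = PairedSampleSet(
            donor_id=donor, compartment=comp, values=smoothed,
            z=pd.Series(kept["z"].to_numpy(), index=ids),
            coords=kept.set_index("sample_id")[["x_mm", "y_mm", "z_mm"]])
    return out
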