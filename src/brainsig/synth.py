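"""Synthetic study generator with planted ground truth.

Emulates the data regime of a point-sampled brain transcriptome paired with
a meta-analytic functional z-map: a handful of donors each contribute sparse
sample points in a shared volume split into cortical and subcortical
compartments; a term map carries positive-z foci on a zero background with
scattered negative voxels; a chosen subset of genes is planted to correlate
spatially with the map at a known effect size (positively or negatively);
every gene is expanded to several probes of which exactly one — the intended
differential-stability winner — carries low probe noise; gene sets are
drawn predominantly from the planted genes or uniformly at random; and a
literature-evidence table is synthesised consistently with known-gene pools.

The planted truth is sufficient to score every downstream stage: ranked-list
recovery, enriched-set recovery and candidate-list precision. A single
master seed spawns per-stage child generators by fixed offsets, so identical
configurations produce byte-identical outputs.

Expression model. For a planted gene g with target correlation rho, the
gene-level value at sample s is

    x_g(s) = sign_g * rho * z~(s) + sqrt(1 - rho^2) * eps,   eps ~ N(0, sd)

where z~ is the map z standardized over that donor-compartment's samples,
so the population per-donor Pearson correlation equals rho analytically.
Non-planted genes carry a donor-shared random spatial gradient of modest
amplitude plus noise: spatially structured, but uncorrelated with the map
in expectation. Compartments add gene-specific baseline offsets, which the
per-compartment z-scoring of preprocessing removes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import TermMap
from .preprocess import ProbeMatrix

# fixed per-stage seed offsets
_STAGE = {"truth": 0, "map": 1, "samples": 2, "expression": 3,
          "gene_sets": 4, "evidence": 5, "write": 6, "map_motor": 11}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulator.

    Defaults define the standard synthetic study: 4 donors, 2,000 genes with
    3 probes each, 100 samples per donor per compartment, planted spatial
    correlation 0.8, and 50 gene sets of which 5 are planted.
    """

    n_donors: int = 4
    n_genes: int = 2000
    probes_per_gene: int = 3
    n_samples_per_donor_per_compartment: int = 100
    volume_shape: tuple[int, int, int] = (30, 36, 30)
    voxel_size_mm: float = 2.0
    n_foci: int = 4
    focus_radius_mm: float = 10.0
    n_planted_per_sign: int = 25
    planted_positive_genes: tuple[str, ...] | None = None
    planted_negative_genes: tuple[str, ...] | None = None
    effect_rho: float = 0.8
    noise_sd: float = 1.0
    n_gene_sets: int = 50
    n_planted_sets: int = 5
    planted_set_fraction: float = 0.8
    # secondary knobs of the noise model
    probe_noise_winner: float = 0.05
    probe_noise_decoy: float = 2.0
    dark_probe_fraction: float = 0.4
    background_p_above: float = 0.98
    dark_p_above: float = 0.3
    gradient_amplitude: float = 0.4
    negative_voxel_fraction: float = 0.05
    positive_sample_fraction: float = 0.5
    pool_size: int = 80
    function: str = "memory"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if not -1.0 <= self.effect_rho <= 1.0:
            raise ValueError("effect_rho must lie in [-1, 1]")
        if not 0.0 <= self.planted_set_fraction <= 1.0:
            raise ValueError("planted_set_fraction must lie in [0, 1]")
        if self.n_foci < 0 or min(self.volume_shape) <= 0:
            raise ValueError("invalid volume configuration")
        pos = set(self.planted_positive_genes or ())
        neg = set(self.planted_negative_genes or ())
        if pos & neg:
            raise ValueError("planted gene lists must be disjoint")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic study."""

    gene_ids: list[str]
    # gene -> (function, sign, rho); only planted genes appear
    planted: dict[str, tuple[str, int, float]]
    intended_probe: dict[str, str]
    dark_probes: set[str]
    gradients: np.ndarray            # (n_genes, 3) unit rows, donor-shared
    functions: tuple[str, ...]
    planted_sets: dict[str, tuple[str, int]] = field(default_factory=dict)
    pools: dict[str, list[str]] = field(default_factory=dict)

    def planted_genes(self, function: str | None = None,
                      sign: int | None = None) -> list[str]:
        return [g for g, (f, s, _) in self.planted.items()
                if (function is None or f == function)
                and (sign is None or s == sign)]

    def to_json(self) -> str:
        return json.dumps({
            "planted": {g: {"function": f, "sign": s, "rho": r}
                        for g, (f, s, r) in self.planted.items()},
            "intended_probe": self.intended_probe,
            "dark_probes": sorted(self.dark_probes),
            "planted_sets": {k: {"function": f, "sign": s}
                             for k, (f, s) in self.planted_sets.items()},
            "pools": self.pools,
        }, indent=1)


def make_truth(cfg: SyntheticConfig,
               functions: Sequence[str] = ()) -> PlantedTruth:
    """Draw planted gene identities, probe roles and gradient directions."""
    rng = stage_rng(cfg.seed, "truth")
    functions = tuple(functions) or (cfg.function,)
    universe = cfg.gene_ids
    planted: dict[str, tuple[str, int, float]] = {}
    if cfg.planted_positive_genes is not None or cfg.planted_negative_genes is not None:
        for g in cfg.planted_positive_genes or ():
            planted[g] = (functions[0], +1, cfg.effect_rho)
        for g in cfg.planted_negative_genes or ():
            planted[g] = (functions[0], -1, cfg.effect_rho)
    else:
        need = 2 * cfg.n_planted_per_sign * len(functions)
        chosen = rng.choice(universe, size=need, replace=False)
        k = cfg.n_planted_per_sign
        for fi, func in enumerate(functions):
            block = chosen[2 * k * fi: 2 * k * (fi + 1)]
            for g in block[:k]:
                planted[g] = (func, +1, cfg.effect_rho)
            for g in block[k:]:
                planted[g] = (func, -1, cfg.effect_rho)
    grads = rng.normal(size=(cfg.n_genes, 3))
    grads /= np.linalg.norm(grads, axis=1, keepdims=True)
    dark: set[str] = set()
    for g in universe:
        for j in range(2, cfg.probes_per_gene + 1):
            if rng.random() < cfg.dark_probe_fraction:
                dark.add(f"{g}_p{j}")
    intended = {g: f"{g}_p1" for g in universe}
    return PlantedTruth(gene_ids=list(universe), planted=planted,
                        intended_probe=intended, dark_probes=dark,
                        gradients=grads, functions=functions)


# ---------------------------------------------------------------------------
# volume and samples

def _compartment_bands(shape: tuple[int, int, int]) -> dict[str, tuple[int, int]]:
    """Split the volume along the third axis into two compartments."""
    nz = shape[2]
    half = nz // 2
    return {"subcortical": (0, half), "cortical": (half, nz)}


def compartment_of_voxel(k: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    bands = _compartment_bands(shape)
    _, half = bands["subcortical"]
    return np.where(np.asarray(k) < half, "subcortical", "cortical")


def generate_term_map(cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None,
                      n_foci: int | None = None) -> TermMap:
    """Positive-z spherical foci on a zero background with negative scatter.

    Peak z per focus is drawn uniformly in [2, 8] and decays linearly to the
    sphere boundary, so a voxel is strictly positive exactly when it lies
    strictly inside at least one focus. Foci alternate between the two
    compartments so both are represented. With no foci the volume is all
    zero. The affine is diagonal with isotropic voxels.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "map")
    n_foci = cfg.n_foci if n_foci is None else n_foci
    shape = tuple(cfg.volume_shape)
    vs = cfg.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    values = np.zeros(shape, dtype=np.float32)
    if n_foci == 0:
        return TermMap(values=values, affine=affine, foci=[])

    extent = np.array(shape) * vs
    r = cfg.focus_radius_mm
    if r > extent.min() / 2:
        raise ValueError("focus does not fit")
    bands = _compartment_bands(shape)
    comps = list(bands)
    grid = np.stack(np.meshgrid(*[np.arange(n) * vs for n in shape],
                                indexing="ij"), axis=-1)
    foci: list[tuple[np.ndarray, float, float]] = []
    for f in range(n_foci):
        comp = comps[f % 2]
        k0, k1 = bands[comp]
        zlo, zhi = k0 * vs + r, (k1 - 1) * vs - r
        if zhi < zlo:
            raise ValueError("focus does not fit")
        center = np.array([rng.uniform(r, e - vs - r) for e in extent[:2]]
                          + [rng.uniform(zlo, zhi)])
        peak = rng.uniform(2.0, 8.0)
        foci.append((center, r, peak))
        d = np.linalg.norm(grid - center, axis=-1)
        blob = np.where(d < r, peak * (1.0 - d / r), 0.0)
        values = np.maximum(values, blob.astype(np.float32))
    bg = values == 0
    n_neg = int(round(cfg.negative_voxel_fraction * bg.sum()))
    if n_neg:
        flat = np.flatnonzero(bg.ravel())
        pick = rng.choice(flat, size=n_neg, replace=False)
        neg = -np.abs(rng.normal(0.0, 1.0, size=n_neg)).astype(np.float32)
        values.ravel()[pick] = neg
    return TermMap(values=values, affine=affine, foci=foci)


def generate_donor_samples(cfg: SyntheticConfig, tmap: TermMap,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Place each donor's sample points on voxel centers.

    Per donor and compartment, voxels are drawn without replacement,
    stratified so that at least the configured fraction (default one half)
    fall inside strictly positive map voxels. Region labels partition each
    compartment into 2x2x2 spatial blocks shared by all donors.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "samples")
    shape = tmap.shape
    n = cfg.n_samples_per_donor_per_compartment
    cols = ["sample_id", "donor_id", "x_mm", "y_mm", "z_mm",
            "compartment", "region_label"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    bands = _compartment_bands(shape)
    ijk_all = np.indices(shape).reshape(3, -1).T
    pos_mask = (tmap.values > 0).ravel()
    rows = []
    for d in range(cfg.n_donors):
        donor = f"D{d + 1}"
        counter = 0
        for comp, (k0, k1) in bands.items():
            in_band = (ijk_all[:, 2] >= k0) & (ijk_all[:, 2] < k1)
            band_idx = np.flatnonzero(in_band)
            pos_idx = band_idx[pos_mask[band_idx]]
            non_idx = band_idx[~pos_mask[band_idx]]
            n_pos = math.ceil(n * cfg.positive_sample_fraction)
            n_non = n - n_pos
            if n_pos > len(pos_idx) or n_non > len(non_idx):
                raise ValueError("requested samples exceed available voxels")
            take = np.concatenate([
                rng.choice(pos_idx, size=n_pos, replace=False),
                rng.choice(non_idx, size=n_non, replace=False)])
            ijk = ijk_all[take]
            xyz = tmap.voxel_to_mm(ijk)
            # 2x2x2 block labels inside the compartment
            bx = (ijk[:, 0] * 2) // shape[0]
            by = (ijk[:, 1] * 2) // shape[1]
            bz = ((ijk[:, 2] - k0) * 2) // max(k1 - k0, 1)
            for m in range(len(take)):
                rows.append((f"{donor}.{counter:04d}", donor,
                             xyz[m, 0], xyz[m, 1], xyz[m, 2], comp,
                             f"{comp[:3]}_{bx[m]}{by[m]}{bz[m]}"))
                counter += 1
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# expression

def _nearest_voxel(tmap: TermMap, xyz: np.ndarray) -> np.ndarray:
    v = tmap.mm_to_voxel_float(xyz)
    return np.trunc(v + np.copysign(0.5, v)).astype(int)


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _generate_expression(cfg: SyntheticConfig, samples: pd.DataFrame,
                         maps: Mapping[str, TermMap], truth: PlantedTruth,
                         rng: np.random.Generator) -> dict[str, ProbeMatrix]:
    universe = truth.gene_ids
    n_genes = len(universe)
    gene_pos = {g: i for i, g in enumerate(universe)}
    # gene x compartment baselines, shared across donors
    baselines = rng.normal(0.0, 2.0, size=(n_genes, 2))
    comp_idx = {"subcortical": 0, "cortical": 1}
    planted_rows = {func: {
        +1: np.array([gene_pos[g] for g in truth.planted_genes(func, +1)], int),
        -1: np.array([gene_pos[g] for g in truth.planted_genes(func, -1)], int),
    } for func in truth.functions}
    null_rows = np.array([gene_pos[g] for g in universe
                          if g not in truth.planted], int)
    ga = cfg.gradient_amplitude

    out: dict[str, ProbeMatrix] = {}
    for donor in samples["donor_id"].unique():
        sub = samples[samples["donor_id"] == donor]
        n_s = len(sub)
        G = np.zeros((n_genes, n_s))
        for comp in sub["compartment"].unique():
            sel = (sub["compartment"] == comp).to_numpy()
            coords = sub.loc[sel, ["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            k = sel.sum()
            for func, tmap in maps.items():
                vox = _nearest_voxel(tmap, coords)
                z = tmap.values[vox[:, 0], vox[:, 1], vox[:, 2]].astype(float)
                z_std = _standardize(z[None, :])[0] if k > 1 else np.zeros(k)
                for sign in (+1, -1):
                    rows = planted_rows[func][sign]
                    if len(rows) == 0:
                        continue
                    rho = np.array([truth.planted[universe[i]][2] for i in rows])
                    eps = rng.normal(0.0, cfg.noise_sd, size=(len(rows), k))
                    block = (sign * rho[:, None] * z_std[None, :]
                             + np.sqrt(1.0 - rho[:, None] ** 2) * eps)
                    cols = np.flatnonzero(sel)
                    G[np.ix_(rows, cols)] = block
            if len(null_rows):
                proj = truth.gradients[null_rows] @ coords.T
                s = _standardize(proj) if k > 1 else np.zeros_like(proj)
                eps = rng.normal(0.0, cfg.noise_sd, size=(len(null_rows), k))
                block = ga * s + math.sqrt(max(1.0 - ga ** 2, 0.0)) * eps
                cols = np.flatnonzero(sel)
                G[np.ix_(null_rows, cols)] = block
            G[:, sel] += baselines[:, [comp_idx[comp]]]
        # expand genes to probes
        P = cfg.probes_per_gene
        probe_ids = [f"{g}_p{j}" for g in universe for j in range(1, P + 1)]
        probe_sd = np.array([cfg.probe_noise_winner if j == 1
                             else cfg.probe_noise_decoy
                             for _ in universe for j in range(1, P + 1)])
        values = np.repeat(G, P, axis=0)
        if probe_sd.max() > 0:
            values = values + rng.normal(0.0, 1.0, size=values.shape) * probe_sd[:, None]
        p_above = np.array([cfg.dark_p_above if pid in truth.dark_probes
                            else cfg.background_p_above for pid in probe_ids])
        flags = (rng.random(values.shape) < p_above[:, None]).astype(np.int8)
        cols = sub["sample_id"].tolist()
        out[donor] = ProbeMatrix(
            donor_id=donor,
            values=pd.DataFrame(values, index=probe_ids, columns=cols),
            probe_to_gene=pd.Series({pid: pid.rsplit("_p", 1)[0]
                                     for pid in probe_ids}),
            above_background=pd.DataFrame(flags, index=probe_ids, columns=cols),
        )
    return out


def generate_expression(cfg: SyntheticConfig, samples: pd.DataFrame,
                        tmap: TermMap, truth: PlantedTruth,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, ProbeMatrix]:
    """Probe-level expression for a single-function study."""
    rng = rng if rng is not None else stage_rng(cfg.seed, "expression")
    return _generate_expression(cfg, samples, {truth.functions[0]: tmap},
                                truth, rng)


# ---------------------------------------------------------------------------
# gene sets, pools, evidence

def generate_gene_sets(cfg: SyntheticConfig, truth: PlantedTruth,
                       rng: np.random.Generator | None = None,
                       size_range: tuple[int, int] = (15, 50),
                       planted_size_range: tuple[int, int] = (15, 30),
                       ) -> dict[str, list[str]]:
    """Gene-set library with planted enriched sets.

    Planted sets draw a fraction ``planted_set_fraction`` of their members
    from the planted pool of one (function, sign); null sets are uniform
    draws from the universe. Membership is recorded in ``truth.planted_sets``
    and every planted gene is guaranteed to appear in at least one planted
    set of its sign.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "gene_sets")
    universe = np.array(truth.gene_ids)
    if size_range[1] > len(universe):
        raise ValueError("set size exceeds gene universe")
    specs: list[tuple[str | None, int, list[str]]] = []
    for func in truth.functions:
        for j in range(cfg.n_planted_sets):
            sign = +1 if j % 2 == 0 else -1
            pool = truth.planted_genes(func, sign)
            size = int(rng.integers(planted_size_range[0],
                                    planted_size_range[1] + 1))
            k_p = min(int(round(cfg.planted_set_fraction * size)), len(pool))
            members = list(rng.choice(pool, size=k_p, replace=False))
            others = [g for g in universe if g not in truth.planted]
            members += list(rng.choice(others, size=size - k_p, replace=False))
            specs.append((func, sign, members))
    n_null = cfg.n_gene_sets - cfg.n_planted_sets * len(truth.functions)
    for _ in range(max(n_null, 0)):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        specs.append((None, 0, members))
    # cover any planted gene missed by the draws
    covered: dict[tuple[str, int], set[str]] = {}
    for func, sign, members in specs:
        if func is not None:
            covered.setdefault((func, sign), set()).update(members)
    for func in truth.functions:
        for sign in (+1, -1):
            missing = [g for g in truth.planted_genes(func, sign)
                       if g not in covered.get((func, sign), set())]
            targets = [i for i, (f, s, _) in enumerate(specs)
                       if f == func and s == sign]
            if not targets:       # no planted set of this sign configured
                continue
            for g in missing:
                specs[int(rng.choice(targets))][2].append(g)
    order = rng.permutation(len(specs))
    sets: dict[str, list[str]] = {}
    for new_id, old in enumerate(order):
        func, sign, members = specs[old]
        sid = f"S{new_id:03d}"
        members = list(dict.fromkeys(members))
        sets[sid] = [members[i] for i in rng.permutation(len(members))]
        if func is not None:
            truth.planted_sets[sid] = (func, sign)
    return sets


def generate_evidence_table(cfg: SyntheticConfig, truth: PlantedTruth,
                            rng: np.random.Generator | None = None,
                            functions: Sequence[str] = ("memory", "motor"),
                            ) -> pd.DataFrame:
    """Binary strong/weak literature-evidence flags consistent with pools.

    Each function's known-gene pool is its planted genes topped up with
    random non-planted genes. Pool members receive at most one of a strong
    or weak flag for that function (planted genes preferentially strong);
    genes outside a pool carry no flags for it.
    """
    rng = rng if rng is not None else stage_rng(cfg.seed, "evidence")
    universe = truth.gene_ids
    non_planted = [g for g in universe if g not in truth.planted]
    ev = pd.DataFrame(0, index=pd.Index(universe, name="gene_id"),
                      columns=[f"{f}_{w}" for f in functions
                               for w in ("strong", "weak")], dtype=int)
    for func in functions:
        planted = truth.planted_genes(func)
        extras_needed = max(cfg.pool_size - len(planted), 0)
        extras = list(rng.choice(non_planted, size=min(extras_needed,
                                                       len(non_planted)),
                                 replace=False))
        pool = planted + extras
        truth.pools[func] = sorted(pool)
        for g in pool:
            ps, pw = (0.6, 0.3) if g in truth.planted else (0.35, 0.35)
            u = rng.random()
            if u < ps:
                ev.loc[g, f"{func}_strong"] = 1
            elif u < ps + pw:
                ev.loc[g, f"{func}_weak"] = 1
    return ev


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticDataset:
    """Everything the discovery pipeline consumes, plus the planted truth."""

    cfg: SyntheticConfig
    maps: dict[str, TermMap]
    samples: pd.DataFrame
    probes: dict[str, ProbeMatrix]
    gene_sets: dict[str, list[str]]
    truth: PlantedTruth
    evidence: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        from . import io as bio
        bio.write_dataset(self, Path(outdir))


def simulate_study(cfg: SyntheticConfig) -> SyntheticDataset:
    """One-function study: map, samples, expression, sets, evidence."""
    truth = make_truth(cfg)
    tmap = generate_term_map(cfg)
    samples = generate_donor_samples(cfg, tmap)
    probes = generate_expression(cfg, samples, tmap, truth)
    sets = generate_gene_sets(cfg, truth)
    evidence = generate_evidence_table(cfg, truth,
                                       functions=(cfg.function, "motor")
                                       if cfg.function != "motor"
                                       else ("memory", cfg.function))
    return SyntheticDataset(cfg=cfg, maps={cfg.function: tmap},
                            samples=samples, probes=probes, gene_sets=sets,
                            truth=truth, evidence=evidence)


def simulate_dual_study(cfg: SyntheticConfig,
                        functions: tuple[str, str] = ("memory", "motor")
                        ) -> SyntheticDataset:
    """Two-function study sharing donors, samples and the gene universe.

    Each function gets its own term map and its own disjoint planted genes
    and planted sets. Sample placement is stratified on the union of the two
    maps' positive voxels so both analyses retain usable points.
    """
    truth = make_truth(cfg, functions=functions)
    map_a = generate_term_map(cfg, rng=stage_rng(cfg.seed, "map"))
    map_b = generate_term_map(cfg, rng=stage_rng(cfg.seed, "map_motor"))
    union = TermMap(values=np.maximum(map_a.values, map_b.values),
                    affine=map_a.affine)
    samples = generate_donor_samples(cfg, union)
    probes = _generate_expression(cfg, samples,
                                  {functions[0]: map_a, functions[1]: map_b},
                                  truth, stage_rng(cfg.seed, "expression"))
    sets = generate_gene_sets(cfg, truth)
    evidence = generate_evidence_table(cfg, truth, functions=functions)
    return SyntheticDataset(cfg=cfg,
                            maps={functions[0]: map_a, functions[1]: map_b},
                            samples=samples, probes=probes, gene_sets=sets,
                            truth=truth, evidence=evidence)
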