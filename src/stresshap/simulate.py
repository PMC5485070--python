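"""Synthetic accession panels with known ground truth.

The generator emulates the statistical structure of a European Arabidopsis
accession panel subjected to seven stress assays:

* **Isolation by distance.**  Demes are scattered over a European-scale
  lon/lat box; per-marker deme allele frequencies drift from a common
  ancestral frequency with spatially correlated perturbations, so nearby
  demes stay similar.  Accessions draw haploid 0/1 calls from their deme's
  frequencies and sit at jittered deme coordinates.
* **Additive trait architecture.**  Seven stress-response traits receive
  additive genetic values drawn from ``N(0, Vg (x) K)`` where K is the
  realized kinship of the simulated genotypes and Vg encodes per-trait
  additive variances (from target narrow-sense heritabilities) and
  genetic correlations (trade-offs).
* **Life cycle.**  A winter/summer annual label arises from a probit on
  standardized latitude (+) and elevation (-) plus a kinship-structured
  genetic liability; per-trait winter-annual effects with the observed sign
  pattern (winter annuals more drought/aphid/thrips-resistant, summer
  annuals more caterpillar-resistant) shift the traits.
* **Bioassay layout.**  Per-plant tables for the four experiments are
  produced by inverting the percentage-reduction definition around a
  log-normal baseline rosette weight and adding block/rack/shelf/tray and
  within-tray positional random effects plus residual noise.

All randomness flows from a single seed; identical truth objects give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioassay import RESPONSE_COLUMNS
from .genotypes import GenotypeMatrix, GeoRecord
from .kinship import KinshipMatrix, compute_kinship

__all__ = ["SimulationTruth", "SimulatedData", "simulate_genotypes_ibd",
           "simulate_phenotypes", "simulate_dataset"]


def _default_h2() -> dict[str, float]:
    return dict(zip(RESPONSE_COLUMNS, [0.41, 0.60, 0.39, 0.67, 0.25, 0.90, 0.34]))


def _default_total_var() -> dict[str, float]:
    return dict(zip(RESPONSE_COLUMNS,
                    [203.28, 191.51, 249.67, 286.24, 381.33, 85.74, 31.15]))


def _default_means() -> dict[str, float]:
    return dict(zip(RESPONSE_COLUMNS,
                    [19.22, 32.40, 48.25, 14.42, 14.15, 21.98, 27.89]))


def _default_lc_effects() -> dict[str, float]:
    # effect of the winter-annual state on each response
    return dict(zip(RESPONSE_COLUMNS,
                    [-9.21, 4.61, 7.37, 10.68, 10.40, -3.50, -1.75]))


def _default_genetic_corr() -> np.ndarray:
    C = np.eye(len(RESPONSE_COLUMNS))
    idx = {t: i for i, t in enumerate(RESPONSE_COLUMNS)}
    # trade-offs: drought vs P. rapae, P. rapae vs aphids
    C[idx["Drought"], idx["P_rapae"]] = C[idx["P_rapae"], idx["Drought"]] = -0.2
    C[idx["P_rapae"], idx["M_persicae"]] = C[idx["M_persicae"], idx["P_rapae"]] = -0.3
    return C


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one simulated panel."""

    seed: int = 7
    n_accessions: int = 240
    n_markers: int = 3000
    n_demes: int = 8
    drift_scale: float = 1.2          # logit-scale SD of deme drift
    spatial_range: float = 8.0        # degrees; correlation length of drift
    coord_jitter: float = 0.8         # degrees of accession scatter per deme
    h2: dict[str, float] = field(default_factory=_default_h2)
    total_var: dict[str, float] = field(default_factory=_default_total_var)
    trait_means: dict[str, float] = field(default_factory=_default_means)
    life_cycle_effects: dict[str, float] = field(default_factory=_default_lc_effects)
    genetic_corr: np.ndarray = field(default_factory=_default_genetic_corr)
    winter_fraction: float = 0.29     # 89 of 308 accessions
    lc_latitude_effect: float = 1.0   # probit slope on standardized latitude
    lc_elevation_effect: float = -0.6
    lc_genetic_sd: float = 0.7
    # bioassay layout and noise
    exp1_reps: int = 6
    exp1_blocks: int = 10
    exp1_racks: int = 6
    exp1_shelves: int = 4
    tray_nx: int = 4
    tray_ny: int = 6
    exp2_blocks: int = 4
    exp2_trays_per_block: int = 40
    exp2_dropout: float = 0.14        # accessions lost to germination failure
    exp3_blocks: int = 5
    exp3_sub_blocks: int = 4
    exp4_blocks: int = 3
    exp4_sub_blocks: int = 4
    exp4_reps: int = 3
    baseline_weight_g: float = 10.0
    baseline_weight_sdlog: float = 0.1
    block_sd: float = 1.0
    rack_sd: float = 0.3
    shelf_sd: float = 0.3
    brs_sd: float = 0.3
    tray_sd: float = 0.3
    tray_x_sd: float = 0.15
    tray_y_sd: float = 0.15
    residual_sd: float = 0.8          # per-plant residual, weight scale
    exp34_block_sd: float = 1.5
    exp34_sub_block_sd: float = 1.0
    exp34_residual_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_accessions < 10 or self.n_markers < 100:
            raise ValueError("need n_accessions >= 10 and n_markers >= 100")
        for t, h in self.h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2[{t}] = {h} outside [0, 1]")
        C = np.asarray(self.genetic_corr, dtype=float)
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError("genetic correlation matrix is not PSD")
        self.genetic_corr = C

    def zero_noise(self) -> "SimulationTruth":
        """Copy with all bioassay noise components set to zero."""
        return replace(
            self, block_sd=0.0, rack_sd=0.0, shelf_sd=0.0, brs_sd=0.0,
            tray_sd=0.0, tray_x_sd=0.0, tray_y_sd=0.0, residual_sd=0.0,
            baseline_weight_sdlog=0.0, exp34_block_sd=0.0,
            exp34_sub_block_sd=0.0, exp34_residual_sd=0.0,
        )


def study_like_truth(seed: int = 7, **overrides) -> SimulationTruth:
    """Preset mirroring the 308-accession European panel with ten demes."""
    params = dict(seed=seed, n_accessions=308, n_markers=3000, n_demes=10)
    params.update(overrides)
    return SimulationTruth(**params)


@dataclass
class SimulatedData:
    truth: SimulationTruth
    genotypes: GenotypeMatrix
    geo: list[GeoRecord]
    kinship: KinshipMatrix
    bioassays: dict[int, pd.DataFrame]
    life_cycle: pd.DataFrame
    responses_true: pd.DataFrame
    genetic_values: pd.DataFrame


# ---------------------------------------------------------------------------
# Genotypes under isolation by distance
# ---------------------------------------------------------------------------

def simulate_genotypes_ibd(
    truth: SimulationTruth,
) -> tuple[GenotypeMatrix, list[GeoRecord]]:
    """Deme-structured genotypes plus jittered collection coordinates.

    Monomorphic markers (possible at small panel sizes) are dropped, so the
    returned matrix may have slightly fewer than ``n_markers`` columns.
    """
    rng = np.random.default_rng(truth.seed)
    D, m, n = truth.n_demes, truth.n_markers, truth.n_accessions
    deme_lon = rng.uniform(-10.0, 30.0, D)
    deme_lat = rng.uniform(36.0, 62.0, D)
    pts = np.column_stack([deme_lon, deme_lat])
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-dist / truth.spatial_range) + 1e-8 * np.eye(D)
    L = np.linalg.cholesky(cov)
    p0 = rng.uniform(0.08, 0.92, m)
    logit0 = np.log(p0 / (1.0 - p0))
    drift = truth.drift_scale * (L @ rng.standard_normal((D, m)))
    deme_freq = 1.0 / (1.0 + np.exp(-(logit0[None, :] + drift)))
    deme_of = np.arange(n) % D
    calls = (rng.random((n, m)) < deme_freq[deme_of]).astype(np.int8)
    poly = (calls.mean(0) > 0) & (calls.mean(0) < 1)
    calls = calls[:, poly]
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j:05d}" for j in range(int(poly.sum()))],
            "chromosome": (np.flatnonzero(poly) % 5 + 1).astype(str),
            "position": np.flatnonzero(poly) // 5 * 1000 + 1,
        }
    )
    accession_ids = [f"acc{i:04d}" for i in range(n)]
    geno = GenotypeMatrix(accession_ids=accession_ids, markers=markers, calls=calls)
    lon = deme_lon[deme_of] + rng.normal(0, truth.coord_jitter, n)
    lat = deme_lat[deme_of] + rng.normal(0, truth.coord_jitter, n)
    elev = np.clip(rng.normal(400, 350, n), 0.0, 1990.0)
    geo = [
        GeoRecord(a, float(np.clip(la, -90, 90)), float(np.clip(lo, -180, 180)),
                  float(e))
        for a, la, lo, e in zip(accession_ids, lat, lon, elev)
    ]
    return geno, geo


# ---------------------------------------------------------------------------
# Phenotypes and bioassay tables
# ---------------------------------------------------------------------------

def _partition(ids: list[str], k: int) -> dict[str, int]:
    return {a: i % k for i, a in enumerate(ids)}


def simulate_phenotypes(
    geno: GenotypeMatrix,
    geo: list[GeoRecord],
    truth: SimulationTruth,
    experiments: tuple[int, ...] = (1, 2, 3, 4),
) -> SimulatedData:
    """Generate life-cycle labels, true responses and per-plant bioassays."""
    rng = np.random.default_rng(truth.seed + 1)
    ids = list(geno.accession_ids)
    n = len(ids)
    traits = RESPONSE_COLUMNS
    T = len(traits)

    kin = compute_kinship(geno, estimator="standardized")
    Lk = np.linalg.cholesky(kin.K + 1e-8 * np.eye(n))

    sd_g = np.array([np.sqrt(truth.h2[t] * truth.total_var[t]) for t in traits])
    Cg = truth.genetic_corr
    Vg_chol = np.linalg.cholesky(
        np.diag(sd_g) @ Cg @ np.diag(sd_g) + 1e-10 * np.eye(T)
    )
    G = Lk @ rng.standard_normal((n, T)) @ Vg_chol.T
    genetic_values = pd.DataFrame(G, index=ids, columns=traits)

    # life cycle: probit on geography plus genetic liability
    lat = np.array([g.latitude for g in geo])
    elev = np.array([g.elevation for g in geo])
    zlat = (lat - lat.mean()) / lat.std()
    zelev = (elev - elev.mean()) / elev.std()
    liab = (
        truth.lc_latitude_effect * zlat
        + truth.lc_elevation_effect * zelev
        + truth.lc_genetic_sd * (Lk @ rng.standard_normal(n))
        + rng.standard_normal(n)
    )
    cut = np.quantile(liab, 1.0 - truth.winter_fraction)
    winter = liab > cut

    flowering = np.where(
        winter, 75.0 + rng.exponential(25.0, n), rng.uniform(25.0, 74.0, n)
    )
    censored = winter & (rng.random(n) < 0.3)
    flowering = np.where(censored, np.nan, flowering)
    after_vern = rng.uniform(20.0, 60.0, n)
    life_cycle = pd.DataFrame(
        {
            "flowering_time_days": flowering,
            "flowering_time_after_vernalization_days": after_vern,
            "censored": censored,
            "strategy": np.where(winter, "winter", "summer"),
        },
        index=pd.Index(ids, name="accession_id"),
    )

    resp = {}
    for j, t in enumerate(traits):
        ve = (1.0 - truth.h2[t]) * truth.total_var[t]
        e = rng.normal(0.0, np.sqrt(ve), n)
        resp[t] = (
            truth.trait_means[t]
            + truth.life_cycle_effects[t] * winter.astype(float)
            + G[:, j]
            + e
        )
    responses = pd.DataFrame(resp, index=pd.Index(ids, name="accession_id"))
    # damage areas and counts cannot be negative
    responses["F_occidentalis"] = responses["F_occidentalis"].clip(lower=0.0)
    responses["M_persicae"] = responses["M_persicae"].clip(lower=0.0)

    bioassays: dict[int, pd.DataFrame] = {}
    if 1 in experiments:
        bioassays[1] = _experiment1(rng, ids, responses, truth)
    if 2 in experiments:
        bioassays[2] = _experiment2(rng, ids, responses, truth)
    if 3 in experiments:
        bioassays[3] = _experiment34(rng, ids, responses["F_occidentalis"], truth,
                                     experiment=3)
    if 4 in experiments:
        bioassays[4] = _experiment34(rng, ids, responses["M_persicae"], truth,
                                     experiment=4)
    return SimulatedData(
        truth=truth,
        genotypes=geno,
        geo=geo,
        kinship=kin,
        bioassays=bioassays,
        life_cycle=life_cycle,
        responses_true=responses,
        genetic_values=genetic_values,
    )


def _treatment_weights(W0: float, row: pd.Series) -> dict[str, float]:
    wd = W0 * (1.0 - row["Drought"] / 100.0)
    return {
        "control": W0,
        "drought": wd,
        "p_rapae": W0 * (1.0 - row["P_rapae"] / 100.0),
        "drought_pieris": wd * (1.0 - row["Drought_Pieris"] / 100.0),
        "botrytis_pieris": W0 * (1.0 - row["Botrytis_Pieris"] / 100.0),
    }


def _experiment1(rng, ids, responses, truth) -> pd.DataFrame:
    # accessions are partitioned over temporal blocks; a fixed set of three
    # calibration accessions recurs in every block so that block effects are
    # separable from genotype effects
    calib = ids[: min(3, len(ids))]
    block_of = _partition(ids, truth.exp1_blocks)
    eff = {
        "B": rng.normal(0, truth.block_sd, truth.exp1_blocks),
        "R": rng.normal(0, truth.rack_sd, truth.exp1_racks),
        "S": rng.normal(0, truth.shelf_sd, truth.exp1_shelves),
    }
    brs_eff: dict[tuple, float] = {}
    tray_eff: dict[tuple, float] = {}
    tx_eff: dict[tuple, float] = {}
    ty_eff: dict[tuple, float] = {}
    rows = []
    capacity = truth.tray_nx * truth.tray_ny
    counters: dict[int, int] = {}
    W0 = {
        a: truth.baseline_weight_g
        * np.exp(rng.normal(0.0, truth.baseline_weight_sdlog))
        for a in ids
    }
    plant = 0
    members: dict[int, list[str]] = {b: [] for b in range(truth.exp1_blocks)}
    for a in ids:
        members[block_of[a]].append(a)
    for b in range(truth.exp1_blocks):
        block_ids = members[b] + [c for c in calib if block_of[c] != b]
        for a in block_ids:
            tw = _treatment_weights(W0[a], responses.loc[a])
            for trt, w in tw.items():
                for _ in range(truth.exp1_reps):
                    slot = counters.get(b, 0)
                    counters[b] = slot + 1
                    tray_idx = slot // capacity
                    within = slot % capacity
                    x = within % truth.tray_nx + 1
                    y = within // truth.tray_nx + 1
                    r = tray_idx % truth.exp1_racks
                    s = (tray_idx // truth.exp1_racks) % truth.exp1_shelves
                    t = tray_idx
                    brs = (b, r, s)
                    if brs not in brs_eff:
                        brs_eff[brs] = rng.normal(0, truth.brs_sd)
                    brst = (b, r, s, t)
                    if brst not in tray_eff:
                        tray_eff[brst] = rng.normal(0, truth.tray_sd)
                    kx = brst + (x,)
                    if kx not in tx_eff:
                        tx_eff[kx] = rng.normal(0, truth.tray_x_sd)
                    ky = brst + (y,)
                    if ky not in ty_eff:
                        ty_eff[ky] = rng.normal(0, truth.tray_y_sd)
                    value = (
                        w + eff["B"][b] + eff["R"][r] + eff["S"][s]
                        + brs_eff[brs] + tray_eff[brst] + tx_eff[kx] + ty_eff[ky]
                        + rng.normal(0, truth.residual_sd)
                    )
                    rows.append(
                        (f"p1_{plant:06d}", a, trt, f"B{b}", "", f"R{r}", f"S{s}",
                         f"T{t}", x, y, value)
                    )
                    plant += 1
    return pd.DataFrame(
        rows,
        columns=["plant_id", "accession_id", "treatment", "block", "sub_block",
                 "rack", "shelf", "tray", "x", "y", "value"],
    )


def _experiment2(rng, ids, responses, truth) -> pd.DataFrame:
    keep = [a for a in ids if rng.random() >= truth.exp2_dropout]
    W0 = {
        a: truth.baseline_weight_g
        * np.exp(rng.normal(0.0, truth.baseline_weight_sdlog))
        for a in keep
    }
    rows = []
    plant = 0
    for b in range(truth.exp2_blocks):
        beff = rng.normal(0, truth.block_sd)
        tray_eff = {
            t: rng.normal(0, truth.tray_sd)
            for t in range(truth.exp2_trays_per_block)
        }
        tx_eff: dict[tuple, float] = {}
        ty_eff: dict[tuple, float] = {}
        slot = 0
        capacity = truth.tray_nx * truth.tray_ny
        for a in keep:
            w = {"control": W0[a],
                 "p_xylostella": W0[a] * (1.0 - responses.loc[a, "P_xylostella"] / 100.0)}
            for trt, wv in w.items():
                t = (slot // capacity) % truth.exp2_trays_per_block
                within = slot % capacity
                x = within % truth.tray_nx + 1
                y = within // truth.tray_nx + 1
                slot += 1
                kx, ky = (t, x), (t, y)
                if kx not in tx_eff:
                    tx_eff[kx] = rng.normal(0, truth.tray_x_sd)
                if ky not in ty_eff:
                    ty_eff[ky] = rng.normal(0, truth.tray_y_sd)
                value = (wv + beff + tray_eff[t] + tx_eff[kx] + ty_eff[ky]
                         + rng.normal(0, truth.residual_sd))
                rows.append(
                    (f"p2_{plant:06d}", a, trt, f"B{b}", "", "", "", f"T{t}",
                     x, y, value)
                )
                plant += 1
    return pd.DataFrame(
        rows,
        columns=["plant_id", "accession_id", "treatment", "block", "sub_block",
                 "rack", "shelf", "tray", "x", "y", "value"],
    )


def _experiment34(rng, ids, trait: pd.Series, truth, experiment: int) -> pd.DataFrame:
    # block is the level of replication: one plant per accession per block
    if experiment == 3:
        n_blocks, n_sub = truth.exp3_blocks, truth.exp3_sub_blocks
    else:
        n_blocks, n_sub = truth.exp4_blocks, truth.exp4_sub_blocks
    rows = []
    plant = 0
    for b in range(n_blocks):
        beff = rng.normal(0, truth.exp34_block_sd)
        sub_eff = {s: rng.normal(0, truth.exp34_sub_block_sd) for s in range(n_sub)}
        for i, a in enumerate(ids):
            s = i % n_sub
            value = (trait[a] + beff + sub_eff[s]
                     + rng.normal(0, truth.exp34_residual_sd))
            rows.append(
                (f"p{experiment}_{plant:06d}", a, "", f"B{b}", f"SB{s}", "", "",
                 "", 0, 0, value)
            )
            plant += 1
    return pd.DataFrame(
        rows,
        columns=["plant_id", "accession_id", "treatment", "block", "sub_block",
                 "rack", "shelf", "tray", "x", "y", "value"],
    )


def simulate_dataset(truth: SimulationTruth,
                     experiments: tuple[int, ...] = (1, 2, 3, 4)) -> SimulatedData:
    """Genotypes plus phenotypes in one call."""
    geno, geo = simulate_genotypes_ibd(truth)
    return simulate_phenotypes(geno, geo, truth, experiments=experiments)
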