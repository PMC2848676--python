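"""Synthetic data for the full mesocosm experiment, with known ground truth.

Generates the four raw input streams of the analysis — velocimetry grids,
biofilm community tables, recirculation decay curves and FTICR-MS peak
lists — for six flumes along a flow-heterogeneity gradient, so every
downstream estimator can be validated against the truth it was generated
from.  The built-in design mirrors the experimental system:

* six 40-m flumes with identical mean velocity (7.6 cm/s) and depth
  (6.7 cm) but spatial speed SD rising from 1.6 to 6.3 cm/s;
* four bedform microhabitats sampled on four dates per flume, communities
  assembled from a regional pool of 76 OTUs with a per-flume realized
  richness near 26; the divergence among microhabitat community centers —
  hence the expected beta diversity — grows with the flume's heterogeneity;
* first-order glucose and bulk-DOC decay whose true rates increase with
  heterogeneity;
* 361 DOC compounds shared across all samples whose true compound-specific
  uptake velocity depends linearly on inflow relative intensity, O:C and
  aromaticity, with the inflow-intensity coefficient weakening as
  heterogeneity rises.

One global seed feeds an explicit per-stream, per-flume substream scheme
(`numpy.random.SeedSequence` spawn keys), so any stream can be regenerated
independently and fixed seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import ftms
from .diversity import MICROHABITATS, OtuTable
from .hydro import FlowField
from .uptake import DecaySeries

__all__ = [
    "SynthConfig",
    "gen_flow_field",
    "gen_communities",
    "gen_decay_series",
    "gen_peaklists",
]

# substream identifiers for the SeedSequence spawn keys
_STREAM_FLOW, _STREAM_COMM, _STREAM_DECAY, _STREAM_PEAKS = 0, 1, 2, 3


@dataclass
class SynthConfig:
    """Design parameters of the simulated mesocosm experiment."""

    n_flumes: int = 6
    heterogeneity_levels: tuple[float, ...] = (1.6, 2.54, 3.48, 4.42, 5.36, 6.3)
    mean_velocity: float = 7.6  # cm/s
    mean_depth: float = 6.7  # cm
    flume_length_m: float = 40.0
    n_microhabitats: int = 4
    n_replicates: int = 3  # bedform replicates pooled into one composite sample
    n_dates: int = 4
    otu_pool: int = 76
    n_compounds: int = 361
    # flow grid
    n_nodes: int = 80
    n_timesteps: int = 60
    turbulence_intensity: float = 0.15  # fluctuation RMS / mean speed
    # community assembly
    mean_flume_richness: float = 26.0
    sd_flume_richness: float = 13.0
    divergence_per_het: float = 0.15  # microhabitat-center log-divergence per cm/s of SD_Rxyz
    dirichlet_concentration: float = 1000.0
    # solute uptake truth: k = base + per_het * SD_Rxyz, 1/h
    glucose_k_base: float = 0.15
    glucose_k_per_het: float = 0.05
    doc_k_base: float = 0.04
    doc_k_per_het: float = 0.012
    control_k: float = 0.01  # biofilm-free control (abiotic losses)
    glucose_ages_d: tuple[int, ...] = (12, 18, 23)
    glucose_age_factor: dict = dc_field(default_factory=lambda: {12: 0.8, 18: 1.0, 23: 1.1})
    doc_age_d: int = 24
    glucose_c0: float = 800.0  # nmol/L
    doc_c0: float = 8.0  # mg/L
    recirculation_h: float = 6.0
    n_decay_samples: int = 13  # samples over the recirculation window
    decay_noise_sd: float = 0.02  # relative (multiplicative) error
    # compound-specific uptake truth: vf = b0 + b_rI*rI + b_oc*OC + b_ai*AI + noise
    vf_intercept: float = 0.30  # cm/h
    rI_slope_intercept: float = 160.0  # b_rI at SD_Rxyz = 0, cm/h per unit rI
    rI_slope_per_het: float = -18.0  # weakening of b_rI per cm/s of SD_Rxyz
    oc_coeff: float = 0.25
    ai_coeff: float = -0.15
    vf_noise_sd: float = 0.05  # cm/h
    n_inflow_only: int = 25  # unshared peaks, exercise the shared-set filter
    n_residual_only: int = 14
    seed: int = 0

    def __post_init__(self):
        het = np.asarray(self.heterogeneity_levels, dtype=float)
        if het.size != self.n_flumes:
            raise ValueError("heterogeneity_levels must have one value per flume")
        if np.any(np.diff(het) <= 0):
            raise ValueError("heterogeneity_levels must be strictly increasing")
        for name in ("n_flumes", "n_microhabitats", "n_replicates", "n_dates",
                     "otu_pool", "n_compounds", "n_nodes", "n_timesteps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- substreams --------------------------------------------------------
    def rng(self, stream: int, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, *key)))

    # -- ground truth ------------------------------------------------------
    def decay_k_true(self, solute: str, flume_index: int, age_d: int | None = None,
                     control: bool = False) -> float:
        """True first-order loss rate (1/h) for a solute in one flume."""
        if control:
            return self.control_k
        het = self.heterogeneity_levels[flume_index]
        if solute == "glucose":
            k = self.glucose_k_base + self.glucose_k_per_het * het
            if age_d is not None:
                k *= self.glucose_age_factor[age_d]
            return k
        if solute == "DOC":
            return self.doc_k_base + self.doc_k_per_het * het
        raise ValueError(f"unknown solute: {solute!r}")

    def slope_vs_het(self, flume_index: int) -> float:
        """True coefficient of rI_inflow in the compound-vf model for one flume."""
        return (self.rI_slope_intercept
                + self.rI_slope_per_het * self.heterogeneity_levels[flume_index])


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

def gen_flow_field(cfg: SynthConfig, flume_index: int) -> FlowField:
    """Velocity grid for one flume with exact spatial mean and SD of node speed.

    Node-mean speeds are drawn from a gamma shape (right-skewed, positive —
    a normal cannot keep speeds positive once the SD approaches the mean)
    and affinely standardized to the exact target mean and SD; each node
    then gets a turbulent (u, v, w) time series rescaled so its time-mean
    speed equals the assigned node speed.  A target SD at or above the mean
    velocity is unreachable under non-negativity and raises.
    """
    if not 0 <= flume_index < cfg.n_flumes:
        raise ValueError("flume_index out of range")
    target_sd = float(cfg.heterogeneity_levels[flume_index])
    mean_v = float(cfg.mean_velocity)
    if mean_v <= 0:
        raise ValueError("mean_velocity must be positive")
    if target_sd >= mean_v:
        raise ValueError(
            f"target spatial SD {target_sd} cm/s unreachable with mean "
            f"{mean_v} cm/s under non-negative speeds")
    rng = cfg.rng(_STREAM_FLOW, flume_index)
    n = cfg.n_nodes
    if target_sd == 0.0:
        speeds = np.full(n, mean_v)
    else:
        shape = (mean_v / target_sd) ** 2
        for _ in range(100):
            raw = rng.gamma(shape, target_sd**2 / mean_v, size=n)
            if raw.std(ddof=1) == 0:
                continue
            speeds = mean_v + target_sd * (raw - raw.mean()) / raw.std(ddof=1)
            if speeds.min() > 0:
                break
        else:
            raise RuntimeError("could not realize positive node speeds for target SD")
    # 5 x 5 cm grid over one bedform
    n_y = 5
    n_x = int(np.ceil(n / n_y))
    xy = np.array([(5.0 * (i // n_y), 5.0 * (i % n_y)) for i in range(n)])
    depth = np.clip(cfg.mean_depth + 0.08 * cfg.mean_depth * rng.standard_normal(n),
                    0.2 * cfg.mean_depth, None)
    # per-node mean direction: mostly streamwise with small lateral/vertical parts
    dirs = np.column_stack([np.ones(n),
                            0.1 * rng.standard_normal(n),
                            0.05 * rng.standard_normal(n)])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vel = np.empty((n, cfg.n_timesteps, 3))
    for i in range(n):
        mean_vec = speeds[i] * dirs[i]
        fluct_sd = cfg.turbulence_intensity * speeds[i]
        series = mean_vec + fluct_sd * rng.standard_normal((cfg.n_timesteps, 3))
        r_real = np.linalg.norm(series, axis=1).mean()
        vel[i] = series * (speeds[i] / r_real)  # exact node-mean speed
    return FlowField(node_ids=np.arange(n), xy=xy, depth=depth, velocities=vel)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _regional_pool(cfg: SynthConfig) -> np.ndarray:
    """Ranked regional relative abundances (geometric-series pool)."""
    ranks = np.arange(cfg.otu_pool)
    p = 0.92**ranks
    return p / p.sum()


def gen_communities(cfg: SynthConfig, flume_index: int) -> OtuTable:
    """Relative-abundance table for one flume: microhabitats x dates.

    A per-flume OTU subset (size drawn around the target mean richness) is
    sampled from the regional pool; each microhabitat's community center is
    a log-space perturbation of the flume center whose magnitude grows
    linearly with the flume's heterogeneity level, and composite samples are
    Dirichlet draws around those centers.  With zero divergence all
    microhabitats share one center and expected beta (q=1) approaches 1.
    """
    if not 0 <= flume_index < cfg.n_flumes:
        raise ValueError("flume_index out of range")
    rng = cfg.rng(_STREAM_COMM, flume_index)
    pool = _regional_pool(cfg)
    # microhabitat perturbation directions are a property of the habitat types
    # (same regional pool everywhere); only their magnitude scales with the
    # flume's heterogeneity, so the divergence gradient is structural
    g_pool = cfg.rng(_STREAM_COMM).standard_normal((cfg.n_microhabitats, cfg.otu_pool))
    richness = int(np.clip(round(rng.normal(cfg.mean_flume_richness,
                                            cfg.sd_flume_richness)),
                           4, cfg.otu_pool))
    support = rng.choice(cfg.otu_pool, size=richness, replace=False, p=pool)
    support.sort()
    center = pool[support] / pool[support].sum()
    delta = cfg.divergence_per_het * cfg.heterogeneity_levels[flume_index]
    rows, index = [], []
    for m, habitat in enumerate(MICROHABITATS[: cfg.n_microhabitats]):
        # standardized with abundance weights: the realized (center-weighted)
        # log-space perturbation has magnitude exactly delta whatever taxa
        # the flume drew, so beta rises with delta by construction
        g = g_pool[m, support]
        wmean = center @ g
        wstd = np.sqrt(center @ (g - wmean) ** 2)
        g = (g - wmean) / wstd
        hab_center = center * np.exp(delta * g)
        hab_center /= hab_center.sum()
        for date in range(cfg.n_dates):
            sample = rng.dirichlet(hab_center * cfg.dirichlet_concentration)
            rows.append(sample)
            index.append((flume_index, habitat, date))
    full = np.zeros((len(rows), cfg.otu_pool))
    full[:, support] = np.asarray(rows)
    full /= full.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        full,
        index=pd.MultiIndex.from_tuples(index, names=["flume", "microhabitat", "date"]),
        columns=[f"otu_{i:03d}" for i in range(cfg.otu_pool)],
    )
    return OtuTable(df)


# ---------------------------------------------------------------------------
# decay curves
# ---------------------------------------------------------------------------

def gen_decay_series(k_true: float, c0: float, times_h: np.ndarray,
                     noise_sd: float, seed: int | np.random.Generator,
                     **meta) -> DecaySeries:
    """Exponential decay with multiplicative relative error.

    ``c(t) = c0 * exp(-k t) * (1 + eps)`` with ``eps ~ N(0, noise_sd)`` —
    relative error matches analytical-chemistry practice, where measurement
    scatter scales with concentration.
    """
    if not np.isfinite(k_true):
        raise ValueError("k_true must be finite")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    times_h = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times_h) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = noise_sd * rng.standard_normal(times_h.size) if noise_sd > 0 else 0.0
    conc = c0 * np.exp(-k_true * times_h) * (1.0 + eps)
    return DecaySeries(times_h, conc, **meta)


def gen_flume_decay(cfg: SynthConfig, flume_index: int, solute: str,
                    age_d: int | None = None, control: bool = False) -> DecaySeries:
    """Decay series for one flume/solute/age under the configured truth."""
    k = cfg.decay_k_true(solute, flume_index, age_d=age_d, control=control)
    c0 = cfg.glucose_c0 if solute == "glucose" else cfg.doc_c0
    times = np.linspace(0.0, cfg.recirculation_h, cfg.n_decay_samples)
    # deterministic substream key (Python's hash() is salted per process)
    subkey = ((1 if solute == "glucose" else 2) * 1000
              + (age_d or 0) * 2 + int(control))
    rng = cfg.rng(_STREAM_DECAY, flume_index, subkey)
    return gen_decay_series(k, c0, times, cfg.decay_noise_sd, rng,
                            solute=solute, flume=flume_index, biofilm_age_d=age_d)


# ---------------------------------------------------------------------------
# FTICR-MS peak lists
# ---------------------------------------------------------------------------

def _sample_formulas(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Unique valid CHONS compositions on the assignment grid, with m/z."""
    con = ftms.AssignmentConstraints()
    seen: set[tuple[int, ...]] = set()
    rows = []
    while len(rows) < cfg.n_compounds:
        c = int(rng.integers(6, 41))
        o = int(round(rng.uniform(0.15, 1.0) * c))
        n = int(rng.choice([0, 1, 2, 3], p=[0.55, 0.25, 0.15, 0.05]))
        s = int(rng.random() < 0.08)
        h = int(round(rng.uniform(0.6, 1.9) * c))
        if (h + n) % 2:  # integer DBE for an even-electron neutral
            h += 1
        key = (c, h, o, n, s)
        if key in seen:
            continue
        dbe, oc, hc, ai = ftms.descriptors(c, h, o, n, s)
        if dbe < 0 or not (con.hc_min <= hc <= con.hc_max) or oc > con.oc_max:
            continue
        mass = ftms.exact_mass(c, h, o, n, s)
        if not 150.0 <= mass <= 800.0:
            continue
        seen.add(key)
        rows.append((c, h, o, n, s, mass, mass - ftms.PROTON_MASS, dbe, oc, hc, ai))
    df = pd.DataFrame(rows, columns=["c", "h", "o", "n", "s", "mass", "mz",
                                     "dbe", "oc", "hc", "ai"])
    # keep shared peaks separable at the matching tolerance (>= 3 ppm apart)
    df = df.sort_values("mz").reset_index(drop=True)
    close = np.diff(df["mz"].to_numpy()) / df["mz"].to_numpy()[:-1] < 3e-6
    if close.any():
        df = df.drop(index=(np.nonzero(close)[0] + 1)).reset_index(drop=True)
    return df


def gen_peaklists(cfg: SynthConfig, flume_index: int
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(inflow, residual) FTICR peak lists for one flume.

    The inflow pool (identical across flumes) carries ``n_compounds`` shared
    compounds with right-skewed (lognormal) intensities plus a few
    inflow-only peaks.  Each compound's true uptake velocity is

        ``vf = b0 + b_rI * rI_inflow + b_oc * O:C + b_ai * AI + noise``

    with the rI coefficient taken from the flume's ``slope_vs_het`` truth,
    and residual intensities are back-computed by inverting the first-order
    mass-transfer relation ``I_res = I_in * exp(-vf * T / h_bar)``.  Columns
    ``formula_true`` and ``vf_true`` carry the ground truth.
    """
    if not 0 <= flume_index < cfg.n_flumes:
        raise ValueError("flume_index out of range")
    rng_pool = cfg.rng(_STREAM_PEAKS)  # flume-independent: shared inflow pool
    compounds = _sample_formulas(cfg, rng_pool)
    n_c = len(compounds)
    intens = rng_pool.lognormal(mean=0.0, sigma=1.2, size=n_c)
    rI_in = intens / intens.sum()
    formulas = [str(ftms.Formula(int(r.c), int(r.h), int(r.o), int(r.n), int(r.s),
                                 r.mass, 0.0, r.dbe, r.oc, r.hc, r.ai, r.n > 0))
                for r in compounds.itertuples()]

    rng_f = cfg.rng(_STREAM_PEAKS, flume_index + 1)
    b_rI = cfg.slope_vs_het(flume_index)
    noise = (cfg.vf_noise_sd * rng_f.standard_normal(n_c)
             if cfg.vf_noise_sd > 0 else np.zeros(n_c))
    vf_true = (cfg.vf_intercept + b_rI * rI_in + cfg.oc_coeff * compounds["oc"]
               + cfg.ai_coeff * compounds["ai"] + noise).to_numpy()
    res_intens = intens * np.exp(-vf_true * cfg.recirculation_h / cfg.mean_depth)

    inflow = pd.DataFrame({"mz": compounds["mz"], "intensity": intens,
                           "formula_true": formulas, "vf_true": np.nan})
    residual = pd.DataFrame({"mz": compounds["mz"], "intensity": res_intens,
                             "formula_true": formulas, "vf_true": vf_true})

    shared_mz = np.sort(compounds["mz"].to_numpy())

    def _extra(rng: np.random.Generator, k: int) -> pd.DataFrame:
        # keep unshared peaks well away (>= 5 ppm) from every shared compound
        out = np.empty(0)
        while out.size < k:
            mz = rng.uniform(150.0, 900.0, size=2 * k)
            j = np.clip(np.searchsorted(shared_mz, mz), 1, shared_mz.size - 1)
            near = np.minimum(np.abs(mz - shared_mz[j - 1]), np.abs(mz - shared_mz[j]))
            out = np.concatenate([out, mz[near / mz > 5e-6]])[:k]
        return pd.DataFrame({"mz": out, "intensity": rng.lognormal(0.0, 1.0, size=k),
                             "formula_true": "", "vf_true": np.nan})

    if cfg.n_inflow_only:
        inflow = pd.concat([inflow, _extra(rng_pool, cfg.n_inflow_only)],
                           ignore_index=True)
    if cfg.n_residual_only:
        residual = pd.concat([residual, _extra(rng_f, cfg.n_residual_only)],
                             ignore_index=True)
    return (inflow.sort_values("mz", ignore_index=True),
            residual.sort_values("mz", ignore_index=True))
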