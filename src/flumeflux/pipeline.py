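"""Config-driven orchestration of the full mesocosm analysis.

``run`` takes a :class:`RunConfig`, generates (or ingests) the four raw data
streams, executes every analysis stage — hydraulics, diversity
partitioning, uptake kinetics, molecular-formula processing, per-flume
compound-uptake regressions, metavariable dissimilarities, the Mantel /
partial-Mantel table and the causal path model — and writes tidy TSV
outputs plus a JSON manifest.  ``report`` renders a human-readable markdown
summary of the six-flume gradient.

Default metavariable declarations (each a dissimilarity among flumes):

====== =======================================================================
HET    Euclidean on z-scored SD_Rxyz
BETA   Euclidean on z-scored beta diversity (q = 1)
DOCUSE Euclidean on per-flume unit-sum-normalized compound-vf vectors
DOCDIV Euclidean on z-scored {slope(vf ~ rI_inflow), SD(vf)}
DOCMT  Euclidean on z-scored bulk-DOC uptake velocity
GLCMT  Euclidean on z-scored glucose uptake velocities (one column per age)
COMP   Bray-Curtis on flume-pooled OTU relative abundances
====== =======================================================================

The default causal graph regresses beta diversity and glucose mass transfer
on flow heterogeneity, resource-use diversity on heterogeneity plus beta
diversity, and bulk DOC mass transfer on heterogeneity plus resource-use
diversity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diversity, ftms, hydro, matstats, regstats, synth, uptake

__all__ = ["RunConfig", "RunResult", "run", "report"]

log = logging.getLogger("flumeflux")

DEFAULT_DAG: dict[str, tuple[str, ...]] = {
    "BETA": ("HET",),
    "GLCMT": ("HET",),
    "DOCDIV": ("HET", "BETA"),
    "DOCMT": ("HET", "DOCDIV"),
}


@dataclass
class RunConfig:
    """All pipeline parameters; loadable from a flat YAML file."""

    mode: str = "synthetic"  # or "files"
    seed: int = 0
    outdir: str = "flumeflux_out"
    # files mode inputs
    flow_field_paths: tuple[str, ...] = ()
    otu_table_path: str | None = None
    decay_manifest_path: str | None = None  # CSV: path,solute,flume,age_d,control
    inflow_peaks_path: str | None = None
    residual_peaks_paths: tuple[str, ...] = ()
    # analysis parameters
    hill_q: float = 1.0
    mz_tol_ppm: float = 1.0
    assign_tol_ppm: float = 1.0
    intensity_norm: str = "shared_sum"
    docuse_scaling: str = "unit_sum"  # or "zscore"
    mantel_mode: str = "full_enumeration"
    mantel_n_perm: int = 9999
    path_n_perm: int = 10_000
    dag: dict = field(default_factory=lambda: dict(DEFAULT_DAG))
    stages: tuple[str, ...] = ("hydro", "diversity", "uptake", "ftms", "synthesis")
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)

    def __post_init__(self):
        if isinstance(self.synth, dict):
            self.synth = synth.SynthConfig(**self.synth)
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        self.synth.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunResult:
    """Bundle of per-stage tables produced by one pipeline run."""

    config: RunConfig
    hydro_summary: pd.DataFrame | None = None
    diversity_table: pd.DataFrame | None = None
    uptake_table: pd.DataFrame | None = None
    compound_table: ftms.CompoundTable | None = None
    flume_models: pd.DataFrame | None = None
    pooled_communities: pd.DataFrame | None = None
    doc_diversity: pd.DataFrame | None = None
    matrices: dict[str, matstats.DistanceMatrix] = field(default_factory=dict)
    mantel_table: pd.DataFrame | None = None
    path_model: matstats.PathModel | None = None
    upgma_linkage: np.ndarray | None = None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_hydro(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    if cfg.mode == "synthetic":
        fields = [synth.gen_flow_field(cfg.synth, f) for f in range(cfg.synth.n_flumes)]
    else:
        if not cfg.flow_field_paths:
            raise FileNotFoundError("files mode: no flow-field CSVs configured")
        fields = [hydro.read_flow_field(p) for p in cfg.flow_field_paths]
    for f, fld in enumerate(fields):
        s = hydro.flume_summary(fld, cfg.synth.flume_length_m)
        rows.append((f, s.mean_rxyz, s.sd_rxyz, s.mean_depth, s.residence_time_min,
                     fld.n_nodes))
    df = pd.DataFrame(rows, columns=["flume", "mean_Rxyz", "SD_Rxyz", "mean_depth",
                                     "residence_time_min", "n_nodes"])
    log.info("hydro: %d flumes, %d nodes each", len(df), df["n_nodes"].iloc[0])
    return df


def _stage_diversity(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if cfg.mode == "synthetic":
        tables = [synth.gen_communities(cfg.synth, f) for f in range(cfg.synth.n_flumes)]
        table = diversity.OtuTable(pd.concat([t.data for t in tables]))
    else:
        if not cfg.otu_table_path:
            raise FileNotFoundError("files mode: no OTU table configured")
        table = diversity.OtuTable.from_tsv(cfg.otu_table_path)
    rows, pooled_rows = [], []
    for flume, sub in table.data.groupby(level="flume"):
        betas, bcs = [], []
        for date, day in sub.groupby(level="date"):
            part = diversity.partition_diversity(day.to_numpy(), q=cfg.hill_q)
            bc = diversity.mean_pairwise_bc(day.to_numpy())
            betas.append(part.beta)
            bcs.append(bc)
            rows.append((flume, date, cfg.hill_q, part.gamma, part.alpha, part.beta,
                         part.richness_gamma, part.evenness_gamma, part.pielou_gamma, bc))
        pooled = sub.mean(axis=0)
        pooled_rows.append(pd.Series(pooled / pooled.sum(), name=flume))
    per_date = pd.DataFrame(rows, columns=["flume", "date", "q", "gamma", "alpha",
                                           "beta", "richness", "evenness", "pielou",
                                           "mean_bray_curtis"])
    pooled_df = pd.DataFrame(pooled_rows)
    log.info("diversity: %d samples, %d OTUs", len(table.data), table.data.shape[1])
    return per_date, pooled_df


def _stage_uptake(cfg: RunConfig, mean_depths: pd.Series) -> pd.DataFrame:
    rows = []
    if cfg.mode == "synthetic":
        sc = cfg.synth
        runs = []
        for f in range(sc.n_flumes):
            for age in sc.glucose_ages_d:
                runs.append((synth.gen_flume_decay(sc, f, "glucose", age_d=age), False))
            runs.append((synth.gen_flume_decay(sc, f, "glucose", control=True), True))
            runs.append((synth.gen_flume_decay(sc, f, "DOC", age_d=sc.doc_age_d), False))
            runs.append((synth.gen_flume_decay(sc, f, "DOC", control=True), True))
    else:
        if not cfg.decay_manifest_path:
            raise FileNotFoundError("files mode: no decay manifest configured")
        manifest = pd.read_csv(cfg.decay_manifest_path)
        runs = []
        for r in manifest.itertuples():
            series = uptake.DecaySeries.from_csv(
                r.path, solute=r.solute, flume=int(r.flume),
                biofilm_age_d=None if pd.isna(r.age_d) else float(r.age_d))
            runs.append((series, bool(r.control)))
    for series, is_control in runs:
        h_bar = float(mean_depths.get(series.flume, mean_depths.mean()))
        res = uptake.uptake_from_series(series, h_bar_cm=h_bar)
        rows.append((series.flume, series.solute, series.biofilm_age_d, is_control,
                     res.k_per_h, res.vf_cm_h, res.r_squared, res.n))
    df = pd.DataFrame(rows, columns=["flume", "solute", "age_d", "control",
                                     "k_per_h", "vf_cm_h", "r_squared", "n"])
    log.info("uptake: %d decay fits", len(df))
    return df


def _stage_ftms(cfg: RunConfig, mean_depths: pd.Series):
    if cfg.mode == "synthetic":
        sc = cfg.synth
        inflow, _ = synth.gen_peaklists(sc, 0)
        residuals = {f"f{f}": synth.gen_peaklists(sc, f)[1] for f in range(sc.n_flumes)}
    else:
        if not cfg.inflow_peaks_path:
            raise FileNotFoundError("files mode: no inflow peak list configured")
        if not cfg.residual_peaks_paths:
            raise FileNotFoundError("files mode: no residual peak lists configured")
        inflow = pd.read_csv(cfg.inflow_peaks_path)
        residuals = {f"f{i}": pd.read_csv(p)
                     for i, p in enumerate(cfg.residual_peaks_paths)}
    table = ftms.shared_compound_set(inflow, residuals, mz_tol_ppm=cfg.mz_tol_ppm,
                                     intensity_norm=cfg.intensity_norm)
    h_bar = float(mean_depths.mean())
    table = ftms.add_compound_vf(table, h_bar_cm=h_bar,
                                 duration_h=cfg.synth.recirculation_h)
    # formula assignment on the shared set
    assigned = [ftms.assign_formula(mz, tol_ppm=cfg.assign_tol_ppm)
                for mz in table.data["mz"]]
    for col in ("c", "h", "o", "n", "s"):
        table.data[col] = [getattr(f, col) if f else np.nan for f in assigned]
    for col in ("dbe", "oc", "hc", "ai"):
        table.data[col] = [getattr(f, col) if f else np.nan for f in assigned]
    table.data["formula"] = [str(f) if f else "" for f in assigned]
    table.data["neutral_mass"] = [f.neutral_mass if f else np.nan for f in assigned]
    log.info("ftms: %d shared compounds, %d with formulas",
             len(table.data), int(table.data["formula"].astype(bool).sum()))

    # per-flume compound-vf regressions and hierarchical partitioning
    model_rows, part_rows, div_rows = [], [], []
    has_formula = table.data["formula"].astype(bool).to_numpy()
    for label in table.residual_labels:
        vf = table.data[f"vf_{label}"].to_numpy()
        rI = table.data["rI_inflow"].to_numpy()
        simple = regstats.ols(vf, rI[:, None], names=("rI_inflow",), response="vf")
        sub = table.data.loc[has_formula]
        X = sub[["rI_inflow", "oc", "hc", "ai"]].copy()
        X["has_n"] = (sub["n"] > 0).astype(float)
        X["mass"] = sub["neutral_mass"]
        names = tuple(X.columns)
        multi = regstats.ols(sub[f"vf_{label}"].to_numpy(), X.to_numpy(), names=names,
                             response="vf")
        part = regstats.hierarchical_partition(sub[f"vf_{label}"].to_numpy(),
                                               X.to_numpy(), names=names)
        model_rows.append((label, simple.coefficients[0], simple.r_squared,
                           multi.r_squared, float(np.std(vf, ddof=1)))
                          + tuple(multi.coefficients))
        for name, ind, joint in zip(names, part.independent, part.joint):
            part_rows.append((label, name, ind, joint, part.r_squared_full))
        h_res, e_res = ftms.doc_pool_diversity(table.data[f"I_res_{label}"])
        div_rows.append((label, h_res, e_res))
    h_in, e_in = ftms.doc_pool_diversity(table.data["I_inflow"])
    models = pd.DataFrame(model_rows, columns=["flume", "slope_rI", "r2_simple",
                                               "r2_full", "sd_vf",
                                               *(f"b_{n}" for n in names)])
    partition = pd.DataFrame(part_rows, columns=["flume", "predictor", "independent",
                                                 "joint", "r2_full"])
    doc_div = pd.DataFrame(div_rows, columns=["flume", "shannon_residual",
                                              "evenness_residual"])
    doc_div["shannon_inflow"] = h_in
    doc_div["evenness_inflow"] = e_in
    return table, models, partition, doc_div


def _stage_synthesis(cfg: RunConfig, result: RunResult) -> None:
    flumes = result.hydro_summary["flume"].tolist()
    idx = pd.Index(flumes, name="flume")
    beta = (result.diversity_table.groupby("flume")["beta"].mean()
            .reindex(flumes))
    het = result.hydro_summary.set_index("flume")["SD_Rxyz"].reindex(flumes)
    upt = result.uptake_table
    doc_vf = (upt[(upt.solute == "DOC") & ~upt.control]
              .set_index("flume")["vf_cm_h"].reindex(flumes))
    glc = (upt[(upt.solute == "glucose") & ~upt.control]
           .pivot_table(index="flume", columns="age_d", values="vf_cm_h")
           .reindex(flumes))
    models = result.flume_models.reset_index(drop=True)
    vf_cols = [f"vf_{lab}" for lab in result.compound_table.residual_labels]
    vf_mat = result.compound_table.data[vf_cols].to_numpy().T  # flumes x compounds
    if cfg.docuse_scaling == "unit_sum":
        docuse = vf_mat / vf_mat.sum(axis=1, keepdims=True)
    elif cfg.docuse_scaling == "zscore":
        docuse = np.apply_along_axis(regstats.zscore, 1, vf_mat)
    else:
        raise ValueError(f"unknown docuse_scaling: {cfg.docuse_scaling!r}")

    mats = {
        "HET": matstats.metavariable_distance(pd.DataFrame({"SD_Rxyz": het}, index=idx)),
        "BETA": matstats.metavariable_distance(pd.DataFrame({"beta": beta.to_numpy()},
                                                            index=idx)),
        "DOCUSE": matstats.DistanceMatrix(
            tuple(idx), matstats.squareform(
                matstats.pdist(docuse, metric="euclidean"), checks=False)),
        "DOCDIV": matstats.metavariable_distance(
            pd.DataFrame({"slope_rI": models["slope_rI"].to_numpy(),
                          "sd_vf": models["sd_vf"].to_numpy()}, index=idx)),
        "DOCMT": matstats.metavariable_distance(
            pd.DataFrame({"vf_DOC": doc_vf.to_numpy()}, index=idx)),
        "GLCMT": matstats.metavariable_distance(
            glc.set_axis(idx, axis=0).rename(columns=lambda a: f"vf_glc_{a}")),
        "COMP": matstats.metavariable_distance(
            result.pooled_communities.set_axis(idx, axis=0), metric="bray_curtis"),
    }
    result.matrices = mats
    result.mantel_table = matstats.mantel_table(
        mats, control="HET", mode=cfg.mantel_mode, n_perm=cfg.mantel_n_perm,
        seed=cfg.seed)
    involved = sorted({n for n in cfg.dag} | {p for ps in cfg.dag.values() for p in ps})
    result.path_model = matstats.path_significance(
        {k: mats[k] for k in involved}, {k: tuple(v) for k, v in cfg.dag.items()},
        n_perm=cfg.path_n_perm, seed=cfg.seed + 1)
    result.upgma_linkage = matstats.upgma(mats["DOCUSE"])
    log.info("synthesis: %d metavariables, %d Mantel tests",
             len(mats), len(result.mantel_table))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run(cfg: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute all configured stages and write outputs under ``outdir``."""
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(config=cfg)
    try:
        result.hydro_summary = _stage_hydro(cfg)
    except Exception as e:
        raise RuntimeError(f"stage hydro failed: {e}") from e
    depths = result.hydro_summary.set_index("flume")["mean_depth"]
    if "diversity" in cfg.stages:
        try:
            result.diversity_table, result.pooled_communities = _stage_diversity(cfg)
        except Exception as e:
            raise RuntimeError(f"stage diversity failed: {e}") from e
    if "uptake" in cfg.stages:
        try:
            result.uptake_table = _stage_uptake(cfg, depths)
        except Exception as e:
            raise RuntimeError(f"stage uptake failed: {e}") from e
    if "ftms" in cfg.stages:
        try:
            (result.compound_table, result.flume_models,
             flume_partitions, result.doc_diversity) = _stage_ftms(cfg, depths)
        except Exception as e:
            raise RuntimeError(f"stage ftms failed: {e}") from e
        flume_partitions.to_csv(out / "hierarchical_partition.tsv", sep="\t", index=False)
    if "synthesis" in cfg.stages:
        try:
            _stage_synthesis(cfg, result)
        except Exception as e:
            raise RuntimeError(f"stage synthesis failed: {e}") from e

    # outputs
    result.hydro_summary.to_csv(out / "hydro_summary.tsv", sep="\t", index=False)
    if result.diversity_table is not None:
        result.diversity_table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    if result.uptake_table is not None:
        result.uptake_table.to_csv(out / "uptake.tsv", sep="\t", index=False)
    if result.compound_table is not None:
        result.compound_table.to_tsv(out / "compounds.tsv")
        result.flume_models.to_csv(out / "flume_models.tsv", sep="\t", index=False)
        result.doc_diversity.to_csv(out / "doc_diversity.tsv", sep="\t", index=False)
    if result.mantel_table is not None:
        result.mantel_table.to_csv(out / "mantel_table.tsv", sep="\t", index=False)
        for name, m in result.matrices.items():
            m.to_tsv(out / f"dist_{name}.tsv")
        result.path_model.to_edge_list().to_csv(out / "path_edges.tsv", sep="\t",
                                                index=False)
        (out / "path_model.dot").write_text(result.path_model.to_dot())
        pd.DataFrame(result.upgma_linkage,
                     columns=["left", "right", "height", "size"]).to_csv(
            out / "upgma_docuse.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stages": list(cfg.stages),
        "config": _config_dict(cfg),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return clean(d)


def report(result: RunResult) -> str:
    """Markdown summary of the six-flume gradient and synthesis statistics."""
    if result.hydro_summary is None:
        raise ValueError("empty result bundle; run the pipeline first")
    lines = ["# Mesocosm analysis summary", "", "## Flume gradient", ""]
    tab = result.hydro_summary.copy()
    if result.diversity_table is not None:
        tab = tab.merge(result.diversity_table.groupby("flume")["beta"].mean(),
                        on="flume")
    if result.uptake_table is not None:
        doc = result.uptake_table.query("solute == 'DOC' and not control")
        tab = tab.merge(doc[["flume", "vf_cm_h"]].rename(columns={"vf_cm_h": "vf_DOC"}),
                        on="flume", how="left")
    if result.flume_models is not None:
        tab["slope_rI"] = result.flume_models["slope_rI"].to_numpy()
    lines.append(tab.round(3).to_markdown(index=False))
    if result.mantel_table is not None:
        lines += ["", "## Mantel / partial Mantel tests", "",
                  result.mantel_table.round(4).to_markdown(index=False)]
    if result.path_model is not None:
        lines += ["", "## Path model", "",
                  result.path_model.to_edge_list().round(4).to_markdown(index=False)]
    return "\n".join(lines) + "\n"
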