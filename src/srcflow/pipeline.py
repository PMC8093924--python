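"""End-to-end orchestration: simulate -> ersp -> cluster -> connect ->
project -> infer -> stats, from a single :class:`~srcflow.config.RunConfig`.

The pipeline produces a result bundle directory containing TSV tables,
JSON inference results, an optional HDF5 epoch container, the resolved
configuration and a log.  Identical configuration and seed give an
identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import density, ersp, icclust, mvar, permclust, stats, synthio
from .config import RunConfig

__all__ = ["ResultBundle", "run_pipeline"]

log = logging.getLogger("srcflow")


@dataclass
class ResultBundle:
    """In-memory handles to everything a pipeline run produced."""

    config: RunConfig
    output_dir: Path
    cohort: pd.DataFrame | None = None
    trials: dict = field(default_factory=dict)
    epochs: list = field(default_factory=list)
    truth: synthio.GroundTruthNetwork | None = None
    ic_records: list = field(default_factory=list)
    cluster_solution: icclust.ClusterSolution | None = None
    parcellation: density.Parcellation | None = None
    roi_tensors: list = field(default_factory=list)
    subject_roi_weights: np.ndarray | None = None
    included_rois: np.ndarray | None = None
    edges: list = field(default_factory=list)
    inference: list = field(default_factory=list)
    stat_results: pd.DataFrame | None = None


def _stage_guard(name: str):
    def deco(fn):
        def wrapped(bundle, cfg, *a, **kw):
            try:
                return fn(bundle, cfg, *a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage_guard("simulate")
def _run_simulate(bundle: ResultBundle, cfg: RunConfig):
    sim = cfg.simulate
    cohort = synthio.generate_cohort(cfg.cohort.n_hc, cfg.cohort.n_ctd, seed=cfg.seed)
    net = synthio.stable_random_network(
        sim.n_sources,
        order=sim.mvar_order,
        density=sim.coupling_density,
        strength=sim.coupling_strength,
        seed=cfg.seed,
        ensure_edges=(tuple(sim.effect_edge),),
    )
    truth = dataclasses.replace(
        net,
        group_effects=(
            synthio.GroupEffect(
                edge=tuple(sim.effect_edge),
                multiplier=sim.effect_multiplier,
                window_ms=tuple(sim.effect_window_ms),
            ),
        ),
    )
    task = synthio.TaskSpec()
    epochs = []
    trials = {}
    for i, row in cohort.iterrows():
        tr = synthio.generate_trial_table(row, task, seed=cfg.seed * 100_003 + 2 * i)
        ep = synthio.generate_source_epochs(
            row, truth, tr, fs=sim.fs, seed=cfg.seed * 100_003 + 2 * i + 1
        )
        trials[row["subject_id"]] = tr
        epochs.append(ep)
    bundle.cohort = cohort
    bundle.trials = trials
    bundle.epochs = epochs
    bundle.truth = truth

    synthio.save_table(bundle.output_dir / "cohort.tsv", cohort)
    all_tr = pd.concat(
        [t.assign(subject_id=sid) for sid, t in trials.items()], ignore_index=True
    )
    synthio.save_table(bundle.output_dir / "trials.tsv", all_tr)
    if sim.save_epochs:
        synthio.save_epochs(bundle.output_dir / "epochs.h5", epochs)
    log.info("simulated %d subjects x %d sources", len(epochs), sim.n_sources)


@_stage_guard("ersp")
def _run_ersp(bundle: ResultBundle, cfg: RunConfig):
    spec = ersp.BandWindowSpec()
    bundle.ic_records = icclust.ic_records_from_epochs(bundle.epochs, spec)
    rows = []
    band_names = list(spec.bands)
    win_names = list(spec.windows)
    for rec in bundle.ic_records:
        for bi, b in enumerate(band_names):
            for wi, w in enumerate(win_names):
                rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        ic_index=rec.ic_index,
                        band=b,
                        window=w,
                        ersp_db=rec.ersp[bi * len(win_names) + wi],
                    )
                )
    pd.DataFrame(rows).to_csv(
        bundle.output_dir / "ersp_band_means.tsv", sep="\t", index=False
    )
    log.info("ERSP features for %d ICs", len(bundle.ic_records))


@_stage_guard("cluster")
def _run_cluster(bundle: ResultBundle, cfg: RunConfig):
    fm = icclust.build_feature_matrix(bundle.ic_records)
    sol = icclust.kmeans_cluster(
        fm, k=cfg.cluster.k, seed=cfg.seed, n_restarts=cfg.cluster.n_restarts
    )
    sol = icclust.retain_by_subject_coverage(
        sol, n_subjects=len(bundle.cohort), threshold=cfg.cluster.coverage_threshold
    )
    bundle.cluster_solution = sol
    sol.to_tsv(bundle.output_dir / "clusters.tsv")
    cents = {
        int(c): {
            "centroid_mm": icclust.cluster_centroid(sol, c)[0].tolist(),
            "sd_mm": icclust.cluster_centroid(sol, c)[1].tolist(),
            "retained": bool(sol.retained[c]),
            "unique_subject_fraction": float(sol.unique_subject_fraction[c]),
        }
        for c in range(sol.k)
    }
    with open(bundle.output_dir / "cluster_centroids.json", "w") as fh:
        json.dump(cents, fh, indent=1)
    log.info("retained %d/%d clusters", int(sol.retained.sum()), sol.k)


@_stage_guard("connect")
def _run_connect(bundle: ResultBundle, cfg: RunConfig):
    cc = cfg.connect
    freqs = mvar.log_freq_grid(cc.n_freqs, cc.freq_lo, cc.freq_hi)
    bundle.ic_tensors = []
    for ep in bundle.epochs:
        # effective connectivity on correct incongruent trials only
        tr = ep.trial_ref
        mask = (tr["condition"] == "incongruent") & tr["correct"]
        sub = mvar.select_top_ics(ep.select_trials(mask.to_numpy()), cc.top_ics)
        tens = mvar.sliding_connectivity(
            sub,
            window_ms=cc.window_ms,
            step_ms=cc.step_ms,
            freqs=freqs,
            order=cc.order,
        )
        bundle.ic_tensors.append(tens)
    log.info("connectivity tensors for %d subjects", len(bundle.ic_tensors))


@_stage_guard("project")
def _run_project(bundle: ResultBundle, cfg: RunConfig):
    pc = cfg.project
    if pc.parcellation_path:
        parc = density.Parcellation.from_nifti(pc.parcellation_path, pc.label_table_path)
    else:
        parc = density.synthetic_parcellation(pc.n_rois, pc.voxel_mm, seed=cfg.seed)
    bundle.parcellation = parc

    roi_tensors = []
    weights_per_subject = []
    for tens in bundle.ic_tensors:
        W = np.stack(
            [
                density.roi_overlap_weights(
                    density.smooth_dipole(loc, parc, pc.fwhm_mm, pc.n_sigma), parc
                )
                for loc in tens.dipole_mni
            ]
        )
        roi_tensors.append(density.project_to_roi(tens, W))
        weights_per_subject.append(W)
    subj_mass = np.stack([W.sum(axis=0) for W in weights_per_subject])
    included, frac = density.roi_coverage_filter(subj_mass, pc.coverage_threshold)
    for rt in roi_tensors:
        rt.included_rois = included
    bundle.roi_tensors = roi_tensors
    bundle.subject_roi_weights = subj_mass
    bundle.included_rois = included
    bundle._ic_weights = weights_per_subject
    log.info("%d/%d ROIs pass the %d%% coverage filter",
             int(included.sum()), parc.n_rois, round(100 * pc.coverage_threshold))


@_stage_guard("infer")
def _run_infer(bundle: ResultBundle, cfg: RunConfig):
    inc = np.flatnonzero(bundle.included_rois)
    edges = [(int(l), int(f)) for l in inc for f in inc if l != f]
    data = permclust.stack_edge_data(bundle.roi_tensors, edges)
    # drop edges with fewer than 2 subjects per group
    ga = (bundle.cohort["group"] == "CTD").to_numpy()
    keep = []
    for e in range(len(edges)):
        avail = ~np.all(np.isnan(data[:, e].reshape(len(ga), -1)), axis=1)
        if (ga & avail).sum() >= 2 and (~ga & avail).sum() >= 2:
            keep.append(e)
    edges = [edges[e] for e in keep]
    data = data[:, keep]
    ic = cfg.infer
    pcfg = permclust.PermutationConfig(
        n_perm=ic.n_perm,
        alpha_pixel=ic.alpha_pixel,
        alpha_cluster=ic.alpha_cluster,
        u=ic.u,
        scope=ic.scope,
        seed=cfg.seed,
        connectivity=ic.connectivity,
        sign_mode=ic.sign_mode,
    )
    results = permclust.group_cluster_inference(data, ga, edges=edges, cfg=pcfg)
    bundle.edges = edges
    bundle.inference = results

    first = bundle.roi_tensors[0]
    out = []
    for res in results:
        for c in res.clusters:
            fi, ti = np.nonzero(c.pixels)
            out.append(
                dict(
                    edge=list(res.edge),
                    sign=c.sign,
                    mass=c.mass,
                    p=c.p_value,
                    significant=c.significant,
                    freq_hz=[float(first.freqs[fi.min()]), float(first.freqs[fi.max()])],
                    time_ms=[float(first.times[ti.min()]), float(first.times[ti.max()])],
                )
            )
    with open(bundle.output_dir / "inference.json", "w") as fh:
        json.dump({"scope": ic.scope, "clusters": out}, fh, indent=1)
    n_sig = sum(len(r.significant_clusters) for r in results)
    log.info("%d significant cluster(s) over %d edges", n_sig, len(edges))


@_stage_guard("stats")
def _run_stats(bundle: ResultBundle, cfg: RunConfig):
    rows = []
    groups = bundle.cohort["group"].to_numpy()

    # sample characterization
    for col in ("age", "iq"):
        r = stats.two_group_t(bundle.cohort[col].to_numpy(), groups)
        rows.append(("sample", col, r))
    tab = pd.crosstab(bundle.cohort["gender"], bundle.cohort["group"]).to_numpy()
    if tab.shape == (2, 2):
        rows.append(("sample", "gender", stats.chi2_yates(tab)))

    # behavioral ANOVAs per condition and measure
    metrics = {
        sid: stats.behavioral_metrics(tr) for sid, tr in bundle.trials.items()
    }
    sid_order = bundle.cohort["subject_id"].tolist()
    for cond in ("congruent", "incongruent"):
        for meas in ("accuracy_pct", "rt_mean_ms", "rt_sd_ms"):
            vals = np.array([metrics[s].loc[cond, meas] for s in sid_order])
            ok = ~np.isnan(vals)
            r = stats.anova_group(vals[ok], groups[ok])
            r.effect_context = f"{cond} {meas}"
            rows.append(("behavior", f"{cond}:{meas}", r))

    # MANOVA -> ANOVA cascade per retained cluster and window
    sol = bundle.cluster_solution
    if sol is not None and sol.retained is not None:
        spec = ersp.BandWindowSpec()
        band_names = list(spec.bands)
        win_names = list(spec.windows)
        ersp_mat = np.array([rec.ersp for rec in bundle.ic_records])
        grp_of = dict(zip(bundle.cohort["subject_id"], bundle.cohort["group"]))
        for c in np.flatnonzero(sol.retained):
            for wi, w in enumerate(win_names):
                cols = [bi * len(win_names) + wi for bi in range(len(band_names))]
                df = icclust.subject_cluster_means(sol, ersp_mat[:, cols], int(c))
                Y = np.stack(df["value"].to_numpy())
                g = np.array([grp_of[s] for s in df["subject_id"]])
                if min((g == gv).sum() for gv in pd.unique(g)) < Y.shape[1] + 2:
                    continue
                man, follow = stats.manova_then_anovas(Y, g, band_names)
                man.effect_context = f"cluster {c} window {w}: " + man.effect_context
                rows.append(("spectral", f"cluster{c}:{w}:manova", man))
                for r in follow:
                    rows.append(
                        ("spectral", f"cluster{c}:{w}:{r.effect_context}", r)
                    )

    table = pd.DataFrame(
        [
            dict(
                family=fam,
                name=name,
                test=r.test,
                statistic=r.statistic,
                df=str(r.df),
                p=r.p,
                context=r.effect_context,
            )
            for fam, name, r in rows
        ]
    )
    bundle.stat_results = table
    table.to_csv(bundle.output_dir / "stats.tsv", sep="\t", index=False)
    log.info("wrote %d statistical tests", len(table))


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute the configured stages in dependency order.

    Stage failures surface as ``RuntimeError`` naming the stage.  With all
    toggles off, the bundle contains only the resolved configuration.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        bundle = ResultBundle(config=cfg, output_dir=out)
        cfg.to_yaml(out / "resolved_config.yaml")
        st = cfg.stages
        if st.simulate:
            _run_simulate(bundle, cfg)
        if st.ersp and bundle.epochs:
            _run_ersp(bundle, cfg)
        if st.cluster and bundle.ic_records:
            _run_cluster(bundle, cfg)
        if st.connect and bundle.epochs:
            _run_connect(bundle, cfg)
        if st.project and getattr(bundle, "ic_tensors", None):
            _run_project(bundle, cfg)
        if st.infer and bundle.roi_tensors:
            _run_infer(bundle, cfg)
        if st.stats and bundle.cohort is not None:
            _run_stats(bundle, cfg)
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()
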