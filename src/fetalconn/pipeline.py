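"""End-to-end pipeline over a working directory.

Stages (each reads its inputs from, and writes its outputs to, ``workdir``):
simulate -> preprocess -> connect -> infer -> growth -> spectra -> report.
Every table carries the configuration hash in its '#' metadata header, and
all randomness derives from the master seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import triu_pairs, upper_vec
from .atlas import make_default_atlas, scale_atlas
from .cohort import (
    GrowthTruth,
    simulate_cohort,
    stratified_ga_sampler,
    uniform_ga_sampler,
)
from .config import PipelineConfig
from .connectome import build_graph, classify_edges, subnetwork_mean
from .growth import bootstrap_compare, stage_assign, summary_ttest
from .inference import nbs, node_stats, spatial_null_screen
from .io import (
    read_atlas,
    read_json,
    read_matrix,
    read_motion_par,
    read_timeseries,
    write_atlas,
    write_json,
    write_matrix,
    write_motion_par,
    write_timeseries,
)
from .preprocess import preprocess_subject
from .spectral import cohort_mean_coherence

log = logging.getLogger("fetalconn")

SUBNETWORKS = (
    "all",
    "frontal",
    "parietal",
    "occipital",
    "temporal",
    "subcortical",
    "interhemispheric",
    "short",
    "long",
)


def _meta(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.hash(), "fetalconn_version": __version__, "seed": cfg.seed}


def _manifest(workdir) -> pd.DataFrame:
    return pd.read_csv(Path(workdir) / "cohort.tsv", sep="\t", comment="#")


def stage_simulate(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = make_default_atlas(cfg.cohort.n_regions, seed=cfg.cohort.atlas_seed)
    truth = GrowthTruth.default(atlas)
    sampler = (
        stratified_ga_sampler()
        if cfg.cohort.sampler == "stratified"
        else uniform_ga_sampler(cfg.cohort.ga_min, cfg.cohort.ga_max)
    )
    cohort = simulate_cohort(
        atlas,
        truth,
        n_subjects=cfg.cohort.n_subjects,
        noise=cfg.noise,
        seed=cfg.seed,
        ga_sampler=sampler,
    )
    meta = _meta(cfg)
    write_atlas(out / "atlas.tsv", atlas, meta=meta)
    rows = []
    for rec in cohort:
        write_timeseries(out / f"{rec.subject_id}_timeseries.tsv", rec.timeseries, atlas.name, meta)
        write_motion_par(out / f"{rec.subject_id}_motion.par", rec.motion)
        noise_names = [f"noise_{k}" for k in range(rec.noise_channels.shape[1])]
        write_timeseries(out / f"{rec.subject_id}_noise.tsv", rec.noise_channels, noise_names, meta)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "ga_weeks": rec.ga_weeks,
                "ga_days": rec.ga_days,
                "brain_volume_cm3": rec.brain_volume_cm3,
                "tr_s": rec.tr_s,
            }
        )
    pd.DataFrame(rows).to_csv(out / "cohort.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "config_used.yaml")


def stage_preprocess(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    manifest = _manifest(out)
    atlas = read_atlas(out / "atlas.tsv")
    from .cohort import SubjectRecord  # local import avoids a cycle at module load

    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        ts, names = read_timeseries(out / f"{sid}_timeseries.tsv", expect_regions=atlas.name)
        motion = read_motion_par(out / f"{sid}_motion.par")
        noise, _ = read_timeseries(out / f"{sid}_noise.tsv")
        rec = SubjectRecord(
            subject_id=sid,
            ga_weeks=float(row["ga_weeks"]),
            ga_days=int(row["ga_days"]),
            timeseries=ts,
            motion=motion,
            noise_channels=noise,
            brain_volume_cm3=float(row["brain_volume_cm3"]),
            tr_s=float(row.get("tr_s", 1.0)),
        )
        clean = preprocess_subject(rec, cfg.preprocess)
        if not clean.usable:
            raise RuntimeError(f"stage preprocess: subject {sid} unusable (too few frames)")
        write_timeseries(out / f"{sid}_clean.tsv", clean.data, names, _meta(cfg))
        write_json(
            out / f"{sid}_qc.json",
            {
                **clean.qc,
                "confound_names": clean.confound_names,
                "dropped_confounds": clean.dropped_confounds,
                "band_hz": list(clean.band_hz),
                "low_confidence": clean.low_confidence,
                "frame_indices": clean.frame_indices,
                "config_hash": cfg.hash(),
            },
        )


def stage_connect(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    manifest = _manifest(out)
    atlas = read_atlas(out / "atlas.tsv")
    for sid in manifest["subject_id"]:
        data, names = read_timeseries(out / f"{sid}_clean.tsv")
        from .preprocess import CleanedSeries

        clean = CleanedSeries(
            data=data,
            frame_indices=np.arange(data.shape[0]),
            confounds=np.empty((data.shape[0], 0)),
            confound_names=[],
        )
        cm = build_graph(clean, region_names=names)
        write_matrix(out / f"{sid}_Z.tsv", cm.Z, names, _meta(cfg))

    classes = classify_edges(atlas)
    i, j = triu_pairs(atlas.n_regions)
    pd.DataFrame(
        {
            "i": i,
            "j": j,
            "distance_mm": classes.distance_mm[i, j],
            "short": classes.short_mask[i, j].astype(int),
            "long": classes.long_mask[i, j].astype(int),
            "interhemispheric": classes.interhemispheric_mask[i, j].astype(int),
            **{
                f"lobe_{name}": mask[i, j].astype(int)
                for name, mask in sorted(classes.lobe_masks.items())
            },
        }
    ).to_csv(out / "edge_classes.tsv", sep="\t", index=False)


def _load_group(workdir):
    out = Path(workdir)
    manifest = _manifest(out)
    atlas = read_atlas(out / "atlas.tsv")
    z_stack, motion = [], []
    for sid in manifest["subject_id"]:
        z, _ = read_matrix(out / f"{sid}_Z.tsv")
        z_stack.append(z)
        qc = read_json(out / f"{sid}_qc.json")
        motion.append(qc["displacement"]["mean_mm"])
    return manifest, atlas, np.stack(z_stack), np.asarray(motion)


def stage_infer(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    manifest, atlas, z_stack, motion = _load_group(out)
    ga_days = manifest["ga_days"].to_numpy(dtype=float)
    classes = classify_edges(atlas)
    inf = cfg.inference

    retained = spatial_null_screen(
        z_stack,
        classes.distance_mm,
        n_sim=inf.screen_n_sim,
        alpha=inf.screen_alpha,
        seed=cfg.seed + 1,
    )
    result = nbs(
        z_stack,
        ga_days,
        motion,
        threshold_f=inf.threshold_f,
        n_perm=inf.n_perm,
        alpha=inf.alpha,
        seed=cfg.seed + 2,
        edge_mask=retained if inf.screen_first else None,
    )

    i, j = triu_pairs(atlas.n_regions)
    from .inference import EdgeGLM

    glm = EdgeGLM().fit(z_stack, ga_days, motion)
    retained_vec = upper_vec(retained)
    pd.DataFrame(
        {
            "i": i,
            "j": j,
            "F": glm.F_,
            "coef_ga": glm.coef_ga_,
            "coef_motion": glm.coef_motion_,
            "retained": retained_vec.astype(int),
            "significant": upper_vec(result.significant_mask).astype(int),
            "component_id": result.component_labels,
        }
    ).to_csv(out / "edges_stats.tsv", sep="\t", index=False)
    write_json(
        out / "nbs_components.json",
        {
            "extents": result.extents,
            "p_values": result.p_values,
            "threshold_f": result.threshold_f,
            "n_perm": result.n_perm,
            "alpha": result.alpha,
            "n_retained_edges": int(retained_vec.sum()),
            "n_significant_edges": int(upper_vec(result.significant_mask).sum()),
            "node_mean_f": node_stats(glm.F_matrix_),
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
        },
    )


def _subject_strengths(z_stack, mask) -> np.ndarray:
    return np.array([subnetwork_mean(z, mask) for z in z_stack])


def stage_growth(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    manifest, atlas, z_stack, _ = _load_group(out)
    ga_weeks = manifest["ga_weeks"].to_numpy(dtype=float)
    classes = classify_edges(atlas)
    edges = pd.read_csv(out / "edges_stats.tsv", sep="\t", comment="#")
    n = atlas.n_regions
    sig = np.zeros((n, n), dtype=bool)
    sig[edges["i"], edges["j"]] = edges["significant"].astype(bool)
    sig |= sig.T

    gcfg = cfg.growth
    restrict = gcfg.restrict_to_significant
    if restrict and not upper_vec(sig).any():
        log.warning("growth: no significant edges; falling back to unrestricted sub-networks")
        restrict = False
    fit_rows, boot_rows = [], []
    for name in SUBNETWORKS:
        mask = classes.mask(name)
        if restrict:
            mask = mask & sig
        if not upper_vec(mask).any():
            log.warning("growth: sub-network %s has no edges after restriction; skipped", name)
            continue
        y = _subject_strengths(z_stack, mask)
        try:
            summary = bootstrap_compare(
                ga_weeks,
                y,
                n_iter=gcfg.n_iter,
                frac=gcfg.frac,
                seed=cfg.seed + 3,
                robust=gcfg.robust,
                expansion_fraction=gcfg.expansion_fraction,
            )
        except Exception as exc:  # degenerate sub-network: record and move on
            log.warning("growth: sub-network %s fit failed: %s", name, exc)
            continue
        lin = summary.full_fits["linear"]
        sig_fit = summary.full_fits["sigmoid"]
        fit_rows.append(
            {
                "subnetwork": name,
                "n_edges": int(upper_vec(mask).sum()),
                "linear_slope": lin.slope_,
                "linear_intercept": lin.intercept_,
                "linear_r2": lin.r2_,
                "linear_adj_r2": lin.adj_r2_,
                "linear_sse": lin.sse_,
                "sigmoid_a": sig_fit.a_,
                "sigmoid_b": sig_fit.b_,
                "sigmoid_c": sig_fit.c_,
                "sigmoid_d": sig_fit.d_,
                "sigmoid_r2": sig_fit.r2_,
                "sigmoid_adj_r2": sig_fit.adj_r2_,
                "sigmoid_sse": sig_fit.sse_,
                "inflection_gw": summary.inflection_gw,
                "expansion_lo_gw": summary.expansion_interval_gw[0],
                "expansion_hi_gw": summary.expansion_interval_gw[1],
                "preferred_model": summary.preferred_model,
                "comparison_p": summary.p_value,
            }
        )
        for it in range(summary.linear_sse.size):
            boot_rows.append(
                {
                    "subnetwork": name,
                    "iteration": it,
                    "linear_sse": summary.linear_sse[it],
                    "sigmoid_sse": summary.sigmoid_sse[it],
                    "linear_adj_r2": summary.linear_adj_r2[it],
                    "sigmoid_adj_r2": summary.sigmoid_adj_r2[it],
                    "inflection_gw": summary.inflection_samples[it],
                }
            )
    pd.DataFrame(fit_rows).to_csv(out / "growth_fits.tsv", sep="\t", index=False)
    pd.DataFrame(boot_rows).to_csv(out / "bootstrap.tsv", sep="\t", index=False)

    # Stage table: per developmental stage, strength over significant edges and
    # mean region-to-region distance at age-scaled coordinates.
    stages = [stage_assign(g) for g in ga_weeks]
    strength = (
        _subject_strengths(z_stack, sig)
        if upper_vec(sig).any()
        else _subject_strengths(z_stack, classes.mask("all"))
    )
    dist = []
    sig_subset = sig if upper_vec(sig).any() else None
    for g in ga_weeks:
        coords = scale_atlas(atlas, min(g, 38.0))
        diff = coords[:, None, :] - coords[None, :, :]
        dmat = np.sqrt((diff**2).sum(-1))
        vals = upper_vec(dmat)
        if sig_subset is not None:
            vals = vals[upper_vec(sig_subset)]
        dist.append(float(vals.mean()))
    dist = np.asarray(dist)

    table = {"config_hash": cfg.hash(), "stages": {}, "contrasts": {}}
    groups = {}
    for label in ("pre", "expansion", "post"):
        sel = np.array([s == label for s in stages])
        groups[label] = sel
        table["stages"][label] = {
            "n": int(sel.sum()),
            "strength_mean": float(strength[sel].mean()) if sel.any() else None,
            "strength_sd": float(strength[sel].std(ddof=1)) if sel.sum() > 1 else None,
            "distance_mean_mm": float(dist[sel].mean()) if sel.any() else None,
            "distance_sd_mm": float(dist[sel].std(ddof=1)) if sel.sum() > 1 else None,
        }
    for name, (g1, g2) in {
        "pre_vs_expansion": ("pre", "expansion"),
        "expansion_vs_post": ("expansion", "post"),
        "pre_vs_post": ("pre", "post"),
    }.items():
        s1, s2 = groups[g1], groups[g2]
        if s1.sum() < 2 or s2.sum() < 2:
            continue
        for qty, vals in (("strength", strength), ("distance_mm", dist)):
            res = summary_ttest(
                vals[s1].mean(),
                vals[s1].std(ddof=1),
                int(s1.sum()),
                vals[s2].mean(),
                vals[s2].std(ddof=1),
                int(s2.sum()),
            )
            table["contrasts"][f"{name}_{qty}"] = {
                "difference": res.difference,
                "t": res.t,
                "p": res.p,
                "df": res.df,
            }
    write_json(out / "stage_table.json", table)


def stage_spectra(cfg: PipelineConfig, workdir) -> None:
    out = Path(workdir)
    manifest = _manifest(out)
    series = [read_timeseries(out / f"{sid}_clean.tsv")[0] for sid in manifest["subject_id"]]
    tr = float(manifest["tr_s"].iloc[0]) if "tr_s" in manifest else 1.0
    spec = cohort_mean_coherence(series, tr_s=tr)
    pd.DataFrame(
        {
            "frequency_hz": spec.freqs_hz,
            "mean_coherence": spec.mean,
            "q25": spec.q25,
            "q75": spec.q75,
        }
    ).to_csv(out / "coherence.tsv", sep="\t", index=False)
    write_json(
        out / "coherence_peaks.json",
        {
            "peaks": [{"frequency_hz": f, "height": h} for f, h in spec.peaks],
            "config_hash": cfg.hash(),
        },
    )


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connect": stage_connect,
    "infer": stage_infer,
    "growth": stage_growth,
    "spectra": stage_spectra,
}


def run_pipeline(cfg: PipelineConfig, workdir) -> dict:
    """Run every stage in order and write a summary report; returns the report."""
    out = Path(workdir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    order = [s for s in STAGES if s != "simulate" or cfg.simulate]
    for name in order:
        t0 = time.perf_counter()
        try:
            STAGES[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "stage_timings_s": timings,
        "nbs": read_json(out / "nbs_components.json"),
        "growth_fits": pd.read_csv(out / "growth_fits.tsv", sep="\t").to_dict("records"),
        "stage_table": read_json(out / "stage_table.json"),
        "coherence_peaks": read_json(out / "coherence_peaks.json"),
    }
    write_json(out / "report.json", report)
    return report
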