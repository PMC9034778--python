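"""End-to-end orchestration: simulate -> microstructure -> LBA -> photometry -> linkage."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lba.inference import PriorSpec, SamplerConfig, fit_per_zone
from .linkage import bh_qvalues, build_linkage_table, correlate_params, regress_dff
from .microstructure import (
    assign_zones,
    classify_motion,
    cluster_zones,
    detect_pauses,
    interpolate_gaps,
    summarize_rts,
)
from .photometry import bootstrap_ci, compute_dff, extract_kernels, pause_dff, spatial_dff
from .synth import CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "segment_cohort"]


def segment_cohort(traces, geometry):
    """Microstructure stage for a list of traces: pauses + zone partition."""
    pauses = []
    for trace in traces:
        tr = interpolate_gaps(trace)
        segs = classify_motion(tr, geometry)
        pauses.extend(detect_pauses(segs, tr, geometry))
        log.info("subject %s: %d pauses detected", trace.subject_id, len(pauses))
    partition = cluster_zones(pauses, geometry)
    boundaries = (
        partition.boundaries
        if partition.contiguous and len(partition.boundaries) == len(geometry.zone_boundaries)
        else geometry.zone_boundaries
    )
    assign_zones(pauses, boundaries)
    return pauses, partition, boundaries


def run_pipeline(
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    sampler: SamplerConfig | None = None,
    priors: PriorSpec | None = None,
    min_trials: int = 20,
    n_boot: int = 1000,
) -> dict:
    """Run the full synthetic-cohort analysis; return the report bundle.

    The report carries the directional findings as booleans plus every
    stage's counts; artifacts and a JSON manifest are written to
    ``out_dir`` when given.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    priors = priors or PriorSpec()
    sampler = sampler or SamplerConfig(seed=config.seed)
    report: dict = {"stages": {}, "seeds": {"cohort": config.seed, "sampler": sampler.seed}}

    traces, recordings, truth = simulate_cohort(config)
    report["stages"]["simulate"] = {
        "n_subjects": len(traces),
        "n_true_pauses": int(len(truth.pauses)),
    }

    geometry = config.geometry
    pauses, partition, boundaries = segment_cohort(traces, geometry)
    rt_summary = summarize_rts(pauses)
    report["stages"]["microstructure"] = {
        "n_pauses": len(pauses),
        "zone_boundaries": list(boundaries),
        "mean_silhouette": partition.mean_silhouette,
        "lognormal_r2": rt_summary.r2,
        "cv_r2": rt_summary.cv_r2,
    }

    fits = fit_per_zone(pauses, priors, sampler, min_trials=min_trials)
    report["stages"]["lba"] = {
        "n_fits": len(fits),
        "all_converged": bool(all(f.converged for f in fits.values())),
        "max_rhat": max((max(f.rhat.values()) for f in fits.values()), default=None),
        "min_ess": min((min(f.ess.values()) for f in fits.values()), default=None),
    }

    pause_rows = []
    kernel_waves = []
    spatial_rows = []
    boot_rng = np.random.default_rng(config.seed + 7)
    kernel_time = None
    by_subject = {p.subject_id: [] for p in pauses}
    for p in pauses:
        by_subject[p.subject_id].append(p)
    for rec in recordings:
        dff = compute_dff(rec)
        sub_pauses = by_subject.get(rec.subject_id, [])
        pd_df = pause_dff(dff, sub_pauses)
        pause_rows.append(pd_df)
        smap = spatial_dff(dff, rec.x, geometry, partition if partition.contiguous else None)
        spatial_rows.append(
            {"subject": rec.subject_id, **{f"bin_{i}": v for i, v in enumerate(smap.bin_means)}}
        )
        goal_onsets = np.array(
            [p.onset_time for p in sub_pauses if p.zone == "goal"], dtype=float
        )
        if goal_onsets.size:
            kern = extract_kernels(dff, goal_onsets)
            if kern.n_events:
                kernel_time = kern.time
                kernel_waves.append(kern.mean)
    pause_table = pd.concat(pause_rows, ignore_index=True) if pause_rows else pd.DataFrame()
    kernels = None
    if len(kernel_waves) >= 2:
        waves = np.asarray(kernel_waves)
        mean, lo, hi, epochs = bootstrap_ci(waves, kernel_time, n_boot=n_boot, rng=boot_rng)
        kernels = {
            "time": kernel_time,
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "epochs": epochs,
        }
    report["stages"]["photometry"] = {
        "n_pause_dff": int(len(pause_table)),
        "n_kernel_subjects": len(kernel_waves),
        "significant_epochs": kernels["epochs"] if kernels else [],
    }

    agg = (
        pause_table.groupby(["subject", "zone"])["dff"].mean().reset_index()
        if len(pause_table)
        else pd.DataFrame(columns=["subject", "zone", "dff"])
    )
    table = build_linkage_table(fits, agg)
    correlations = {p: correlate_params(table, p) for p in ("v_approach", "v_avoid", "caution")}
    correlations_q = bh_qvalues(
        {p: c["p"] for p, c in correlations.items() if c.get("p") is not None}
    )
    regression = regress_dff(table)
    report["stages"]["linkage"] = {
        "n_rows": len(table),
        "regression": {
            "beta": regression.beta,
            "adj_r2": regression.adj_r2,
            "F": regression.f_stat,
            "p": regression.p_value,
        },
        "correlations": {
            p: {k: v for k, v in c.items() if k != "per_subject"}
            for p, c in correlations.items()
        },
        "bh_q": correlations_q,
    }

    # directional findings
    caut = {
        zone: np.mean([f.posterior_mean()["caution"] for (s, z), f in fits.items() if z == zone])
        for zone in {z for (_, z) in fits}
    }
    goal_p = [p for p in pauses if p.zone == "goal"]
    rt_app = np.mean([p.duration for p in goal_p if p.outcome == "approach"]) if goal_p else np.nan
    rt_avd = np.mean([p.duration for p in goal_p if p.outcome == "avoid"]) if goal_p else np.nan
    report["findings"] = {
        "caution_goal_gt_mid": bool(caut.get("goal", np.nan) > caut.get("mid", np.nan)),
        "avoid_rt_gt_approach_rt_at_goal": bool(rt_avd > rt_app),
        "dff_caution_association_positive": bool(
            (correlations["caution"].get("r") or 0) > 0
        ),
        "group_mean_caution": {k: float(v) for k, v in caut.items()},
        "goal_rt_approach": float(rt_app),
        "goal_rt_avoid": float(rt_avd),
    }

    if out_dir is not None:
        _write_outputs(
            Path(out_dir), config, sampler, report, pauses, partition, fits, pause_table,
            spatial_rows, kernels, table,
        )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_outputs(
    out, config, sampler, report, pauses, partition, fits, pause_table,
    spatial_rows, kernels, table,
):
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "subject": p.subject_id,
                "session": p.session_id,
                "onset_s": p.onset_time,
                "offset_s": p.offset_time,
                "rt_s": p.duration,
                "x_cm": p.location,
                "zone": p.zone,
                "outcome": p.outcome,
            }
            for p in pauses
        ]
    ).to_csv(out / "pauses.csv", index=False)
    (out / "zones.json").write_text(
        json.dumps(
            _jsonable(
                {
                    "k": partition.k,
                    "boundaries": partition.boundaries,
                    "mean_silhouette": partition.mean_silhouette,
                    "min_silhouette": partition.min_silhouette,
                    "contiguous": partition.contiguous,
                }
            ),
            indent=2,
        )
    )
    fit_summary = {
        f"{s}/{z}": {
            "mean": f.posterior_mean(),
            "ci95": f.credible_interval(),
            "rhat": f.rhat,
            "ess": f.ess,
            "converged": f.converged,
        }
        for (s, z), f in fits.items()
    }
    (out / "lba_fits.json").write_text(json.dumps(_jsonable(fit_summary), indent=2))
    if len(pause_table):
        pause_table.to_csv(out / "pause_dff.csv", index=False)
    if spatial_rows:
        pd.DataFrame(spatial_rows).to_csv(out / "spatial_dff.csv", index=False)
    if kernels is not None:
        pd.DataFrame(
            {
                "time_s": kernels["time"],
                "mean": kernels["mean"],
                "ci_lower": kernels["lower"],
                "ci_upper": kernels["upper"],
            }
        ).to_csv(out / "kernels.csv", index=False)
        (out / "kernel_epochs.json").write_text(json.dumps(_jsonable(kernels["epochs"])))
    table.to_csv(out / "linkage_table.csv", index=False)
    manifest = {
        "package_version": __version__,
        "cohort_config": _jsonable(
            {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()
                if k != "pause_hazard_profile"
            }
        ),
        "sampler_config": dataclasses.asdict(sampler),
        "seeds": report["seeds"],
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, default=str))
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
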