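"""End-to-end study orchestration: simulate/load, analyze, report.

``run_pipeline`` chains the analyses in their methodological order: basic
event features and group comparison, directional rank profiles, viewing
priority with severity correlations, visual-field maps, kernel-PCA
embedding with naive-Bayes cross-validation, and perimetry summaries (IVF
scores).  Outputs are CSV tables and map files plus one JSON summary;
identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import directions, io_formats, kpca, maps, perimetry, priority
from .cohort import CohortBundle, CohortConfig, make_cohort
from .gaze import basic_features, compare_groups
from .geometry import MONOCULAR_SCREEN

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: input source, regime, toggles, output directory."""

    out_dir: str = "gazefield_out"
    seed: int = 0
    regime: str = "monocular"             # monocular | binocular
    events_path: str | None = None        # csv_events input; None -> simulate
    cohort: CohortConfig | None = None    # simulation config when simulating
    analyses: tuple = ("features", "directions", "vp", "maps", "kpca", "ivf")

    def __post_init__(self) -> None:
        if self.regime not in ("monocular", "binocular"):
            raise ValueError("regime must be 'monocular' or 'binocular'")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj


def _comparison_dict(c) -> dict:
    return {
        "median_control": c.median_a, "median_patient": c.median_b,
        "sd_control": c.sd_a, "sd_patient": c.sd_b,
        "u": c.u_statistic, "z": c.z, "p": c.p,
        "corrected_alpha": c.corrected_alpha, "significant": c.significant,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "regime": config.regime}

    if config.events_path is not None:
        raise NotImplementedError(
            "external event tables enter through io_formats.read_event_table; "
            "wire them into a CohortBundle-shaped container first"
        )
    cohort_cfg = config.cohort or CohortConfig(
        master_seed=config.seed, binocular=(config.regime == "binocular")
    )
    bundle = make_cohort(cohort_cfg)
    controls = bundle.participants("control")
    patients = bundle.participants("patient")
    summary["n_controls"] = len(controls)
    summary["n_patients"] = len(patients)

    stage = None
    try:
        if "features" in config.analyses:
            stage = "features"
            feats = {p: basic_features(bundle.trials_of(p)) for p in bundle.participants()}
            df = pd.DataFrame.from_dict(feats, orient="index")
            df.index.name = "participant"
            df["group"] = [bundle.groups[p] for p in df.index]
            df.to_csv(out / "features.csv")
            comparisons = {}
            for feat in ("fixation_duration_ms", "saccade_amplitude_deg",
                         "saccade_peak_velocity_deg_s"):
                a = [feats[p][feat] for p in controls]
                b = [feats[p][feat] for p in patients]
                comparisons[feat] = _comparison_dict(compare_groups(a, b, n_comparisons=4))
            summary["features"] = comparisons

        profiles = {p: directions.directional_profile(
            [s for t in bundle.trials_of(p) for s in t.saccades])
            for p in bundle.participants()}
        if "directions" in config.analyses:
            stage = "directions"
            ctrl_profiles = [profiles[p] for p in controls]
            rows = []
            for pid in patients:
                rp = directions.normalized_rank_profile(profiles[pid], ctrl_profiles)
                for b in range(directions.N_BINS):
                    rows.append(dict(participant=pid,
                                     bin_start_deg=b * directions.BIN_WIDTH,
                                     median_rank=rp.median_rank[b],
                                     max_rank=rp.max_rank[b],
                                     flag_low=bool(rp.flag_low[b]),
                                     flag_high=bool(rp.flag_high[b])))
            pd.DataFrame(rows).to_csv(out / "rank_profiles.csv", index=False)
            summary["control_extent"] = directions.control_extent(ctrl_profiles)

        vp_summary = None
        vp_records = []
        if "vp" in config.analyses:
            stage = "vp"
            params = priority.VPParams(seed=config.seed)
            ctrl_trials = bundle.control_trials()
            for pid in bundle.participants():
                vp_records.extend(priority.score_cohort_member(
                    bundle.trials_of(pid), ctrl_trials, params))
            pd.DataFrame([
                dict(participant=r.participant, clip=r.clip, t_on=r.onset,
                     vp=r.vp, n_reference=r.n_reference, n_random=r.n_random)
                for r in vp_records
            ]).to_csv(out / "vp_records.csv", index=False)
            severity = {}
            if "ivf" in config.analyses:
                severity = {
                    "md_tested": {p: bundle.fields[p]["tested"].md for p in patients},
                    "ivf_score": {
                        p: float(perimetry.ivf_score(perimetry.merge_ivf(
                            bundle.fields[p]["tested"], bundle.fields[p]["covered"])))
                        for p in patients
                    },
                    "md_difference": {
                        p: bundle.fields[p]["tested"].md - bundle.fields[p]["covered"].md
                        for p in patients
                    },
                }
            vp_summary = priority.summarize_vp(vp_records, severity or None)
            overall = vp_summary["overall_means"]
            vp_ctrl = [overall[p] for p in controls if p in overall]
            vp_pat = [overall[p] for p in patients if p in overall]
            summary["vp"] = {
                "comparison": _comparison_dict(
                    compare_groups(vp_ctrl, vp_pat, n_comparisons=4)),
                "correlations": vp_summary.get("correlations", {}),
            }

        spec = maps.MapSpec()
        vf_vectors = {}
        for pid in bundle.participants():
            vecs = [np.asarray([[s.x1 - s.x0, s.y1 - s.y0]])
                    for t in bundle.trials_of(pid) for s in t.saccades]
            vf_vectors[pid] = (np.concatenate(vecs) if vecs else np.empty((0, 2)))
        if "maps" in config.analyses:
            stage = "maps"
            heat = {p: maps.fixation_heatmap(vf_vectors[p], spec)
                    for p in bundle.participants()}
            ctrl_maps = [heat[p] for p in controls]
            for pid in patients:
                rank = maps.relative_rank_map(heat[pid], ctrl_maps)
                io_formats.write_map(rank, out / f"rank_map_{pid}.tsv")
            rows = []
            for pid in patients:
                fld = bundle.fields[pid]["effective"]
                _, r = maps.binned_map_vs_sensitivity(vf_vectors[pid], fld)
                rows.append(dict(participant=pid, layout=fld.layout, r=r))
            pd.DataFrame(rows).to_csv(out / "sensitivity_correlations.csv", index=False)
            summary["fixation_vs_sensitivity_r"] = {
                row["participant"]: row["r"] for row in rows
            }

        if "kpca" in config.analyses:
            stage = "kpca"
            count_maps = {
                p: [maps.fixation_count_map(
                    np.concatenate([[[s.x1 - s.x0, s.y1 - s.y0]]
                                    for s in t.saccades]) if t.saccades
                    else np.empty((0, 2)), spec)
                    for t in bundle.trials_of(p)]
                for p in bundle.participants()
            }
            kmat, pids = kpca.kernel_matrix(count_maps, kpca.KernelSpec())
            emb = kpca.kpca_project(kmat)
            labels = np.array([bundle.groups[p] for p in pids])
            ncomp = min(5, emb.projections.shape[1])
            min_class = min(np.sum(labels == g) for g in np.unique(labels))
            nfolds = int(min(10, min_class))
            cv = kpca.nb_crossval(
                emb.projections, labels,
                kpca.ClassifierConfig(n_components=ncomp, n_folds=nfolds,
                                      seed=config.seed))
            emb_df = pd.DataFrame(
                emb.projections[:, :ncomp],
                columns=[f"comp{i + 1}" for i in range(ncomp)], index=pids)
            emb_df.insert(0, "group", labels)
            emb_df.to_csv(out / "embedding.csv", index_label="participant")
            pd.DataFrame([{"maps": "fixation", "accuracy": cv["report"]}]).to_csv(
                out / "accuracy.csv", index=False)
            summary["kpca"] = {
                "explained_variance_first2": float(emb.explained_variance[:2].sum()),
                "dropped_mass": emb.dropped_mass,
                "nb_accuracy_mean": cv["mean"],
                "nb_accuracy_report": cv["report"],
            }

        if "ivf" in config.analyses:
            stage = "ivf"
            rows = []
            for pid in patients:
                f = bundle.fields[pid]
                ivf = perimetry.merge_ivf(f["tested"], f["covered"])
                ms = perimetry.md_summaries(f["tested"].md, f["covered"].md, "right")
                rows.append(dict(participant=pid, md_tested=f["tested"].md,
                                 md_covered=f["covered"].md,
                                 md_difference=ms["md_difference"],
                                 ivf_score=perimetry.ivf_score(ivf)))
            pd.DataFrame(rows).to_csv(out / "ivf_scores.csv", index=False)
            summary["ivf_scores"] = {r["participant"]: r["ivf_score"] for r in rows}
    except Exception:
        log.error("pipeline stage %r failed; partial outputs kept in %s", stage, out)
        raise

    summary_json = json.dumps(_jsonable(summary), indent=1, sort_keys=True)
    (out / "summary.json").write_text(summary_json)
    return summary
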