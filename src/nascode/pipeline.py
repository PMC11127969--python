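"""End-to-end orchestration: sequences -> consistency -> boundaries ->
embedding -> behavior -> decoding, with every stage's outputs and the
effective configuration written to a results directory."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, boundaries, consistency, decoding, embedding, sequences
from .synth import Session, target_label

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("sequences", "consistency", "boundaries", "embedding", "behavior", "decoding")


@dataclass
class RunConfig:
    """Every tunable of the analysis stages, serializable to YAML.

    Defaults follow the recorded-task values where the source protocol prints
    them (100 ms SDF kernel, 0.5 Hz rate floor, >=5 trials per condition,
    1 s FWHM threshold, k=3 projection, 5-fold nearest-centroid CV, 10-fold
    SVM CV, 10-90% ablation at 100 iterations).
    """

    kernel_sd_s: float = 0.1
    grid_dt_s: float = 0.001
    min_rate_hz: float = 0.5
    min_trials: int = 5
    shuffle_repeats: int = 100
    fwhm_threshold_s: float = 1.0
    fwhm_bandwidth_s: float = 0.1
    boundary_bin_s: float = 0.1
    k: int = 3
    min_overlap: int = 10
    resample_points: int = 50
    nc_folds: int = 5
    svm_folds: int = 10
    p_threshold: float = 0.05
    percentile_grid: tuple[float, ...] = decoding.DEFAULT_PERCENTILE_GRID
    ablation_fractions: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    ablation_iters: int = 100
    n_link_shuffles: int = 200
    sd_thresholds_ms: tuple[float, ...] = consistency.DEFAULT_SD_THRESHOLDS_MS
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("percentile_grid", "ablation_fractions", "sd_thresholds_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _resolve_stages(stages) -> list[str]:
    if stages is None:
        return list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    # preserve canonical order and pull in upstream dependencies
    want = set(stages)
    need = set()
    for s in STAGES:
        if s in want:
            need.add(s)
    if need & {"consistency", "boundaries", "embedding", "behavior", "decoding"}:
        need.add("sequences")
    if need & {"embedding", "behavior", "decoding"}:
        need.add("boundaries")
    if need & {"behavior", "decoding"}:
        need.add("embedding")
    return [s for s in STAGES if s in need]


def run_pipeline(
    session: Session,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the analysis stages in order on one session.

    Returns a results dictionary keyed by stage; when ``outdir`` is given each
    stage's tables, a summary record and the effective configuration are
    written there. ``stages`` selects the stages to run (upstream dependencies
    are pulled in automatically); a stage failure propagates with the stage
    named.
    """
    cfg = config or RunConfig()
    todo = _resolve_stages(stages)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "effective_config.yaml")

    results: dict = {"stages": todo}
    summary: dict = {}
    trials = session.trials
    correct_ids = trials.loc[trials["correct"], "trial_id"].to_numpy()
    target = trials.set_index("trial_id").apply(
        lambda r: target_label(r.target_row, r.target_col), axis=1
    )

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    seqs = None
    if "sequences" in todo:
        try:
            seqs = sequences.build_sequences(
                session, min_rate_hz=cfg.min_rate_hz, kernel_sd=cfg.kernel_sd_s, dt=cfg.grid_dt_s
            )
        except Exception as e:  # noqa: BLE001
            _fail("sequences", e)
        results["sequences"] = seqs
        if out is not None:
            seqs.to_csv(out / "sequences.tsv", sep="\t", na_rep="NA")
    seqs_correct = seqs.loc[[i for i in seqs.index if i in set(correct_ids)]] if seqs is not None else None

    if "consistency" in todo:
        try:
            cres = consistency.consistency_analysis(
                seqs_correct,
                target.loc[seqs_correct.index],
                min_trials=cfg.min_trials,
                n_repeats=cfg.shuffle_repeats,
                seed=cfg.seed,
                thresholds_ms=cfg.sd_thresholds_ms,
            )
        except Exception as e:  # noqa: BLE001
            _fail("consistency", e)
        results["consistency"] = cres
        summary["mean_difference_ms"] = cres.mean_difference_ms
        summary["fraction_below"] = {str(k): v for k, v in cres.fraction_below.items()}
        if out is not None:
            tidy = cres.sd.stack().rename("sd_s").reset_index()
            tidy.columns = ["unit_id", "condition", "sd_s"]
            tidy.to_csv(out / "consistency_sd.tsv", sep="\t", index=False)

    bres = None
    if "boundaries" in todo:
        try:
            bres = boundaries.boundary_analysis(
                seqs_correct,
                delay_on=float(trials["t_delay_on"].iloc[0]),
                nav_on=float(trials["t_nav_on"].iloc[0]),
                t_end=float(trials["t_end"].iloc[0]),
                fwhm_threshold_s=cfg.fwhm_threshold_s,
                bandwidth_s=cfg.fwhm_bandwidth_s,
                bin_s=cfg.boundary_bin_s,
            )
        except Exception as e:  # noqa: BLE001
            _fail("boundaries", e)
        results["boundaries"] = bres
        summary["pre_delay_boundary_s"] = bres.pre_delay_t
        summary["pre_nav_boundary_s"] = bres.pre_nav_t
        summary["fraction_time_selective"] = bres.fraction_selective
        if out is not None:
            with open(out / "boundaries.yaml", "w") as fh:
                yaml.safe_dump(
                    {
                        "pre_delay_t": bres.pre_delay_t,
                        "pre_nav_t": bres.pre_nav_t,
                        "fraction_selective": bres.fraction_selective,
                        "selective_units": [int(u) for u in bres.selective_units],
                    },
                    fh,
                )

    proj = centroids = centroid_D = None
    delay_window = None
    if "embedding" in todo:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                windows = decoding.epoch_windows(
                    trials,
                    bres.pre_delay_t if bres is not None else None,
                    bres.pre_nav_t if bres is not None else None,
                )
            delay_window = windows["delay"]
            mem = sequences.mask_epoch(seqs_correct, delay_window)
            proj, centroids, centroid_D = embedding.embed(
                mem, target.loc[mem.index], k=cfg.k, min_overlap=cfg.min_overlap
            )
        except Exception as e:  # noqa: BLE001
            _fail("embedding", e)
        results["embedding"] = {"projection": proj, "centroids": centroids, "centroid_D": centroid_D}
        if out is not None:
            pt = proj.P.copy()
            pt["condition"] = target.loc[proj.P.index]
            pt.to_csv(out / "projection.tsv", sep="\t")
            centroid_D.to_csv(out / "centroid_distances.tsv", sep="\t")

    if "behavior" in todo:
        try:
            avg = behavior.average_trajectories_by_target(
                session.trajectories, trials,
                camera=session.config.camera() if session.config else behavior.Camera(),
                n_points=cfg.resample_points,
            )
            frechet_D = behavior.frechet_matrix(avg)
            rho = behavior.link_correlation(centroid_D, frechet_D)
            null = behavior.shuffle_link(
                proj.P, target.loc[proj.P.index], frechet_D,
                n_shuffles=cfg.n_link_shuffles, seed=cfg.seed,
            )
        except Exception as e:  # noqa: BLE001
            _fail("behavior", e)
        results["behavior"] = {"frechet_D": frechet_D, "link_rho": rho, "null_rhos": null}
        summary["link_rho"] = rho
        summary["link_null_p95"] = float(np.quantile(null, 0.95))
        if out is not None:
            frechet_D.to_csv(out / "frechet_distances.tsv", sep="\t")

    if "decoding" in todo:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ep = decoding.epoch_decode(
                    seqs_correct, trials,
                    bres.pre_delay_t if bres is not None else None,
                    bres.pre_nav_t if bres is not None else None,
                    k=cfg.k, min_overlap=cfg.min_overlap, k_folds=cfg.nc_folds, seed=cfg.seed,
                )
                tgt_reports = decoding.combined_target_decode(
                    seqs_correct, trials, k=cfg.k, min_overlap=cfg.min_overlap,
                    k_folds=cfg.nc_folds, seed=cfg.seed, percentile_grid=cfg.percentile_grid,
                )
                pers_rep, seq_rep = decoding.compare_codes(
                    session, seqs_correct, delay_window=delay_window,
                    p_threshold=cfg.p_threshold, folds=cfg.svm_folds, seed=cfg.seed,
                    k=cfg.k, min_overlap=cfg.min_overlap,
                )
        except Exception as e:  # noqa: BLE001
            _fail("decoding", e)
        reports = {"epoch": ep, **tgt_reports, "sequence_svm": seq_rep}
        if pers_rep is not None:
            reports["persistent_svm"] = pers_rep
        results["decoding"] = reports
        for name, rep in reports.items():
            summary[f"accuracy_{name}"] = rep.mean_accuracy
            summary[f"chance_{name}"] = rep.chance
        if out is not None:
            rows = [
                {"task": r.task, "fold": i, "accuracy": a, "chance": r.chance, "seed": r.seed}
                for r in reports.values()
                for i, a in enumerate(r.fold_accuracies)
            ]
            pd.DataFrame(rows).to_csv(out / "decoder_reports.tsv", sep="\t", index=False)

    results["summary"] = summary
    if out is not None:
        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(_yamlify(summary), fh)
    return results


def _yamlify(obj):
    if isinstance(obj, dict):
        return {k: _yamlify(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
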