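"""End-to-end synthetic experiment runner.

Composes the whole study on simulated data with known ground truth:
single-fly conditioning (learning indices, exclusion rule), a two-group
imaging cohort (motion correction, frame QC, smoothing, activity maps,
peak responses, sparseness, inter-odor correlation), MBON trained:untrained
response ratios with a Monte-Carlo power check, and qPCR fold changes —
then runs the group statistics and writes a results bundle with a full
provenance manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, imaging, popstats, stats, synthetic
from .io import dump_json, scores_to_frame

log = logging.getLogger("mbplast")

__all__ = [
    "BehaviorConfig",
    "ImagingConfig",
    "MbonConfig",
    "QpcrConfig",
    "RunConfig",
    "simulate_imaging_cohort",
    "analyze_cohort_fly",
    "run_endtoend",
]


@dataclass
class BehaviorConfig:
    n_flies: int = 30
    pre_bias: float = 1.0
    post_bias_trained: float = 3.0  # control genotype learns: 50% -> 25% odor side
    post_bias_knockdown: float = 1.0  # knockdown genotype fails to learn
    test_s: float = 180.0
    zone_halfwidth: float = 2.5
    min_entries: int = 4


@dataclass
class ImagingConfig:
    n_per_group: int = 8
    shape: tuple[int, int, int] = (60, 48, 48)
    frame_period: float = 0.2
    prestim_window: tuple[float, float] = (0.0, 6.0)
    stim_windows: dict = field(default_factory=lambda: {"MCH": (6.0, 8.0), "OCT": (9.0, 11.0)})
    knockdown_gain: float = 1.5
    amplitude: float = 1.0
    amplitude_cv: float = 0.2
    frac_active: float = 0.15
    noise_sd: float = 2.0
    jitter_px: int = 2
    corrupt_fraction: float = 0.05
    max_shift: int = 10
    sd_factor: float = 2.0
    # explicit QC threshold, standing in for the per-brain manual choice:
    # strong odor responses legitimately lower the frame-to-baseline
    # correlation, so the outlier-based auto rule is reserved for
    # response-free calibration movies
    qc_threshold: float = 0.5


@dataclass
class MbonConfig:
    n_per_group: int = 5
    depression: float = 0.5
    cv: float = 0.2
    power_sims: int = 500
    alpha: float = 0.05


@dataclass
class QpcrConfig:
    true_fold: float = 0.4
    ct_noise_sd: float = 0.05
    n_replicates: int = 3


@dataclass
class RunConfig:
    seed: int = 0
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    mbon: MbonConfig = field(default_factory=MbonConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=doc.get("seed", 0),
            behavior=BehaviorConfig(**doc.get("behavior", {})),
            imaging=ImagingConfig(**_tupled(doc.get("imaging", {}), ("shape", "prestim_window"))),
            mbon=MbonConfig(**doc.get("mbon", {})),
            qpcr=QpcrConfig(**doc.get("qpcr", {})),
        )


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    if "stim_windows" in d:
        d["stim_windows"] = {k: tuple(v) for k, v in d["stim_windows"].items()}
    return d


def _gamma_roi(spatial_shape: tuple[int, int]) -> np.ndarray:
    """Designated gamma-lobe ROI: a central block covering ~25% of the frame."""
    ny, nx = spatial_shape
    mask = np.zeros(spatial_shape, dtype=bool)
    mask[ny // 4 : 3 * ny // 4, nx // 4 : 3 * nx // 4] = True
    return mask


def simulate_imaging_cohort(cfg: ImagingConfig, seed: int) -> list[dict]:
    """Simulate control and knockdown imaging cohorts.

    Each fly gets its own baseline image and sparse per-odor response
    maps (confined to the gamma ROI); knockdown flies carry the
    multiplicative response gain on the gamma-designated pixels.
    Returns per-fly records with the movie, ground truth and ROI.
    """
    rng = np.random.default_rng(seed)
    T = cfg.shape[0]
    spatial = cfg.shape[1:]
    roi = _gamma_roi(spatial)
    records = []
    for group, gain in (("control", 1.0), ("knockdown", cfg.knockdown_gain)):
        for i in range(cfg.n_per_group):
            baseline = synthetic.random_baseline_image(spatial, rng)
            maps = {
                odor: synthetic.random_response_map(
                    spatial, rng, cfg.frac_active, cfg.amplitude, cfg.amplitude_cv, within=roi
                )
                for odor in cfg.stim_windows
            }
            xy = np.zeros((T, 2), dtype=int)
            if cfg.jitter_px > 0:
                xy = rng.integers(-cfg.jitter_px, cfg.jitter_px + 1, size=(T, 2))
            n_corrupt = int(round(cfg.corrupt_fraction * T))
            corrupt = tuple(
                int(f)
                for f in rng.choice(
                    np.flatnonzero(np.arange(T) * cfg.frame_period >= cfg.prestim_window[1]),
                    size=n_corrupt,
                    replace=False,
                )
            ) if n_corrupt else ()
            params = synthetic.MovieParams(
                shape=cfg.shape,
                frame_period=cfg.frame_period,
                baseline_image=baseline,
                response_maps=maps,
                stim_windows=dict(cfg.stim_windows),
                noise_sd=cfg.noise_sd,
                xy_shifts=xy,
                corrupt_frames=corrupt,
                knockdown_gain=gain,
                knockdown_mask=roi,
                seed=int(rng.integers(2**31)),
            )
            movie, truth = synthetic.simulate_movie(params)
            records.append(
                dict(fly_id=f"{group}_{i:03d}", group=group, movie=movie, truth=truth, roi=roi)
            )
    return records


def analyze_cohort_fly(rec: dict, cfg: ImagingConfig, prestim: tuple[float, float]) -> dict:
    """Full imaging analysis of one fly: correction, QC, smoothing,
    activity maps, gamma-ROI peaks, sparseness and inter-odor correlation."""
    movie = rec["movie"]
    mc = imaging.correct_motion_xy(movie, max_shift=cfg.max_shift)
    movie = mc.movie
    if movie.is_volumetric:
        movie = imaging.correct_motion_z(movie).movie
    baseline_img = movie.data[movie.frames_in(prestim)].mean(axis=0)
    qc = imaging.qc_discard_frames(movie, baseline_img, threshold=cfg.qc_threshold)
    smoothed = imaging.smooth_for_analysis(movie)
    odors = list(cfg.stim_windows)
    maps = {
        odor: imaging.compute_activity_map(
            smoothed, prestim, cfg.stim_windows[odor], sd_factor=cfg.sd_factor, kept=qc.kept
        )
        for odor in odors
    }
    peaks = {}
    for odor in odors:
        trace = imaging.roi_dff_trace(smoothed, rec["roi"], prestim, kept=qc.kept, roi_name="gamma")
        peaks[odor] = imaging.peak_response(trace, cfg.stim_windows[odor])
    sp = {
        odor: popstats.population_sparseness(maps[odor], mask=rec["roi"]).SP for odor in odors
    }
    corr = popstats.interodor_correlation(maps[odors[0]], maps[odors[1]], max_shift=cfg.max_shift)
    return dict(
        fly_id=rec["fly_id"],
        group=rec["group"],
        maps=maps,
        peaks=peaks,
        sparseness=sp,
        interodor_r=corr.r_pearson,
        n_kept=int(qc.kept.sum()),
        xy_shifts=mc.shifts,
    )


def _stage_behavior(cfg: BehaviorConfig, seed: int) -> dict:
    exp = synthetic.simulate_conditioning_experiment(
        pre_bias=cfg.pre_bias,
        post_bias_trained=cfg.post_bias_trained,
        post_bias_control=cfg.post_bias_knockdown,
        n_flies=cfg.n_flies,
        seed=seed,
        test_s=cfg.test_s,
    )
    # group labels: 'trained' cohort = control genotype, 'control' cohort = knockdown genotype
    label = {"trained": "control_genotype", "control": "knockdown"}
    scores = [
        behavior.score_fly(
            f["traj_pre"], exp.schedule_pre, f["traj_post"], exp.schedule_post,
            exp.trained_odor, cfg.zone_halfwidth, group=label[f["group"]],
        )
        for f in exp.flies
    ]
    kept, excluded = behavior.apply_exclusion(scores, cfg.min_entries)
    table = scores_to_frame(kept).rename(columns={"learning_index": "value"})
    kw = stats.kruskal_wallis_dunn(table[["group", "value"]])
    return dict(
        scores=scores_to_frame(kept + excluded),
        stats=kw,
        expected_li=dict(
            control_genotype=exp.expected_li_trained, knockdown=exp.expected_li_control
        ),
        n_excluded=len(excluded),
    )


def _stage_imaging(cfg: ImagingConfig, prestim: tuple[float, float], seed: int) -> dict:
    records = simulate_imaging_cohort(cfg, seed)
    results = [analyze_cohort_fly(r, cfg, prestim) for r in records]
    odors = list(cfg.stim_windows)
    rows = [
        dict(
            fly_id=r["fly_id"],
            group=r["group"],
            interodor_r=r["interodor_r"],
            n_kept=r["n_kept"],
            **{f"peak_{o}": r["peaks"][o] for o in odors},
            **{f"sp_{o}": r["sparseness"][o] for o in odors},
        )
        for r in results
    ]
    table = pd.DataFrame(rows)
    peak_stats = {
        o: stats.kruskal_wallis_dunn(
            table.rename(columns={f"peak_{o}": "value"})[["group", "value"]]
        )
        for o in odors
    }
    return dict(table=table, peak_stats=peak_stats)


def _stage_mbon(cfg: MbonConfig, seed: int) -> dict:
    params = synthetic.MbonSimParams(
        n_per_group=cfg.n_per_group, depression=cfg.depression, cv=cfg.cv, seed=seed
    )
    table = synthetic.simulate_mbon_table(params)
    ratios_mch = popstats.mbon_ratio_table(table, "MCH", "OCT")
    ratios_oct = popstats.mbon_ratio_table(table, "OCT", "IAA")
    mw = stats.mann_whitney(
        ratios_mch.query("group=='trained'")["ratio"].to_numpy(),
        ratios_mch.query("group=='mock'")["ratio"].to_numpy(),
    )

    def sampler(rng, n):
        p = synthetic.MbonSimParams(
            n_per_group=n, depression=cfg.depression, cv=cfg.cv, seed=int(rng.integers(2**31))
        )
        t = synthetic.simulate_mbon_table(p)
        r = popstats.mbon_ratio_table(t, "MCH", "OCT")
        return (
            r.query("group=='trained'")["ratio"].to_numpy(),
            r.query("group=='mock'")["ratio"].to_numpy(),
        )

    power = stats.power_two_sample(
        sampler, cfg.n_per_group, alpha=cfg.alpha, n_sims=cfg.power_sims, seed=seed
    )
    return dict(
        table=table,
        ratios_mch_oct=ratios_mch,
        ratios_oct_iaa=ratios_oct,
        mw=mw,
        power=power,
    )


def _stage_qpcr(cfg: QpcrConfig, seed: int) -> dict:
    ct = synthetic.simulate_ct_table(
        {"knockdown": cfg.true_fold},
        ct_noise_sd=cfg.ct_noise_sd,
        n_replicates=cfg.n_replicates,
        seed=seed,
    )
    folds = stats.ddct_fold_change(ct, calibrator_sample="control")
    return dict(ct_table=ct, folds=folds)


def run_endtoend(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages and write the results bundle.

    Any stage failure marks the bundle incomplete; completed stages are
    still written.  Returns the in-memory bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in ("behavior", "imaging", "mbon", "qpcr")}
    bundle: dict = {"complete": True, "stage_errors": {}}

    def run_stage(name, fn, *args):
        try:
            bundle[name] = fn(*args)
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            log.error("stage %s failed: %s", name, exc)
            bundle["complete"] = False
            bundle["stage_errors"][name] = "".join(
                traceback.format_exception_only(type(exc), exc)
            ).strip()

    run_stage("behavior", _stage_behavior, config.behavior, stage_seeds["behavior"])
    run_stage("imaging", _stage_imaging, config.imaging, config.imaging.prestim_window, stage_seeds["imaging"])
    run_stage("mbon", _stage_mbon, config.mbon, stage_seeds["mbon"])
    run_stage("qpcr", _stage_qpcr, config.qpcr, stage_seeds["qpcr"])

    # ---- write bundle -----------------------------------------------------
    if "behavior" in bundle:
        bundle["behavior"]["scores"].to_csv(out / "learning_indices.csv", index=False)
    if "imaging" in bundle:
        bundle["imaging"]["table"].to_csv(out / "imaging_summary.csv", index=False)
    if "mbon" in bundle:
        bundle["mbon"]["ratios_mch_oct"].to_csv(out / "mbon_ratios_mch_oct.csv", index=False)
        bundle["mbon"]["ratios_oct_iaa"].to_csv(out / "mbon_ratios_oct_iaa.csv", index=False)
    if "qpcr" in bundle:
        bundle["qpcr"]["folds"].to_csv(out / "qpcr_fold_changes.csv", index=False)

    stats_doc = {}
    if "behavior" in bundle:
        kw = bundle["behavior"]["stats"]
        stats_doc["behavior_kw"] = dict(
            H=kw.statistic, p=kw.p_raw,
            pairwise=[dataclasses.asdict(c) for c in kw.pairwise],
            expected_li=bundle["behavior"]["expected_li"],
            n_excluded=bundle["behavior"]["n_excluded"],
        )
    if "imaging" in bundle:
        stats_doc["imaging_peak_kw"] = {
            o: dict(H=r.statistic, p=r.p_raw, pairwise=[dataclasses.asdict(c) for c in r.pairwise])
            for o, r in bundle["imaging"]["peak_stats"].items()
        }
    if "mbon" in bundle:
        stats_doc["mbon"] = dict(
            mw_p=bundle["mbon"]["mw"].p_raw,
            mw_method=bundle["mbon"]["mw"].method,
            power=dataclasses.asdict(bundle["mbon"]["power"]),
        )
    dump_json(stats_doc, out / "statistics.json")

    manifest = dict(
        package_version=__version__,
        seed=config.seed,
        stage_seeds=stage_seeds,
        config=dataclasses.asdict(config),
        complete=bundle["complete"],
        stage_errors=bundle["stage_errors"],
    )
    dump_json(manifest, out / "manifest.json")
    return bundle
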