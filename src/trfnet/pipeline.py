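"""End-to-end orchestration of the synthetic-study analysis.

Runs the full chain — simulate, hyperalign, source-reconstruct, estimate
TRFs, build TRF-correlation networks, scan densities with community
detection, select the optimal scale, and evaluate condition separability —
for one or more denoising pathways:

* ``single_trial``   — one subject's raw trials, no denoising;
* ``naive_average``  — plain cross-subject additive average;
* ``hyperaligned``   — MCCA canonical-component denoising with aligned
  component averaging, rendered in a consensus montage.

Every stochastic stage draws its own seed derived from the run seed, so a
run report is bit-for-bit reproducible for a given configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._utils import child_seed
from .clustereval import (
    DEFAULT_WINDOWS_MS,
    coupling_correlation,
    embed_2d,
    kmeans_f1,
    vectorize_network,
    window_cluster,
)
from .hyperalign import denoise_and_average, fit_mcca, naive_average
from .inverse import aggregate_roi, apply_inverse, make_inverse_operator
from .network import mean_connectivity, threshold_density, trf_connectivity
from .scales import scan_densities, select_scale
from .synth import CONDITIONS, make_envelope, make_ground_truth, simulate_study
from .trf import default_lag_grid, fit_encoder, loo_crossval

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_pathways", "PATHWAYS"]

PATHWAYS = ("single_trial", "naive_average", "hyperaligned")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults reproduce the study conditions the generator emulates:
    21 subjects, 48 trials (24 per condition) at 250 Hz, 68 regions.
    """

    seed: int = 0
    n_subjects: int = 21
    n_trials_per_condition: int = 24
    n_channels: int = 128
    n_sources: int = 500
    n_roi: int = 68
    n_communities: int = 4
    fs: float = 250.0
    trial_duration_s: float = 5.0
    snr_db: float = -12.0
    misalignment: float = 0.5
    modulation_band_hz: tuple = (2.0, 8.0)
    # hyperalignment
    mcca_ridge: float = 1e-6
    n_components: int | None = None
    # inverse
    alpha: float = 0.05
    # TRFs
    encoder_ridge: float = 0.01
    decoder_lag_step_ms: float = 40.0
    ridge_grid: tuple = tuple(10.0**k for k in range(-3, 4))
    # networks & scales
    gamma: float = 1.0
    t_grid_max: float = 0.50
    scan_n_runs: int = 20
    final_n_runs: int = 100
    # evaluation
    windows_ms: tuple = DEFAULT_WINDOWS_MS
    embed_method: str = "tsne"
    perplexity: float = 10.0
    kmeans_reps: int = 200
    scan_kmeans_reps: int = 100
    single_trial_subject: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if self.trial_duration_s <= 1.0:
            raise ValueError("trials must be longer than 1 s to cover the lag window")
        if not 0 < self.t_grid_max <= 1:
            raise ValueError("t_grid_max must lie in (0, 1]")
        if self.embed_method not in ("tsne", "pca"):
            raise ValueError("embed_method must be 'tsne' or 'pca'")
        if not 0 <= self.single_trial_subject < self.n_subjects:
            raise ValueError("single_trial_subject out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows_ms"] = [list(w) for w in self.windows_ms]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable results of one pipeline run."""

    config: dict
    prediction: dict  # pathway -> {"r": [...], "z": [...], "mean_r", "mean_z"}
    f1_full: dict  # pathway -> mean F1 on full (unthresholded) networks
    windows_f1: dict  # "lo-hi" -> F1 (hyperaligned pathway)
    scan: dict  # per-condition density-scan summaries + selection
    coupling: dict  # condition -> within-community TRF coupling r
    provenance: dict

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        text = json.dumps(asdict(self), sort_keys=True, indent=1, default=_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _pathway_trial(study, pathway, trial, mcca_model, n_components, subject):
    if pathway == "single_trial":
        return np.asarray(study.data[subject, trial], dtype=float)
    if pathway == "naive_average":
        return naive_average(study, trial)
    if pathway == "hyperaligned":
        return denoise_and_average(mcca_model, study, trial, n_components=n_components)
    raise ValueError(f"unknown pathway {pathway!r}")


def run_pipeline(config: RunConfig, pathways: tuple = PATHWAYS, cache_dir=None,
                 multiscale: bool = True) -> RunReport:
    """Execute the full analysis and return a reproducible report.

    ``cache_dir`` (optional) persists the simulated study and per-pathway
    region time courses keyed by the configuration hash, so repeated runs
    with the same configuration resume instead of recomputing.
    """
    cfg = config
    unknown = set(pathways) - set(PATHWAYS)
    if unknown:
        raise ValueError(f"unknown pathways: {sorted(unknown)}")
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    # --- stage 1: ground truth and stimuli -------------------------------
    gt = make_ground_truth(
        n_roi=cfg.n_roi,
        n_channels=cfg.n_channels,
        n_sources=cfg.n_sources,
        n_communities=cfg.n_communities,
        misalignment=cfg.misalignment,
        seed=child_seed(cfg.seed, "ground-truth"),
        n_subjects=cfg.n_subjects,
    )
    n_trials = 2 * cfg.n_trials_per_condition
    envelopes = [
        make_envelope(
            cfg.trial_duration_s,
            cfg.fs,
            modulation_band_hz=cfg.modulation_band_hz,
            seed=child_seed(cfg.seed, f"envelope-{t}"),
        )
        for t in range(n_trials)
    ]

    # --- stage 2: simulate the study -------------------------------------
    study_file = cache / f"study-{chash}.h5" if cache else None
    if study_file is not None and study_file.exists():
        from .io import load_study

        study = load_study(study_file)
    else:
        study = simulate_study(
            gt,
            envelopes,
            n_subjects=cfg.n_subjects,
            n_trials_per_condition=cfg.n_trials_per_condition,
            snr_db=cfg.snr_db,
            seed=child_seed(cfg.seed, "study"),
        )
        if study_file is not None:
            from .io import save_study

            save_study(study_file, study)

    # --- stage 3: hyperalignment model (fit once on all trials) ----------
    mcca_model = None
    if "hyperaligned" in pathways:
        datasets = [
            study.data[i].transpose(0, 2, 1).reshape(-1, study.n_channels)
            for i in range(study.n_subjects)
        ]
        mcca_model = fit_mcca(datasets, ridge=cfg.mcca_ridge)
        del datasets

    inv_op = make_inverse_operator(gt.leadfield, alpha=cfg.alpha)
    encoder_lags = default_lag_grid(cfg.fs)
    decoder_lags = default_lag_grid(cfg.fs, step_ms=cfg.decoder_lag_step_ms)
    natural_trials = study.trials_of(CONDITIONS[0])

    prediction: dict = {}
    f1_full: dict = {}
    trf_by_pathway: dict = {}
    roi_series_by_pathway: dict = {}

    for pathway in pathways:
        # --- stage 4: denoise, invert, aggregate -------------------------
        roi_file = cache / f"roi-{pathway}-{chash}.npy" if cache else None
        if roi_file is not None and roi_file.exists():
            roi_series = np.load(roi_file)
        else:
            roi_series = np.empty((n_trials, cfg.n_roi, len(envelopes[0])))
            for t in range(n_trials):
                sens = _pathway_trial(
                    study, pathway, t, mcca_model, cfg.n_components, cfg.single_trial_subject
                )
                src = apply_inverse(inv_op, sens)
                roi_series[t] = aggregate_roi(src, gt.parcellation, cfg.fs).values
            if roi_file is not None:
                np.save(roi_file, roi_series)
        roi_series_by_pathway[pathway] = roi_series

        # --- stage 5: decoder leave-one-out on the natural condition -----
        trials = [(envelopes[t], roi_series[t]) for t in natural_trials]
        results = loo_crossval(
            trials,
            lags_ms=decoder_lags,
            ridge_grid=cfg.ridge_grid,
            fs=cfg.fs,
            method_tag=pathway,
        )
        rs = np.array([res.r for res in results])
        zs = np.array([res.z for res in results])
        prediction[pathway] = {
            "r": rs.tolist(),
            "z": zs.tolist(),
            "mean_r": float(np.nanmean(rs)),
            "mean_z": float(np.nanmean(zs)),
        }

        # --- stage 6: per-trial encoder TRFs and full-network F1 ---------
        trf_weights = np.empty((n_trials, cfg.n_roi, encoder_lags.size))
        for t in range(n_trials):
            model = fit_encoder(
                envelopes[t], roi_series[t], lags_ms=encoder_lags,
                ridge=cfg.encoder_ridge, fs=cfg.fs,
            )
            trf_weights[t] = model.weights
        trf_by_pathway[pathway] = trf_weights

        feats = np.stack(
            [vectorize_network(trf_connectivity(trf_weights[t]).values) for t in range(n_trials)]
        )
        emb = embed_2d(
            feats, method=cfg.embed_method,
            seed=child_seed(cfg.seed, f"embed-{pathway}"), perplexity=cfg.perplexity,
        )
        f1_full[pathway] = kmeans_f1(
            emb, study.condition_labels, n_reps=cfg.kmeans_reps,
            seed=child_seed(cfg.seed, f"f1-{pathway}"),
        )

    # --- stage 7: multi-scale community structure (hyperaligned) ---------
    scan_report: dict = {}
    windows_f1: dict = {}
    coupling: dict = {}
    if multiscale and "hyperaligned" in pathways:
        trf_weights = trf_by_pathway["hyperaligned"]
        trial_nets = [trf_connectivity(trf_weights[t]) for t in range(n_trials)]
        cond_nets = {
            cond: mean_connectivity(
                [trial_nets[t] for t in study.trials_of(cond)], tag=cond
            )
            for cond in CONDITIONS
        }
        t_grid = np.round(
            np.arange(1, int(round(cfg.t_grid_max * 100)) + 1) * 0.01, 2
        )
        scans = {
            cond: scan_densities(
                cond_nets[cond], t_grid=t_grid, gamma=cfg.gamma,
                n_runs=cfg.scan_n_runs, seed=child_seed(cfg.seed, f"scan-{cond}"),
            )
            for cond in CONDITIONS
        }
        # separability F1 at each density, from per-trial thresholded networks
        f1_curve = np.empty(t_grid.size)
        for k, t_val in enumerate(t_grid):
            feats = np.stack(
                [
                    vectorize_network(threshold_density(net, float(t_val)).values)
                    for net in trial_nets
                ]
            )
            emb = embed_2d(
                feats, method=cfg.embed_method,
                seed=child_seed(cfg.seed, f"embed-scan-{k}"), perplexity=cfg.perplexity,
            )
            f1_curve[k] = kmeans_f1(
                emb, study.condition_labels, n_reps=cfg.scan_kmeans_reps,
                seed=child_seed(cfg.seed, f"f1-scan-{k}"),
            )
        selected = select_scale(scans[CONDITIONS[0]], f1_curve)
        from .network import detect_communities

        scan_report = {"densities": t_grid.tolist(), "f1_curve": f1_curve.tolist(),
                       "selected_density": selected}
        for cond in CONDITIONS:
            final = detect_communities(
                threshold_density(cond_nets[cond], selected),
                gamma=cfg.gamma, n_runs=cfg.final_n_runs,
                seed=child_seed(cfg.seed, f"final-detect-{cond}"),
            )
            scan_report[cond] = {
                "Q": scans[cond].Q.tolist(),
                "vi": scans[cond].vi.tolist(),
                "selected_partition": final.labels.tolist(),
                "selected_Q": final.quality,
                "n_communities": final.n_communities,
            }

        # --- stage 8: TRF window clustering and within-community coupling
        windows_raw = window_cluster(
            trf_weights, study.condition_labels, lags_ms=encoder_lags,
            windows_ms=cfg.windows_ms, method=cfg.embed_method,
            seed=child_seed(cfg.seed, "windows"), n_reps=cfg.kmeans_reps,
            perplexity=cfg.perplexity,
        )
        windows_f1 = {f"{int(lo)}-{int(hi)}": v for (lo, hi), v in windows_raw.items()}

        # coupling between two regions that share a community under natural
        # speech but fall in different communities under reversed speech --
        # their TRFs should be tightly coupled only in the natural condition
        nat_labels = gt.community_labels[CONDITIONS[0]]
        rev_labels = gt.community_labels[CONDITIONS[1]]
        largest = np.bincount(nat_labels).argmax()
        members = np.flatnonzero(nat_labels == largest)
        pair = (members[0], members[-1])
        if rev_labels[pair[0]] == rev_labels[pair[1]]:
            for a in members:
                for b in members[::-1]:
                    if rev_labels[a] != rev_labels[b]:
                        pair = (a, b)
                        break
                else:
                    continue
                break
        for cond in CONDITIONS:
            idx = study.trials_of(cond)
            mean_trf = trf_weights[idx].mean(axis=0)
            coupling[cond] = coupling_correlation(
                mean_trf[pair[0]], mean_trf[pair[1]], encoder_lags
            )

    provenance = {
        "seed": cfg.seed,
        "config_hash": chash,
        "pathways": list(pathways),
        "package": "trfnet 0.1.0",
    }
    if cache is not None:
        manifest = {}
        for f in sorted(cache.glob(f"*{chash}*")):
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        provenance["artifacts"] = manifest
    return RunReport(
        config=cfg.to_dict(),
        prediction=prediction,
        f1_full=f1_full,
        windows_f1=windows_f1,
        scan=scan_report,
        coupling=coupling,
        provenance=provenance,
    )


def compare_pathways(report: RunReport, n_boot: int = 1000, seed: int | None = None) -> dict:
    """Rank pathways by mean Fisher-z decoding accuracy with bootstrap CIs."""
    if len(report.prediction) < 2:
        raise ValueError("report must contain at least 2 pathways")
    rng = np.random.default_rng(child_seed(seed, "bootstrap"))
    summary = {}
    for pathway, pred in report.prediction.items():
        z = np.asarray(pred["z"], dtype=float)
        z = z[np.isfinite(z)]
        boots = np.array(
            [rng.choice(z, size=z.size, replace=True).mean() for _ in range(n_boot)]
        )
        summary[pathway] = {
            "mean_z": float(z.mean()),
            "ci_low": float(np.percentile(boots, 2.5)),
            "ci_high": float(np.percentile(boots, 97.5)),
            "n_trials": int(z.size),
        }
    ordering = sorted(summary, key=lambda p: summary[p]["mean_z"], reverse=True)
    return {"summary": summary, "ordering": ordering}
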