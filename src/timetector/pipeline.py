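"""End-to-end run: simulate -> inject -> preprocess -> train -> detect -> score.

The pipeline mirrors the study protocol: a chronological 80/10/10 split, a
min–max scaler fitted on the training segment, sliding 24-step windows,
denoising corruption of the training inputs, twin-branch training with
early stopping, and dynamic-threshold flagging of the test segment.
Labelled spikes are injected into the test segment only, so the labelled
evaluation mimics annotating a held-out portion of an otherwise unlabelled
stream while training data stay uncontaminated.

Every quantity the run reports is recomputed from the artifacts of that
run; a fixed seed makes the whole chain bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .detect import (
    dynamic_threshold,
    flag_anomalies,
    predict_future,
    reconstruct_series,
    reconstruction_errors,
)
from .evaluate import correlation_analysis, detection_metrics, regression_metrics, roc_auc
from .model import TTTBAD, TTTBADConfig, save as save_model, train
from .preprocess import (
    apply_scaler,
    chronological_split,
    fit_scaler,
    make_windows,
    with_corruption,
)
from .simulate import PROFILES, SimConfig, generate_barn_series, inject_anomalies, random_spike_events

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved settings of one full run (written next to its outputs)."""

    profile: str = "indoor"
    n_days: int = 20
    step_minutes: int = 5
    seed: int = 7
    spike_rate: float = 0.01
    spike_magnitude: float = 8.0
    split_fractions: tuple = (0.8, 0.1, 0.1)
    window_length: int = 24
    horizon: int = 1
    stride: int = 1
    feature_range: tuple = (0.0, 1.0)
    noise_sd: float = 0.1
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 4
    learning_rate: float = 1e-3
    threshold_window: int = 288
    threshold_k: float = 3.0
    out_dir: str | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    metrics: dict
    model: TTTBAD
    feedback: object
    errors: object
    thresholds: object
    anomaly_mask: object
    labels_scored: np.ndarray
    scaler: object
    frame: object
    files: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    sim = SimConfig(
        profile=cfg.profile, n_days=cfg.n_days, step_minutes=cfg.step_minutes, seed=cfg.seed
    )
    clean = generate_barn_series(sim)
    T = clean.n_rows
    n_train = int(np.floor(cfg.split_fractions[0] * T))
    n_val = int(np.floor(cfg.split_fractions[1] * T))
    test_start = n_train + n_val

    events = random_spike_events(
        clean, cfg.spike_rate, cfg.spike_magnitude, seed=cfg.seed + 101, start=test_start
    )
    frame, labels = inject_anomalies(clean, events, seed=cfg.seed + 202)

    train_frame, val_frame, test_frame = chronological_split(frame, cfg.split_fractions)
    scaler = fit_scaler(train_frame, cfg.feature_range)
    train_s = apply_scaler(train_frame, scaler)
    val_s = apply_scaler(val_frame, scaler)
    test_s = apply_scaler(test_frame, scaler)

    mk = dict(window_length=cfg.window_length, horizon=cfg.horizon, stride=cfg.stride)
    train_ds = with_corruption(make_windows(train_s, split="train", **mk), cfg.noise_sd, cfg.seed + 303)
    val_ds = with_corruption(make_windows(val_s, split="val", **mk), cfg.noise_sd, cfg.seed + 404)
    test_ds = make_windows(test_s, split="test", **mk)

    model_cfg = TTTBADConfig(
        features=len(PROFILES[cfg.profile]),
        window_length=cfg.window_length,
        horizon=cfg.horizon,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        learning_rate=cfg.learning_rate,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    model = TTTBAD(model_cfg)
    model, feedback = train(model, train_ds, val_ds)

    # detection on the (label-bearing) test segment
    errors = reconstruction_errors(model, test_ds)
    window = min(cfg.threshold_window, errors.n_rows)
    thresholds = dynamic_threshold(errors, window=window, k=cfg.threshold_k)
    mask = flag_anomalies(errors, thresholds)
    scored = slice(test_start + errors.offset, test_start + errors.offset + errors.n_rows)
    labels_scored = labels[scored]
    det = detection_metrics(labels_scored, mask.flags)
    rocs = roc_auc(labels_scored, errors.values, errors.feature_names)
    aucs = {k: (r.auc if r is not None else None) for k, r in rocs.items()}
    defined = [a for a in aucs.values() if a is not None]

    # clean-data reconstruction quality on the validation segment
    recon_val, lo = reconstruct_series(model, val_ds)
    r2 = {}
    for i, name in enumerate(val_ds.feature_names):
        r2[name] = regression_metrics(val_s.values[lo : lo + len(recon_val), i], recon_val[:, i]).r2
    r2_defined = [v for v in r2.values() if v is not None]

    corr = correlation_analysis(clean)
    th_idx = {n: i for i, n in enumerate(clean.feature_names)}
    temp_hum_r = float(corr.matrix.iloc[th_idx["temperature"], th_idx["humidity"]])

    metrics = {
        "seed": cfg.seed,
        "package_version": __version__,
        "sizes": {
            "rows_total": T,
            "rows_train": n_train,
            "rows_val": n_val,
            "rows_test": T - test_start,
            "windows_train": train_ds.n_windows,
            "epochs_run": len(feedback.epochs),
        },
        "threshold": {"window": window, "k": cfg.threshold_k},
        "detection": det.as_dict(),
        "roc_auc": aucs,
        "roc_auc_mean": float(np.mean(defined)) if defined else None,
        "reconstruction_r2": r2,
        "reconstruction_r2_mean": float(np.mean(r2_defined)) if r2_defined else None,
        "anomaly_rate_pct": {n: float(p) for n, p in zip(mask.feature_names, mask.percentages)},
        "temperature_humidity_correlation": temp_hum_r,
    }

    result = PipelineResult(
        config=cfg,
        metrics=metrics,
        model=model,
        feedback=feedback,
        errors=errors,
        thresholds=thresholds,
        anomaly_mask=mask,
        labels_scored=labels_scored,
        scaler=scaler,
        frame=frame,
    )
    if cfg.out_dir is not None:
        result.files = _write_artifacts(result, model, test_ds, scaler, frame, labels)
    return result


def _write_artifacts(result: PipelineResult, model, test_ds, scaler, frame, labels) -> dict:
    import pandas as pd
    import yaml

    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {"pipeline": asdict(result.config), "package_version": __version__}, fh, sort_keys=True
        )
    files["config"] = cfg_path

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(result.metrics, indent=2, sort_keys=True) + "\n")
    files["metrics"] = metrics_path

    err = result.errors
    rows = []
    for i in range(err.n_rows):
        for c, name in enumerate(err.feature_names):
            rows.append(
                {
                    "timestamp": err.timestamps[i] if err.timestamps is not None else i,
                    "feature": name,
                    "error": err.values[i, c],
                    "threshold": result.thresholds.threshold[i, c],
                    "flag": int(result.anomaly_mask.flags[i, c]),
                    "label": int(result.labels_scored[i, c]),
                }
            )
    anomalies_path = out / "anomalies.csv"
    pd.DataFrame(rows).to_csv(anomalies_path, index=False)
    files["anomalies"] = anomalies_path

    feedback_path = out / "feedback.csv"
    result.feedback.to_csv(feedback_path)
    files["feedback"] = feedback_path

    fc = predict_future(model, test_ds, scaler)
    from .preprocess import invert_scaler

    actuals = invert_scaler(test_ds.Y_future, scaler)
    forecasts_path = out / "forecasts.csv"
    fc.to_dataframe(actuals).to_csv(forecasts_path, index=False)
    files["forecasts"] = forecasts_path

    from .evaluate import correlation_analysis

    corr_path = out / "correlation.csv"
    correlation_analysis(frame).matrix.to_csv(corr_path)
    files["correlation"] = corr_path

    model_path = out / "model.npz"
    save_model(model, model_path)
    files["model"] = model_path
    scaler_path = out / "scaler.json"
    from .preprocess import scaler_to_json

    scaler_to_json(scaler, scaler_path)
    files["scaler"] = scaler_path
    return files
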