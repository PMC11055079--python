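"""Small end-to-end run: simulate, train, detect, evaluate.

Uses a short series and a reduced epoch budget so it finishes in about a
minute on one CPU; the shipped tests run the full-scale version.
"""

from timetector.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    profile="indoor",
    n_days=6,
    seed=7,
    spike_rate=0.01,        # 1% of test cells get an 8-sigma spike
    max_epochs=6,
    threshold_window=160,   # trailing samples for the rolling statistics
    threshold_k=3.0,
)
result = run_pipeline(config)

m = result.metrics
det = m["detection"]
print(f"trained {m['sizes']['epochs_run']} epochs on {m['sizes']['windows_train']} windows")
print(f"spike recall    {det['recall']:.3f}   (share of injected spikes flagged)")
print(f"spike precision {det['precision']:.3f}   (share of flags that are real spikes)")
print(f"accuracy        {det['accuracy']:.4f}, mean ROC AUC {m['roc_auc_mean']:.3f}")
print(f"validation reconstruction R^2 (mean over features): "
      f"{m['reconstruction_r2_mean']:.3f}")
print("flagged share per feature (%):",
      {k: round(v, 2) for k, v in m["anomaly_rate_pct"].items()})

# Recall counts recovered ground-truth spikes; precision is limited by how
# often ordinary noise exceeds the rolling threshold; R^2 close to 1 means
# the twin-branch autoencoder reproduces clean data almost perfectly.
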