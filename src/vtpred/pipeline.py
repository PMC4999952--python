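"""End-to-end orchestration: extract, compare, train three models, report.

The experiment mirrors the intended clinical study design: a cohort of
labeled 5-minute windows is reduced to 14-parameter feature vectors, the
two groups are compared parameter by parameter, a single stratified
2/3 : 1/3 partition is drawn, and one perceptron per feature set
(HRV-11, RRV-3, combined-14) is trained and evaluated on the shared
held-out test set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classifier import (EvalReport, MLPModel, TrainConfig, evaluate, predict,
                         split_stratified, train_mlp)
from .hrv_features import hrv_vector
from .peak_detection import detect_r_peaks
from .rr_preprocess import preprocess_rr
from .rrv_features import breath_series, rrv_stats
from .signal_io import (FEATURE_NAMES, HRV_FEATURES, RRV_FEATURES,
                        FeatureVector, LabeledWindow)

__all__ = [
    "FEATURE_SETS",
    "DEFAULT_HIDDEN_SIZES",
    "ExperimentConfig",
    "ExperimentResult",
    "WindowExtractionError",
    "extract_features",
    "extract_cohort",
    "compare_groups",
    "run_experiment",
    "report",
]

logger = logging.getLogger(__name__)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "hrv": HRV_FEATURES,
    "rrv": RRV_FEATURES,
    "all": FEATURE_NAMES,
}

DEFAULT_HIDDEN_SIZES: dict[str, int] = {"hrv": 5, "rrv": 5, "all": 13}


class WindowExtractionError(RuntimeError):
    """A stage failed on this window; it must be excluded, not trained on."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for :func:`run_experiment`."""

    feature_sets: tuple[str, ...] = ("hrv", "rrv", "all")
    hidden_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HIDDEN_SIZES))
    train_fraction: float = 2 / 3
    split_seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    outdir: Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")


@dataclass
class ExperimentResult:
    model: MLPModel
    report: EvalReport
    feature_set: str
    n_train: int
    n_test: int


def extract_features(window: LabeledWindow) -> FeatureVector:
    """Run the full extraction chain on one window.

    ECG: R-peak detection, ectopic flag + IPFM correction, 11 HRV
    parameters.  Respiration: band-pass, positive-peak detection, 3 RRV
    parameters.  Per-window QC counts are logged.

    Raises
    ------
    WindowExtractionError
        When any stage fails; the message carries the reason.
    """
    try:
        beats = detect_r_peaks(window.ecg)
        nn = preprocess_rr(beats)
        hrv = hrv_vector(nn)
        breaths = breath_series(window.resp)
        rrv = rrv_stats(breaths.periods)
    except (ValueError, RuntimeError) as exc:
        raise WindowExtractionError(f"{window.source_id}: {exc}") from exc
    logger.info("%s: %d beats, %d corrected ectopic, %d breaths",
                window.source_id, len(beats), nn.n_corrected, len(breaths.peak_times))
    return FeatureVector(**hrv, **rrv)


def extract_cohort(windows: list[LabeledWindow]
                   ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract features for every window; QC failures are excluded.

    Returns the feature frame (features + ``label``, ``source_id`` index)
    and the list of ``(source_id, reason)`` exclusions.
    """
    rows = {}
    labels = {}
    excluded: list[tuple[str, str]] = []
    for window in windows:
        try:
            fv = extract_features(window)
        except WindowExtractionError as exc:
            logger.warning("excluding window: %s", exc)
            excluded.append((window.source_id, str(exc)))
            continue
        rows[window.source_id] = {n: getattr(fv, n) for n in FEATURE_NAMES}
        labels[window.source_id] = window.label
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["label"] = pd.Series(labels)
    df.index.name = "source_id"
    return df, excluded


def compare_groups(features: pd.DataFrame, test: str = "mannwhitney",
                   alternative: str = "two-sided") -> pd.DataFrame:
    """Per-parameter group means, SDs and a two-sample p-value.

    ``test`` is ``mannwhitney`` (default; several parameters are heavily
    right-skewed) or ``ttest`` (Welch).  Rows follow the fixed parameter
    order; groups are ``label`` +1 (pre-VT) vs -1 (control).
    """
    if test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    vt = features[features["label"] > 0]
    ctl = features[features["label"] < 0]
    if len(vt) < 3 or len(ctl) < 3:
        raise ValueError("both groups need at least 3 members")
    rows = []
    for name in FEATURE_NAMES:
        a = vt[name].to_numpy(dtype=float)
        b = ctl[name].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if test == "mannwhitney":
            p = float(sstats.mannwhitneyu(a, b, alternative=alternative).pvalue)
        else:
            p = float(sstats.ttest_ind(a, b, equal_var=False,
                                       alternative=alternative).pvalue)
        rows.append({
            "parameter": name,
            "control_mean": float(np.mean(b)), "control_sd": float(np.std(b, ddof=1)),
            "vt_mean": float(np.mean(a)), "vt_sd": float(np.std(a, ddof=1)),
            "p_value": p, "test": test,
        })
    return pd.DataFrame(rows).set_index("parameter")


def run_experiment(features: pd.DataFrame,
                   cfg: ExperimentConfig | None = None
                   ) -> dict[str, ExperimentResult]:
    """Train and evaluate one model per feature set on a shared partition.

    ``features`` must carry the 14 parameters plus ``label``.  The same
    stratified train/test split underlies every feature set.  With
    ``cfg.outdir`` set, models (JSON), reports (JSON), ROC points (CSV)
    and a text summary are written; reruns are byte-identical.
    """
    cfg = cfg or ExperimentConfig()
    labels = features["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if counts.min() < 6:
        raise ValueError("need at least 6 windows per class")
    train_idx, test_idx = split_stratified(labels, cfg.train_fraction,
                                           seed=cfg.split_seed)
    results: dict[str, ExperimentResult] = {}
    for fs_name in cfg.feature_sets:
        names = FEATURE_SETS[fs_name]
        x = features.loc[:, list(names)].to_numpy(dtype=float)
        n_hidden = cfg.hidden_sizes.get(fs_name, DEFAULT_HIDDEN_SIZES[fs_name])
        model = train_mlp(x[train_idx], labels[train_idx], n_hidden, cfg.train)
        scores = predict(model, x[test_idx])
        rep = evaluate(scores, labels[test_idx])
        results[fs_name] = ExperimentResult(model=model, report=rep,
                                            feature_set=fs_name,
                                            n_train=len(train_idx),
                                            n_test=len(test_idx))
        logger.info("%s: trained %d epochs (mse %.3g), test accuracy %.3f",
                    fs_name, model.epochs_run, model.final_mse, rep.accuracy)
    if cfg.outdir is not None:
        _write_outputs(results, cfg)
    return results


def _write_outputs(results: dict[str, ExperimentResult],
                   cfg: ExperimentConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    text, doc = report(results)
    (outdir / "summary.txt").write_text(text)
    (outdir / "report.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    for fs_name, res in results.items():
        res.model.to_json(outdir / f"model_{fs_name}.json")
        if res.report.roc is not None:
            roc = pd.DataFrame(res.report.roc, columns=["fpr", "tpr"])
            roc.to_csv(outdir / f"roc_{fs_name}.csv", index=False)


def _pct(value: float, num: int, den: int) -> str:
    return f"{100 * value:.1f} ({num}/{den})"


def report(results: dict[str, ExperimentResult]) -> tuple[str, dict]:
    """Human-readable summary plus a machine-readable JSON document."""
    if not results:
        raise ValueError("empty results")
    lines = ["model      input  sensitivity    specificity    accuracy"
             "       ppv            npv            auc"]
    doc: dict[str, dict] = {}
    for fs_name, res in results.items():
        r = res.report
        auc_text = f"{r.auc:.2f}" if r.auc is not None else "n/a"
        lines.append(
            f"{fs_name:<10} {len(FEATURE_SETS[fs_name]):<6} "
            f"{_pct(r.sensitivity, r.tp, r.tp + r.fn):<14} "
            f"{_pct(r.specificity, r.tn, r.tn + r.fp):<14} "
            f"{_pct(r.accuracy, r.tp + r.tn, r.tp + r.tn + r.fp + r.fn):<14} "
            f"{_pct(r.ppv, r.tp, r.tp + r.fp):<14} "
            f"{_pct(r.npv, r.tn, r.tn + r.fn):<14} "
            f"{auc_text}")
        doc[fs_name] = {
            "n_inputs": len(FEATURE_SETS[fs_name]),
            "n_train": res.n_train, "n_test": res.n_test,
            **res.report.to_dict(),
        }
    return "\n".join(lines) + "\n", doc


def plot_roc(results: dict[str, ExperimentResult], path: str | Path) -> Path:
    """Save an ROC overlay of all evaluated models (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    styles = {"hrv": "--", "rrv": "-.", "all": "-"}
    for fs_name, res in results.items():
        if res.report.roc is None:
            continue
        fpr, tpr = zip(*res.report.roc)
        ax.plot(fpr, tpr, styles.get(fs_name, "-"),
                label=f"{fs_name} (AUC {res.report.auc:.2f})")
    ax.plot([0, 1], [0, 1], ":", color="grey", label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
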