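"""Run configuration and the full encode→scale→rank→select→train→evaluate flow.

A :class:`RunConfig` carries every parameter that influences output; its
defaults equal the tuned pipeline (min-max scaling, tau 0.7, top-k 350,
RBF kernel with C=11 and gamma=0.1, 10-fold CV). Re-running the same
configuration reproduces every artifact bit-for-bit: nothing
time-dependent is written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classifier, encoding, evaluation, pssm_io, selection

log = logging.getLogger("snare-sap")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Inputs are either a directory of ``.pssm`` files plus a label table
    (``pssm_dir``/``labels``) or a precomputed feature table
    (``train_features``); ``test_features``/``test_pssm_dir`` optionally
    add an independent test evaluation.
    """

    out_dir: str = "run"
    pssm_dir: str | None = None
    labels: str | None = None
    train_features: str | None = None
    test_features: str | None = None
    test_pssm_dir: str | None = None
    test_labels: str | None = None
    scaling: str = "minmax"
    length_normalize: bool = False
    rfe: selection.RFEConfig = field(default_factory=selection.RFEConfig)
    top_k: int = 350
    svm: classifier.SVMConfig = field(default_factory=classifier.SVMConfig)
    folds: int = 10
    seed: int = 1

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "pssm_dir": self.pssm_dir,
            "labels": self.labels,
            "train_features": self.train_features,
            "test_features": self.test_features,
            "test_pssm_dir": self.test_pssm_dir,
            "test_labels": self.test_labels,
            "scaling": self.scaling,
            "length_normalize": self.length_normalize,
            "rfe": {
                "ranking_C": self.rfe.ranking_C,
                "corr_threshold": self.rfe.corr_threshold,
                "step": self.rfe.step,
                "seed": self.rfe.seed,
            },
            "top_k": self.top_k,
            "svm": self.svm.to_dict(),
            "folds": self.folds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rfe" in d and isinstance(d["rfe"], dict):
            d["rfe"] = selection.RFEConfig(**d["rfe"])
        if "svm" in d and isinstance(d["svm"], dict):
            d["svm"] = classifier.SVMConfig.from_dict(d["svm"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_pssm_dir(pssm_dir, labels_path=None) -> encoding.FeatureMatrix:
    """Encode every ``.pssm`` file in a directory into one feature matrix.

    Labels, when given, are matched to profiles by file stem.
    """
    pssm_dir = Path(pssm_dir)
    files = sorted(pssm_dir.glob("*.pssm"))
    if not files:
        raise FileNotFoundError(f"no .pssm files in {pssm_dir}")
    profiles = [pssm_io.parse_pssm(f) for f in files]
    labels = None
    if labels_path is not None:
        table = pssm_io.read_labels(labels_path)
        missing = [p.sequence_id for p in profiles if p.sequence_id not in table]
        if missing:
            raise KeyError(f"profiles without labels: {missing[:5]}")
        labels = [table[p.sequence_id] for p in profiles]
    return encoding.encode_profiles(profiles, labels)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e

    return wrap


def run_pipeline(
    config: RunConfig,
    train: encoding.FeatureMatrix | None = None,
    test: encoding.FeatureMatrix | None = None,
) -> evaluation.EvaluationReport:
    """Execute the full pipeline and write all artifacts.

    ``train``/``test`` matrices may be passed in memory (they override
    the configured paths). Artifacts under ``config.out_dir``: the echoed
    configuration, the feature ranking, the trained model, the CV report
    and — when a test set is given — the independent-test report. The
    returned report is the test report if a test set exists, else the CV
    report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    run_log = []

    def note(msg: str) -> None:
        log.info(msg)
        run_log.append(msg)

    # ---- load / encode -------------------------------------------------
    if train is None:
        if config.train_features:
            train = _stage("load-features")(
                pssm_io.read_feature_table, config.train_features
            )
        elif config.pssm_dir:
            train = _stage("encode")(load_pssm_dir, config.pssm_dir, config.labels)
        else:
            raise PipelineError("stage 'load' failed: no training input configured")
    note(f"train matrix: {train.n_samples} x {train.n_features}")
    if test is None:
        if config.test_features:
            test = _stage("load-features")(
                pssm_io.read_feature_table, config.test_features
            )
        elif config.test_pssm_dir:
            test = _stage("encode")(
                load_pssm_dir, config.test_pssm_dir, config.test_labels
            )

    if not (1 <= config.top_k <= train.n_features):
        raise PipelineError(
            f"stage 'select' failed: top_k={config.top_k} out of range "
            f"[1, {train.n_features}]"
        )

    # ---- scale (fit on train only) --------------------------------------
    scaler = _stage("scale")(encoding.fit_scaler, train, config.scaling)
    train_scaled = _stage("scale")(encoding.apply_scaler, train, scaler)
    note(f"scaling: {config.scaling}")

    # ---- rank + select ---------------------------------------------------
    ranking = _stage("rank")(selection.rank_features_rfe_cbr, train_scaled, config.rfe)
    pssm_io.write_ranking(ranking, out / "ranking.csv")
    selected = _stage("select")(selection.select_top_k, train_scaled, ranking, config.top_k)
    note(
        f"ranking: tau={config.rfe.corr_threshold} step={config.rfe.step} "
        f"C={config.rfe.ranking_C}; selected top {config.top_k}"
    )

    # ---- cross-validate --------------------------------------------------
    cv_report = _stage("cross-validate")(
        evaluation.cross_validate, selected, config.svm, config.folds, config.seed
    )
    cv_report.to_json(out / "cv_report.json")
    note(
        f"cv ({config.folds}-fold, seed {config.seed}): "
        f"acc={cv_report.acc:.4f} mcc={cv_report.mcc:.4f}"
    )

    # ---- final model -----------------------------------------------------
    model = _stage("train")(
        classifier.train,
        selected,
        config.svm,
        scaler,
        train.feature_ids,
    )
    classifier.save_model(model, out / "model.json")

    # ---- independent test ------------------------------------------------
    report = cv_report
    if test is not None:
        labels, scores = _stage("predict")(classifier.predict, model, test)
        if test.y is not None:
            report = _stage("evaluate")(evaluation.evaluate, test.y, labels, scores)
            report.to_json(out / "test_report.json")
            note(
                f"independent test: acc={report.acc:.4f} sn={report.sn:.4f} "
                f"sp={report.sp:.4f} mcc={report.mcc:.4f} auc={report.auc:.4f}"
            )
        import pandas as pd

        pd.DataFrame({"label": labels, "score": scores}).to_csv(
            out / "predictions.csv", index=False
        )
    (out / "run.log").write_text("\n".join(run_log) + "\n")
    return report
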