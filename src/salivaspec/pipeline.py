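"""End-to-end screening workflow.

``run_pipeline`` executes the full chain on a cohort (simulated or loaded
from CSV):

    load/simulate -> average replicates -> truncate -> SG 2nd derivative ->
    vector normalise -> T2/Q outlier removal -> Kennard-Stone 70/30 split ->
    train-fit centring -> train-fit PCA -> classifier fit -> evaluate train
    and test -> marker extraction

Every statistic that could leak information — the centring mean, the PCA
loadings, CV hyperparameter choices — is fitted on the training split only
and merely *applied* to the test split, so the test metrics are an external
validation on blind samples.  All randomness flows from the run seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger("salivaspec.pipeline")

from . import __version__
from .dataset import SpectralDataset, average_replicates, read_dataset
from .preprocess import (
    CentreModel,
    PreprocessConfig,
    apply_centre,
    fit_centre,
    preprocess,
)
from .chemometrics import (
    GAConfig,
    fit_pca,
    ga_select,
    hotelling_q_outliers,
    kennard_stone_split,
    project,
    select_k,
)
from .classify import (
    fit_discriminant,
    fit_knn,
    fit_plsda,
    fit_svm,
    predict_discriminant,
    predict_knn,
    predict_plsda,
    predict_svm,
)
from .markers import (
    assign_bands,
    dbm_spectrum,
    extract_markers,
    load_assignments,
    total_loading,
)
from .synth import CohortConfig, simulate_cohort
from .validate import ConfusionMatrix, MetricsReport, confusion, metrics, roc_auc

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_models", "MODELS"]

MODELS = ("pca-lda", "pca-qda", "pca-svm", "ga-lda", "ga-qda", "pls-da", "knn", "svm")


@dataclass
class RunConfig:
    """Everything one screening run needs; seed is mandatory for any
    stochastic step and defaults the cohort seed when simulating."""

    endpoint: str = "lung"
    cohort: CohortConfig | None = None  # simulate when set ...
    spectra_path: str | None = None  # ... else load these
    metadata_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    outlier_alpha: float = 0.95
    outlier_variance: float = 0.95  # explained-variance kept by the outlier PCA
    split_fraction: float = 0.70
    model: str = "pca-qda"
    n_components: int | None = None  # PCs or LVs; CV-chosen when None
    k_limit: int = 15
    k_strategy: str = "cv_accuracy"
    priors: str = "equal"
    ga: GAConfig | None = None
    attach_assignments: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.cohort is None and (self.spectra_path is None or self.metadata_path is None):
            raise ValueError("provide either a CohortConfig or spectra/metadata paths")


@dataclass
class RunReport:
    """Structured record of one run: stage bookkeeping, model summary,
    train/test performance and the marker table."""

    endpoint: str
    model: str
    counts: dict
    n_components: int | None
    explained_pct: float | None
    train_confusion: ConfusionMatrix
    train_metrics: MetricsReport
    test_confusion: ConfusionMatrix
    test_metrics: MetricsReport
    markers: pd.DataFrame
    seed: int
    version: str = __version__
    artifacts: dict = field(default_factory=dict, repr=False)

    def to_json(self, **dumps_kwargs) -> str:
        payload = {
            "endpoint": self.endpoint,
            "model": self.model,
            "counts": self.counts,
            "n_components": self.n_components,
            "explained_pct": self.explained_pct,
            "train_confusion": asdict(self.train_confusion),
            "train_metrics": asdict(self.train_metrics),
            "train_metrics_printed": self.train_metrics.as_printed(),
            "test_confusion": asdict(self.test_confusion),
            "test_metrics": asdict(self.test_metrics),
            "test_metrics_printed": self.test_metrics.as_printed(),
            "markers": self.markers.to_dict(orient="records"),
            "seed": self.seed,
            "version": self.version,
        }
        return json.dumps(payload, **dumps_kwargs)

    def summary(self) -> str:
        """Human-readable block mirroring the publication table layout."""
        lines = [
            f"endpoint: {self.endpoint}   model: {self.model}   seed: {self.seed}",
            "counts: " + ", ".join(f"{k}={v}" for k, v in self.counts.items()),
        ]
        if self.n_components is not None:
            ev = f" ({self.explained_pct:.1f}% of explained variance)" if self.explained_pct else ""
            lines.append(f"components: {self.n_components}{ev}")
        header = f"{'':10s}{'AC':>6s}{'SENS':>6s}{'SPEC':>6s}{'F':>6s}{'G':>6s}"
        lines.append(header)
        for name, rep in (("Training", self.train_metrics), ("Testing", self.test_metrics)):
            p = rep.as_printed()
            cells = "".join(
                f"{p[m]:>6.2f}" if p[m] is not None else f"{'--':>6s}"
                for m in ("AC", "SENS", "SPEC", "F", "G")
            )
            lines.append(f"{name:10s}{cells}")
        if self.test_metrics.auc is not None:
            lines.append(f"test AUC: {self.test_metrics.auc:.2f}")
        return "\n".join(lines)


class PipelineError(RuntimeError):
    """An error annotated with the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self._t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - self._t0)
            return False

    return _Ctx()


def prepare_cohort(config: RunConfig):
    """Stages up to and including the train/test split.

    Returns ``(raw_averaged, train_ds, test_ds, counts)`` where the two
    datasets are preprocessed (not yet centred) sample-level spectra.
    """
    counts: dict = {}
    with _stage("load"):
        if config.cohort is not None:
            ds = simulate_cohort(config.cohort)
        else:
            ds = read_dataset(config.spectra_path, config.metadata_path)
        counts["loaded"] = ds.n_rows
    with _stage("average_replicates"):
        raw = average_replicates(ds)
        counts["averaged"] = raw.n_rows
    with _stage("preprocess"):
        pre = preprocess(raw, config.preprocess)
    with _stage("outliers"):
        X = pre.intensities
        mean = X.mean(axis=0)
        k_out = select_k(
            X - mean, strategy="explained_variance_threshold",
            threshold=config.outlier_variance, limit=min(X.shape) - 1,
        )
        out_pca = fit_pca(X - mean, k_out)
        report = hotelling_q_outliers(out_pca, X - mean, alpha=config.outlier_alpha)
        keep = ~report.flags
        pre = pre.subset(np.nonzero(keep)[0])
        raw = raw.subset(np.nonzero(keep)[0])
        counts["outliers_removed"] = int(report.flags.sum())
        counts["retained"] = pre.n_rows
        for cls in ("positive", "control"):
            if np.sum(pre.labels == cls) == 0:
                raise ValueError(f"no {cls} samples left after outlier removal")
    with _stage("split"):
        split = kennard_stone_split(pre, fraction=config.split_fraction, per_class=True)
        train = pre.subset_samples(split.train_ids)
        test = pre.subset_samples(split.test_ids)
        counts["train"] = train.n_rows
        counts["test"] = test.n_rows
    logger.info("cohort prepared: %s", counts)
    return raw, train, test, counts


def _fit_model(config: RunConfig, train: SpectralDataset, centre: CentreModel):
    """Fit the chosen classifier on the centred training spectra.

    Returns ``(predict_fn, n_components, explained_pct, pca_model)`` where
    ``predict_fn`` maps centred spectra to a ClassifierOutput.
    """
    Xt = apply_centre(centre, train).intensities
    y = train.labels
    seed = config.seed
    name = config.model
    pca_model = None
    n_comp = None
    explained = None

    if name.startswith("pca-"):
        kind = {"pca-lda": "linear", "pca-qda": "quadratic", "pca-svm": None}[name]
        k = config.n_components or select_k(
            Xt, y, strategy=config.k_strategy, limit=config.k_limit, seed=seed,
            kind=kind or "quadratic",
        )
        pca_model = fit_pca(Xt, k)
        n_comp = k
        explained = float(pca_model.explained_pct.sum())
        scores = pca_model.scores
        if name == "pca-svm":
            clf = fit_svm(scores, y, kernel="rbf", seed=seed)
            predict = lambda Z: predict_svm(clf, project(pca_model, Z))
        else:
            clf = fit_discriminant(scores, y, kind=kind, priors=config.priors)
            predict = lambda Z: predict_discriminant(clf, project(pca_model, Z))
    elif name.startswith("ga-"):
        kind = {"ga-lda": "linear", "ga-qda": "quadratic"}[name]
        ga_cfg = config.ga or GAConfig(seed=seed)
        result = ga_select(Xt, y, ga_cfg)
        cols = result.selected
        clf = fit_discriminant(Xt[:, cols], y, kind=kind, priors=config.priors)
        n_comp = len(cols)
        predict = lambda Z: predict_discriminant(clf, Z[:, cols])
    elif name == "pls-da":
        model = fit_plsda(Xt, y, a=config.n_components, seed=seed)
        n_comp = model.a
        predict = lambda Z: predict_plsda(model, Z)
    elif name == "knn":
        model = fit_knn(Xt, y, k=config.n_components, seed=seed)
        n_comp = model.k
        predict = lambda Z: predict_knn(model, Z)
    elif name == "svm":
        model = fit_svm(Xt, y, kernel="rbf", seed=seed)
        predict = lambda Z: predict_svm(model, Z)
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(name)
    return predict, n_comp, explained, pca_model


def _evaluate(predict, centre: CentreModel, ds: SpectralDataset):
    Z = apply_centre(centre, ds).intensities
    out = predict(Z)
    cm = confusion(ds.labels, out.predicted)
    auc = None
    if len(set(ds.labels)) == 2:
        auc = roc_auc(out.decision_score, ds.labels)
    return cm, metrics(cm, auc=auc)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the whole screening workflow; see the module docstring."""
    raw, train, test, counts = prepare_cohort(config)
    with _stage("centre"):
        centre = fit_centre(train)
    with _stage("fit"):
        predict, n_comp, explained, pca_model = _fit_model(config, train, centre)
    with _stage("evaluate"):
        train_cm, train_rep = _evaluate(predict, centre, train)
        test_cm, test_rep = _evaluate(predict, centre, test)
    with _stage("markers"):
        marker_table = _markers_for(config, raw, train, test, pca_model)
    return RunReport(
        endpoint=config.endpoint,
        model=config.model,
        counts=counts,
        n_components=n_comp,
        explained_pct=explained,
        train_confusion=train_cm,
        train_metrics=train_rep,
        test_confusion=test_cm,
        test_metrics=test_rep,
        markers=marker_table,
        seed=config.seed,
        artifacts={
            "centre": centre,
            "pca": pca_model,
            "predict": predict,
            "raw": raw,
            "train": train,
            "test": test,
        },
    )


def _markers_for(config, raw, train, test, pca_model) -> pd.DataFrame:
    """Marker table: train-fitted PCA loadings + whole-cohort DBM spectra.

    The DBM is descriptive (class-mean difference), not a predictive
    statistic, so it uses every retained sample; only the loadings come
    from the train-fitted model.
    """
    if pca_model is None:
        return pd.DataFrame(columns=["wavenumber", "direction", "loading_weight",
                                     "dbm_value", "assignment"])
    pre_pos = np.vstack([train.rows_for("positive"), test.rows_for("positive")])
    pre_ctl = np.vstack([train.rows_for("control"), test.rows_for("control")])
    dbm_pre = dbm_spectrum(pre_pos, pre_ctl)
    dbm_raw = dbm_spectrum(raw.rows_for("positive"), raw.rows_for("control"))
    table = extract_markers(
        train.axis,
        pca_model.loadings,
        dbm_pre,
        raw_axis=raw.axis,
        dbm_raw=dbm_raw,
    )
    if config.attach_assignments and config.endpoint in ("lung", "prostate"):
        table = assign_bands(table, load_assignments(config.endpoint))
    return table


def compare_models(config: RunConfig, model_list: list[str]) -> pd.DataFrame:
    """Fit several classifiers on one shared prepared cohort and split.

    Returns one row per model with the exact test-set metric suite; every
    model sees the same preprocessing, outlier removal, split, centring and
    seed, so differences reflect the classifiers alone.
    """
    if not model_list:
        raise ValueError("model_list must name at least one model")
    raw, train, test, counts = prepare_cohort(config)
    centre = fit_centre(train)
    rows = []
    for name in model_list:
        cfg = RunConfig(**{**asdict_shallow(config), "model": name})
        predict, n_comp, explained, _ = _fit_model(cfg, train, centre)
        cm, rep = _evaluate(predict, centre, test)
        rows.append(
            {
                "model": name,
                "n_components": n_comp,
                "AC": rep.ac,
                "SENS": rep.sens,
                "SPEC": rep.spec,
                "F": rep.f,
                "G": rep.g,
                "AUC": rep.auc,
            }
        )
    return pd.DataFrame(rows)


def asdict_shallow(config: RunConfig) -> dict:
    """Field dict of a RunConfig without deep-copying nested configs."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a JSON file (nested cohort/preprocess dicts)."""
    with open(path) as fh:
        payload = json.load(fh)
    if "cohort" in payload and isinstance(payload["cohort"], dict):
        payload["cohort"] = CohortConfig(**payload["cohort"])
    if "preprocess" in payload and isinstance(payload["preprocess"], dict):
        payload["preprocess"] = PreprocessConfig(**payload["preprocess"])
    if "ga" in payload and isinstance(payload["ga"], dict):
        payload["ga"] = GAConfig(**payload["ga"])
    return RunConfig(**payload)
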