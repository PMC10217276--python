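"""Config-driven orchestration of the grading and calibration studies.

The qualitative pipeline chains pretreatment -> PCA latent-variable
selection -> SMOTE augmentation -> stratified 8:2 split -> score
standardization -> BPNN training (plain gradient descent or PSO-seeded
gradient descent) -> evaluation. The quantitative pipeline splits first,
augments the training portion only (so no test-sample feature influences
any fitted statistic), and trains a single-output regression network; a
PLS1 model on the same PCA scores is the linear baseline.

Two split protocols exist in the field for augmented data and both are
supported via ``split_order``: "augment-first" (augment the whole table,
then split — the qualitative default) and "split-first" (hold out raw
samples untouched, augment only the training part — the quantitative
default, which is leak-free).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpnn as bp
from . import pca as pca_mod
from . import pso as pso_mod
from .metrics import EvaluationReport, classification_report, pearson_r, rmse, roc_auc
from .plsr import plsr_fit, plsr_predict
from .pretreatment import METHODS, PretreatmentConfig, apply
from .smote import SmoteConfig, smote
from .spectra import SpectrumSet, read_spectra, stratified_indices, stratified_split
from .synthetic import SyntheticConfig, generate

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_qualitative",
    "run_quantitative",
    "compare_pretreatments",
    "save_report",
]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""


@dataclass
class BPNNConfig:
    hidden: int | None = None      # None -> round(sqrt(m+n)) + a
    a: int = 8                     # adjustable constant of the size formula
    eta0: float = 0.001
    epochs: int = 1800
    schedule: str = "gaussian"
    p: float = 2.0
    gamma: float | None = None
    seed: int = 0


@dataclass
class PSOConfig:
    enabled: bool = True
    n_particles: int = 30
    omega: float = 0.2
    c1: float = 1.4
    c2: float = 2.0
    iterations: int = 100
    bounds: float = 2.0
    vclamp: float = 0.5
    seed: int = 0


@dataclass
class PipelineConfig:
    """One data source (synthetic config or CSV paths), the stage blocks,
    the split protocol and the run mode."""

    mode: str = "qualitative"                 # qualitative | quantitative | compare
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    spectra_path: str | None = None
    metadata_path: str | None = None
    pretreatment: PretreatmentConfig = field(default_factory=PretreatmentConfig)
    pca_threshold: float = 0.99
    pca_k_override: int | None = None
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    plsr_components: int = 5
    test_fraction: float = 0.2
    split_seed: int = 0
    split_order: str | None = None            # None -> mode default
    quantitative_model: str = "pso-bpnn"      # plsr | bpnn | pso-bpnn
    compute_rmsecv: bool = False
    rmsecv_folds: int | None = None
    outdir: str | None = None

    @classmethod
    def for_quantitative(cls, **overrides) -> "PipelineConfig":
        """Defaults tuned for the °Brix regression study: hidden size from
        a=4 (h=10 at 35 inputs) and the regression PSO parameters
        (omega=0.7, c1=1.9, c2=1.7, 400 iterations)."""
        base = dict(
            mode="quantitative",
            bpnn=BPNNConfig(eta0=0.001, epochs=2000, a=4),
            pso=PSOConfig(omega=0.7, c1=1.9, c2=1.7, iterations=400),
        )
        base.update(overrides)
        return cls(**base)

    def resolved_split_order(self) -> str:
        if self.split_order is not None:
            if self.split_order not in ("augment-first", "split-first"):
                raise ValueError("split_order must be 'augment-first' or 'split-first'")
            return self.split_order
        return "augment-first" if self.mode == "qualitative" else "split-first"

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {k: conv(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            for key in ("band_centers", "band_widths", "band_strengths"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "wavelengths" in syn:
                syn["wavelengths"] = np.asarray(syn["wavelengths"], dtype=float)
            d["synthetic"] = SyntheticConfig(**syn)
        if "pretreatment" in d and isinstance(d["pretreatment"], dict):
            d["pretreatment"] = PretreatmentConfig(**d["pretreatment"])
        if "smote" in d and isinstance(d["smote"], dict):
            sm = dict(d["smote"])
            if "multipliers" in sm:
                sm["multipliers"] = {int(k): int(v) for k, v in sm["multipliers"].items()}
            d["smote"] = SmoteConfig(**sm)
        if "bpnn" in d and isinstance(d["bpnn"], dict):
            d["bpnn"] = BPNNConfig(**d["bpnn"])
        if "pso" in d and isinstance(d["pso"], dict):
            d["pso"] = PSOConfig(**d["pso"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def load_data(config: PipelineConfig) -> SpectrumSet:
    with _stage("data"):
        if config.spectra_path is not None:
            return read_spectra(config.spectra_path, config.metadata_path)
        if config.synthetic is None:
            raise ValueError("config must name a spectra file or a synthetic block")
        return generate(config.synthetic)


def _schedule(cfg: BPNNConfig, epochs: int | None = None) -> bp.LRSchedule:
    T = epochs if epochs is not None else cfg.epochs
    return bp.LRSchedule(kind=cfg.schedule, eta0=cfg.eta0, T=T, p=cfg.p, gamma=cfg.gamma)


def _swarm_config(cfg: PSOConfig) -> pso_mod.SwarmConfig:
    return pso_mod.SwarmConfig(
        n_particles=cfg.n_particles, omega=cfg.omega, c1=cfg.c1, c2=cfg.c2,
        max_iterations=cfg.iterations, bounds=cfg.bounds,
        velocity_clamp=cfg.vclamp, seed=cfg.seed,
    )


def _train_classifier(
    config: PipelineConfig, x_train: np.ndarray, grades_train: np.ndarray
) -> tuple[bp.BPNNModel, dict]:
    m = x_train.shape[1]
    n = 3
    h = config.bpnn.hidden or bp.hidden_size(m, n, config.bpnn.a)
    targets = bp.one_hot(grades_train, n)
    schedule = _schedule(config.bpnn)
    traces: dict = {}
    with _stage("train"):
        if config.pso.enabled:
            model, pso_trace, gd_trace = pso_mod.pso_train_bpnn(
                x_train, targets, (m, h, n), _swarm_config(config.pso),
                schedule, gd_epochs=config.bpnn.epochs, seed=config.bpnn.seed,
                output_activation="sigmoid",
            )
            traces["pso_fitness"] = pso_trace
        else:
            init = bp.init_bpnn(m, h, n, "sigmoid", seed=config.bpnn.seed)
            model, gd_trace = bp.train_gd(
                init, x_train, targets, schedule, epochs=config.bpnn.epochs
            )
        traces["train_mse"] = gd_trace.mse if gd_trace is not None else np.empty(0)
        traces["learning_rate"] = (
            gd_trace.learning_rate if gd_trace is not None else np.empty(0)
        )
    traces["params"] = {"m": m, "h": h, "n": n, "eta0": config.bpnn.eta0,
                        "schedule": config.bpnn.schedule,
                        "omega": config.pso.omega, "c1": config.pso.c1,
                        "c2": config.pso.c2}
    return model, traces


def run_qualitative(config: PipelineConfig) -> EvaluationReport:
    """3-grade SSC classification study; returns the evaluation report."""
    data = load_data(config)
    if data.grade is None or np.any(data.grade == 0):
        raise PipelineError("stage 'data': qualitative mode requires graded samples")
    with _stage("pretreatment"):
        pretreated = apply(data, config.pretreatment)

    order = config.resolved_split_order()
    if order == "augment-first":
        with _stage("pca"):
            model_pca = pca_mod.fit_pca(pretreated)
            k = config.pca_k_override or pca_mod.select_k(
                model_pca.cumulative, config.pca_threshold
            )
            scores = pca_mod.transform(pretreated, model_pca, k)
        with _stage("smote"):
            aug_x, aug_g = smote(scores, data.grade, config.smote)
        with _stage("split"):
            tr, te = stratified_indices(aug_g, config.test_fraction, config.split_seed)
        x_train, g_train = aug_x[tr], aug_g[tr]
        x_test, g_test = aug_x[te], aug_g[te]
    else:  # split-first: raw hold-out untouched by augmentation or PCA fitting
        with _stage("split"):
            train_set, test_set = stratified_split(
                data, config.test_fraction, config.split_seed
            )
        pre_train = apply(train_set, config.pretreatment)
        pre_test = apply(test_set, config.pretreatment)
        with _stage("pca"):
            model_pca = pca_mod.fit_pca(pre_train)
            k = config.pca_k_override or pca_mod.select_k(
                model_pca.cumulative, config.pca_threshold
            )
            x_train = pca_mod.transform(pre_train, model_pca, k)
            x_test = pca_mod.transform(pre_test, model_pca, k)
        with _stage("smote"):
            x_train, g_train = smote(x_train, train_set.grade, config.smote)
        g_test = test_set.grade

    with _stage("standardize"):
        scaler = bp.Standardizer().fit(x_train)
        x_train_s = scaler.transform(x_train)
        x_test_s = scaler.transform(x_test)

    model, traces = _train_classifier(config, x_train_s, g_train)

    with _stage("evaluate"):
        pred = bp.predict_grade(model, x_test_s)
        report = classification_report(g_test, pred)
        scores_out = bp.forward(model, x_test_s)
        present = np.unique(g_test)
        if present.size > 1:
            try:
                report.auc = roc_auc(g_test, scores_out)
            except ValueError:
                report.auc = None
        train_pred = bp.predict_grade(model, x_train_s)
        report.extras["train_accuracy"] = float(np.mean(train_pred == g_train) * 100)
        report.extras["k_selected"] = int(k)
        report.extras["traces"] = traces
        report.extras["n_train"] = int(len(g_train))
        report.extras["n_test"] = int(len(g_test))
    _maybe_save(config, report)
    return report


def run_quantitative(config: PipelineConfig) -> EvaluationReport:
    """°Brix regression study (r_cal/RMSEC, r_pre/RMSEP, optional RMSECV)."""
    data = load_data(config)
    if data.ssc is None or np.any(np.isnan(data.ssc)):
        raise PipelineError("stage 'data': quantitative mode requires SSC on every sample")
    with _stage("split"):
        train_set, test_set = stratified_split(
            data, config.test_fraction, config.split_seed
        )
    with _stage("pretreatment"):
        pre_train = apply(train_set, config.pretreatment)
        pre_test = apply(test_set, config.pretreatment)
    with _stage("pca"):
        model_pca = pca_mod.fit_pca(pre_train)
        k = config.pca_k_override or pca_mod.select_k(
            model_pca.cumulative, config.pca_threshold
        )
        x_train = pca_mod.transform(pre_train, model_pca, k)
        x_test = pca_mod.transform(pre_test, model_pca, k)
    n_raw_train = x_train.shape[0]
    with _stage("smote"):
        x_aug, _, y_aug = smote(
            x_train, train_set.grade, config.smote, targets=train_set.ssc
        )
    with _stage("standardize"):
        scaler = bp.Standardizer().fit(x_aug)
        y_scaler = bp.Standardizer().fit(y_aug[:, None])
        xa = scaler.transform(x_aug)
        ya = y_scaler.transform(y_aug[:, None]).ravel()
        xt = scaler.transform(x_test)

    which = config.quantitative_model
    traces: dict = {}
    with _stage("train"):
        if which == "plsr":
            n_comp = min(config.plsr_components, min(xa.shape[0] - 1, xa.shape[1]))
            pls = plsr_fit(xa, ya, n_comp)
            predict = lambda z: plsr_predict(pls, z)  # noqa: E731
        else:
            m = xa.shape[1]
            h = config.bpnn.hidden or bp.hidden_size(m, 1, min(config.bpnn.a, 10))
            schedule = _schedule(config.bpnn)
            if which == "pso-bpnn":
                net, pso_trace, gd_trace = pso_mod.pso_train_bpnn(
                    xa, ya, (m, h, 1), _swarm_config(config.pso), schedule,
                    gd_epochs=config.bpnn.epochs, seed=config.bpnn.seed,
                    output_activation="linear",
                )
                traces["pso_fitness"] = pso_trace
            elif which == "bpnn":
                init = bp.init_bpnn(m, h, 1, "linear", seed=config.bpnn.seed)
                net, gd_trace = bp.train_gd(
                    init, xa, ya, schedule, epochs=config.bpnn.epochs
                )
            else:
                raise ValueError(
                    f"unknown quantitative model {which!r}; use plsr|bpnn|pso-bpnn"
                )
            traces["train_mse"] = gd_trace.mse
            predict = lambda z: bp.forward(net, z).ravel()  # noqa: E731

    with _stage("evaluate"):
        def predict_brix(z: np.ndarray) -> np.ndarray:
            return y_scaler.inverse(predict(z)[:, None]).ravel()

        # calibration statistics on the original (un-augmented) training rows
        cal_pred = predict_brix(xa[:n_raw_train])
        test_pred = predict_brix(xt)
        report = EvaluationReport(
            r_cal=pearson_r(train_set.ssc, cal_pred),
            rmsec=rmse(train_set.ssc, cal_pred),
            r_pre=pearson_r(test_set.ssc, test_pred),
            rmsep=rmse(test_set.ssc, test_pred),
        )
        report.extras["k_selected"] = int(k)
        report.extras["model"] = which
        report.extras["traces"] = traces
        report.extras["predicted_test_ssc"] = test_pred.tolist()

    if config.compute_rmsecv:
        from .metrics import loo_rmsecv

        with _stage("rmsecv"):
            # fold models train on standardized targets internally but the
            # factory consumes and predicts raw °Brix
            def factory(fx: np.ndarray, fy: np.ndarray):
                ysc = bp.Standardizer().fit(fy[:, None])
                fys = ysc.transform(fy[:, None]).ravel()
                if which == "plsr":
                    ncomp = min(
                        config.plsr_components, min(fx.shape[0] - 1, fx.shape[1])
                    )
                    mdl = plsr_fit(fx, fys, ncomp)
                    return lambda z: ysc.inverse(plsr_predict(mdl, z)[:, None]).ravel()
                mm = fx.shape[1]
                hh = config.bpnn.hidden or bp.hidden_size(mm, 1, min(config.bpnn.a, 10))
                net0 = bp.init_bpnn(mm, hh, 1, "linear", seed=config.bpnn.seed)
                netf, _ = bp.train_gd(
                    net0, fx, fys, _schedule(config.bpnn), epochs=config.bpnn.epochs
                )
                return lambda z: ysc.inverse(
                    bp.forward(netf, z).ravel()[:, None]
                ).ravel()

            report.rmsecv = loo_rmsecv(xa, y_aug, factory, n_folds=config.rmsecv_folds)
    _maybe_save(config, report)
    return report


def compare_pretreatments(config: PipelineConfig) -> pd.DataFrame:
    """Run the qualitative pipeline once per pretreatment (six methods plus
    raw spectra) with shared seeds; returns a comparison table."""
    rows = []
    for method in [m for m in METHODS if m != "none"] + ["none"]:
        cfg = dataclasses.replace(
            config,
            mode="qualitative",
            pretreatment=dataclasses.replace(config.pretreatment, method=method),
            outdir=None,
        )
        rep = run_qualitative(cfg)
        rows.append(
            {
                "method": "raw" if method == "none" else method,
                "lvs": rep.extras["k_selected"],
                "accuracy_pct": rep.accuracy,
                "recall_pct": rep.macro_recall,
                "f1": rep.macro_f1,
            }
        )
    table = pd.DataFrame(rows)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "pretreatment_comparison.csv", index=False)
        config.to_yaml(out / "resolved_config.yaml")
    return table


def save_report(report: EvaluationReport, outdir: str | Path) -> None:
    """Serialize a report: JSON summary plus confusion/trace CSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    traces = d.pop("traces", None)
    d.pop("predicted_test_ssc", None)
    with open(out / "report.json", "w") as fh:
        json.dump(d, fh, indent=2)
    if report.confusion is not None:
        pd.DataFrame(
            report.confusion,
            index=[f"true_{g}" for g in (1, 2, 3)],
            columns=[f"pred_{g}" for g in (1, 2, 3)],
        ).to_csv(out / "confusion.csv")
    if traces:
        for name, arr in traces.items():
            if isinstance(arr, np.ndarray) and arr.size:
                pd.DataFrame({name: arr}).to_csv(out / f"trace_{name}.csv", index=False)


def _maybe_save(config: PipelineConfig, report: EvaluationReport) -> None:
    if config.outdir:
        save_report(report, config.outdir)
        config.to_yaml(Path(config.outdir) / "resolved_config.yaml")
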