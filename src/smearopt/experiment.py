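"""End-to-end experiments: data preparation, the BO-over-CNN loop, reports.

An :class:`ExperimentConfig` captures everything a run needs — the data
source (an on-disk folder of class-labeled images, or the synthetic
generator), the four-variable search space, the training constants and
the optimization budget.  ``run_optimization`` prepares the data
(merge -> augment -> resize -> split), runs Bayesian optimization where
every trial trains a CNN and scores its validation error, and writes a
reproducible set of artifacts: a config + seed snapshot, the per-trial
trace CSV, the best model, its training history, and test-set metrics
computed only for the best trial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .architecture import ArchitectureConfig, LayerPlan, LayerSpec, build_architecture
from .bayesopt import BOResult, run_bayesian_optimization, write_trace_csv
from .data import (
    DISEASED,
    HEALTHY,
    DatasetBundle,
    augment,
    bundle_to_arrays,
    confusion_counts,
    load_image_folder,
    resize_images,
    sensitivity_specificity_accuracy,
    split_dataset,
)
from .network import Network
from .search import SearchSpace, paper_search_space
from .synthetic import SmearParams, generate_dataset
from .training import (
    TrainingConfig,
    TrainingHistory,
    evaluate_objective,
    load_model,
    save_model,
    train_network,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "prepare_data",
           "run_optimization", "evaluate_model"]


@dataclass
class ExperimentConfig:
    """Full experiment description; defaults reproduce the reference setup.

    The default configuration is the full-scale one: 64x64 inputs, six-fold
    augmentation, an 80/10/10 split, mini-batches of 128, 150 epochs per
    trial with the 0.1-per-40-epochs learning-rate drop, batch-norm decay
    0.1, dropout 0.5, a 30-evaluation budget and a 1e-4 stop threshold.
    """

    # data source: a folder of class subdirectories, or synthetic counts
    data_dir: str | None = None
    extra_data_dir: str | None = None  # second source set, merged in
    synthetic_healthy: int = 189
    synthetic_diseased: int = 179
    synthetic_render_size: int = 256
    synthetic_seed: int = 7

    # preprocessing
    image_size: int = 64
    apply_augmentation: bool = True
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_by_source: bool = False

    # architecture / training constants
    base_filters: int = 32
    dropout_p: float = 0.5
    batch_size: int = 128
    max_epochs: int = 150
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 40
    bn_decay: float = 0.1

    # Bayesian optimization
    search_space: list[dict] = field(
        default_factory=lambda: paper_search_space().to_config()
    )
    max_evaluations: int = 30
    stop_threshold: float = 1e-4
    n_initial: int = 4

    seed: int = 0
    output_dir: str = "runs/experiment"

    @classmethod
    def fast_profile(cls, **overrides) -> "ExperimentConfig":
        """Desk-scale profile: 32x32 images, 280 synthetic frames split
        200/40/40, 10 epochs per trial, a 5-evaluation budget."""
        base = cls(
            synthetic_healthy=140,
            synthetic_diseased=140,
            synthetic_render_size=96,
            image_size=32,
            apply_augmentation=False,
            fractions=(5 / 7, 1 / 7, 1 / 7),
            max_epochs=10,
            max_evaluations=5,
            n_initial=4,
        )
        return replace(base, **overrides)

    def space(self) -> SearchSpace:
        return SearchSpace.from_config(self.search_space)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)


@dataclass
class ExperimentResult:
    bo_result: BOResult
    best_model: Network
    best_plan: LayerPlan
    best_history: TrainingHistory
    test_metrics: dict
    output_dir: Path


def prepare_data(config: ExperimentConfig) -> DatasetBundle:
    """Load or synthesize images, then augment, resize and split."""
    if config.data_dir is not None:
        bundle = load_image_folder(config.data_dir)
        if config.extra_data_dir is not None:
            from .data import merge_datasets

            bundle = merge_datasets(bundle, load_image_folder(config.extra_data_dir))
    else:
        params = SmearParams().for_size(config.synthetic_render_size)
        bundle = generate_dataset(
            config.synthetic_healthy,
            config.synthetic_diseased,
            params=params,
            seed=config.synthetic_seed,
        )
    if config.apply_augmentation:
        bundle = augment(bundle)
    bundle = resize_images(bundle, config.image_size, config.image_size)
    return split_dataset(
        bundle,
        fractions=config.fractions,
        seed=config.seed,
        by_source=config.split_by_source,
    )


def _standardize(Xtr, *others):
    """Per-channel standardization using training-set statistics."""
    mean = Xtr.mean(axis=(0, 2, 3), keepdims=True)
    sd = Xtr.std(axis=(0, 2, 3), keepdims=True)
    sd = np.where(sd < 1e-6, 1.0, sd)
    out = [(Xtr - mean) / sd] + [(X - mean) / sd for X in others]
    return out, mean.ravel(), sd.ravel()


def run_optimization(config: ExperimentConfig) -> ExperimentResult:
    """Run the full search and write all artifacts under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    bundle = prepare_data(config)
    Xtr, ytr = bundle_to_arrays(bundle, "train")
    Xval, yval = bundle_to_arrays(bundle, "val")
    Xtest, ytest = bundle_to_arrays(bundle, "test")
    (Xtr, Xval, Xtest), ch_mean, ch_sd = _standardize(Xtr, Xval, Xtest)

    space = config.space()
    best = {"objective": np.inf, "model": None, "plan": None, "history": None}
    trial_counter = {"i": 0}

    def objective(point: dict) -> float:
        trial_counter["i"] += 1
        trial_seed = (config.seed * 100003 + trial_counter["i"]) % (2**31)
        arch = ArchitectureConfig(
            cbd=int(point["cbd"]),
            base_filters=config.base_filters,
            input_height=config.image_size,
            input_width=config.image_size,
            dropout_p=config.dropout_p,
        )
        plan = build_architecture(arch)
        tc = TrainingConfig(
            initial_learning_rate=point["initial_learning_rate"],
            momentum=point["momentum"],
            regularization=point["regularization"],
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            lr_drop_factor=config.lr_drop_factor,
            lr_drop_period=config.lr_drop_period,
            bn_decay=config.bn_decay,
            seed=trial_seed,
        )
        model, history = train_network(plan, (Xtr, ytr), (Xval, yval), tc)
        err = evaluate_objective(model, (Xval, yval))
        if err < best["objective"]:
            best.update(objective=err, model=model, plan=plan, history=history)
        return err

    result = run_bayesian_optimization(
        objective,
        space,
        max_evaluations=config.max_evaluations,
        stop_threshold=config.stop_threshold,
        n_initial=config.n_initial,
        rng=np.random.default_rng(config.seed),
    )
    write_trace_csv(result, out / "trace.csv")

    if best["model"] is None:
        raise RuntimeError("every trial failed; no model to evaluate")

    # held-out test evaluation, best trial only
    model: Network = best["model"]
    preds = model.predict(Xtest)
    labels = np.where(np.asarray(ytest) == 1, DISEASED, HEALTHY)
    pred_labels = np.where(preds == 1, DISEASED, HEALTHY)
    counts = confusion_counts(pred_labels, labels)
    sn, sp, ac = sensitivity_specificity_accuracy(counts)
    metrics = {
        "sensitivity": sn,
        "specificity": sp,
        "accuracy": ac,
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "best_validation_error": result.best_objective,
        "best_point": result.best_point,
        "stopped_by": result.stopped_by,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)

    save_model(model, out / "best_model.npz")
    with open(out / "best_plan.json", "w") as fh:
        fh.write(best["plan"].to_json())
    best["history"].to_csv(out / "best_history.csv")
    with open(out / "normalization.json", "w") as fh:
        json.dump({"mean": ch_mean.tolist(), "sd": ch_sd.tolist()}, fh)

    return ExperimentResult(
        bo_result=result,
        best_model=model,
        best_plan=best["plan"],
        best_history=best["history"],
        test_metrics=metrics,
        output_dir=out,
    )


def _plan_from_listing(listing: list[dict], input_shape, num_classes) -> LayerPlan:
    layers = tuple(
        LayerSpec(d["kind"], {k: v for k, v in d.items() if k != "kind"})
        for d in listing
    )
    return LayerPlan(layers=layers, input_shape=tuple(input_shape),
                     num_classes=num_classes)


def evaluate_model(run_dir, data) -> dict:
    """Score a saved run's best model on new data.

    ``data`` is either a prepared ``(X, y)`` pair (already standardized)
    or a :class:`DatasetBundle`; bundles are standardized with the run's
    stored channel statistics.  Returns per-image predicted classes with
    softmax probabilities plus the sensitivity/specificity/accuracy
    summary.
    """
    run_dir = Path(run_dir)
    for needed in ("best_plan.json", "best_model.npz", "normalization.json"):
        if not (run_dir / needed).exists():
            raise FileNotFoundError(f"missing artifact {needed} in {run_dir}")
    with open(run_dir / "best_plan.json") as fh:
        listing = json.load(fh)
    with open(run_dir / "normalization.json") as fh:
        norm = json.load(fh)

    if isinstance(data, DatasetBundle):
        X, y = bundle_to_arrays(data)
        mean = np.asarray(norm["mean"], dtype=np.float32)[None, :, None, None]
        sd = np.asarray(norm["sd"], dtype=np.float32)[None, :, None, None]
        X = (X - mean) / sd
    else:
        X, y = data

    shape = X.shape[1:]
    plan = _plan_from_listing(listing, shape, num_classes=2)
    model = load_model(plan, run_dir / "best_model.npz")

    probs = model.predict_proba(X)
    preds = probs.argmax(axis=1)
    labels = np.where(np.asarray(y) == 1, DISEASED, HEALTHY)
    pred_labels = np.where(preds == 1, DISEASED, HEALTHY)
    counts = confusion_counts(pred_labels, labels)
    sn, sp, ac = sensitivity_specificity_accuracy(counts)
    return {
        "sensitivity": sn,
        "specificity": sp,
        "accuracy": ac,
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "per_image": [
            {"predicted": str(pl), "probability": float(p.max())}
            for pl, p in zip(pred_labels, probs)
        ],
    }
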