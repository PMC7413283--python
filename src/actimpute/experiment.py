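"""End-to-end experiment protocols.

``run_experiment`` executes the full pipeline on one or more datasets:
complete-record filtering, 9 AM - 9 PM window extraction, seeded corruption
(fixed per record), model fitting per method, imputation, and evaluation.
The autoencoder is trained once on the primary dataset's training split and
applied to every dataset without retraining; the classical baselines are
rebuilt per evaluation dataset without a train/test split, mirroring how
reference-free imputers are used in practice.

``finetune_protocol`` continues training a pre-trained autoencoder on a new
dataset split 9:1:1 into train/validation/test, early-stopping on the
validation split, and reports test metrics for both the baseline and the
fine-tuned model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import baselines, zidcae
from .geometry import build_architecture
from .metrics import MetricsReport, MvpaConfig, compute_report
from .records import (
    WINDOW_MINUTES,
    RecordSet,
    corrupt_set,
    extract_window,
    is_complete,
)

logger = logging.getLogger("actimpute")

METHODS = ("mean", "zip", "bayes", "zidcae")


@dataclass
class ExperimentConfig:
    methods: tuple[str, ...] = METHODS
    corruption_length: int = 30
    train_fraction: float = 0.9       # remainder is the test split
    validation_fraction: float = 0.1  # taken out of the training split
    split_by_subject: bool = False
    rng_seed: int = 0
    m: int = 30
    k: int = 60
    train_cfg: zidcae.TrainConfig | None = None
    mice_cfg: baselines.MiceConfig | None = None
    mvpa_cfg: MvpaConfig | None = None

    def __post_init__(self) -> None:
        for method in self.methods:
            if method not in METHODS:
                raise ValueError(f"unknown method {method!r}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.corruption_length < 1 or self.corruption_length > WINDOW_MINUTES:
            raise ValueError("invalid corruption length")


def preprocess(record_set: RecordSet, min_run: int = 30) -> RecordSet:
    """Keep complete full-day records, then extract the 9 AM - 9 PM window."""
    kept = [r for r in record_set.records if is_complete(r, min_run)]
    logger.info("preprocess: %d/%d records complete", len(kept), len(record_set))
    return RecordSet([extract_window(r) for r in kept])


def split_records(
    record_set: RecordSet,
    train_fraction: float,
    validation_fraction: float,
    rng_seed: int,
    by_subject: bool = False,
) -> RecordSet:
    """Attach seeded train/validation/test labels (by record or by subject)."""
    rng = np.random.default_rng(rng_seed)
    n = len(record_set)
    if by_subject:
        subjects = sorted({r.subject_id for r in record_set.records})
        perm = rng.permutation(len(subjects))
        n_train = int(round(train_fraction * len(subjects)))
        train_subjects = {subjects[i] for i in perm[:n_train]}
        n_val = int(round(validation_fraction * n_train))
        val_subjects = {subjects[i] for i in perm[:n_val]}
        labels = [
            "test" if r.subject_id not in train_subjects
            else ("validation" if r.subject_id in val_subjects else "train")
            for r in record_set.records
        ]
    else:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        n_val = int(round(validation_fraction * n_train))
        labels = ["test"] * n
        for pos, idx in enumerate(perm[:n_train]):
            labels[idx] = "validation" if pos < n_val else "train"
    counts = {lab: labels.count(lab) for lab in ("train", "validation", "test")}
    logger.info("split: %s", counts)
    return RecordSet(record_set.records, record_set.masks, labels)


def _impute_with_method(
    method: str,
    corrupted: RecordSet,
    model: zidcae.ZIDCAE | None,
    cfg: ExperimentConfig,
    mean_reference: RecordSet | None = None,
) -> RecordSet:
    if method == "mean":
        # primary dataset: per-minute means come from the training split;
        # external datasets: rebuilt from the evaluation set itself
        mean_model = baselines.fit_mean_model(mean_reference or corrupted)
        records = [
            baselines.mean_impute(mean_model, rec, mask)
            for rec, mask in zip(corrupted.records, corrupted.masks)
        ]
        return RecordSet(records, corrupted.masks, corrupted.split_labels)
    if method in ("zip", "bayes"):
        mice_cfg = cfg.mice_cfg or baselines.MiceConfig(rng_seed=cfg.rng_seed)
        mice_cfg = dc_replace(mice_cfg, regressor=method)
        return baselines.mice_impute(corrupted, mice_cfg)
    if method == "zidcae":
        if model is None:
            raise ValueError("zidcae method requires a trained model")
        return zidcae.impute_set(model, corrupted)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    datasets: dict[str, RecordSet],
    cfg: ExperimentConfig,
    primary: str | None = None,
    preprocessed: bool = False,
) -> tuple[dict[str, dict[str, MetricsReport]], zidcae.ZIDCAE | None]:
    """Run the full protocol; returns (reports[dataset][method], model).

    The first dataset (or ``primary``) supplies the autoencoder's training
    and validation splits and is evaluated on its held-out test split; the
    other datasets are external validation sets imputed whole, without
    retraining the autoencoder.
    """
    if not datasets:
        raise ValueError("no datasets given")
    primary = primary or next(iter(datasets))
    if primary not in datasets:
        raise ValueError(f"primary dataset {primary!r} not found")

    prepared: dict[str, RecordSet] = {}
    for name, record_set in datasets.items():
        try:
            prepared[name] = record_set if preprocessed else preprocess(record_set)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"preprocess failed for dataset {name!r}: {exc}") from exc
        if len(prepared[name]) == 0:
            raise RuntimeError(f"preprocess left no records in dataset {name!r}")

    model: zidcae.ZIDCAE | None = None
    eval_sets: dict[str, RecordSet] = {}
    mean_refs: dict[str, RecordSet | None] = {}
    if "zidcae" in cfg.methods:
        labelled = split_records(
            prepared[primary],
            cfg.train_fraction,
            cfg.validation_fraction,
            cfg.rng_seed,
            cfg.split_by_subject,
        )
        train_cfg = cfg.train_cfg or zidcae.TrainConfig(rng_seed=cfg.rng_seed)
        train_cfg = dc_replace(train_cfg, corruption_length=cfg.corruption_length)
        spec = build_architecture(cfg.m, cfg.k)
        try:
            model = zidcae.train(labelled.split("train"), labelled.split("validation"), spec, train_cfg)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"autoencoder training failed: {exc}") from exc
        eval_sets[primary] = labelled.split("test")
    else:
        labelled = split_records(
            prepared[primary], cfg.train_fraction, cfg.validation_fraction, cfg.rng_seed
        )
        eval_sets[primary] = labelled.split("test")
    mean_refs[primary] = labelled.split("train")
    for name, record_set in prepared.items():
        if name != primary:
            eval_sets[name] = record_set
            mean_refs[name] = None

    reports: dict[str, dict[str, MetricsReport]] = {}
    for name, clean in eval_sets.items():
        corrupted = corrupt_set(clean, cfg.corruption_length, cfg.rng_seed)
        reports[name] = {}
        for method in cfg.methods:
            try:
                imputed = _impute_with_method(method, corrupted, model, cfg, mean_refs.get(name))
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"imputation failed (dataset {name!r}, method {method!r}): {exc}") from exc
            mvpa_cfg = cfg.mvpa_cfg or MvpaConfig.for_axis(clean.records[0].axis_kind)
            reports[name][method] = compute_report(clean, imputed, corrupted.masks, mvpa_cfg)
            logger.info(
                "dataset %s method %s: partial RMSE %.1f, partial MAE %.1f",
                name, method,
                reports[name][method].partial_rmse,
                reports[name][method].partial_mae,
            )
    return reports, model


def finetune_protocol(
    model: zidcae.ZIDCAE,
    dataset: RecordSet,
    cfg: ExperimentConfig,
    finetune_epochs: int = 30,
) -> tuple[MetricsReport, MetricsReport]:
    """9:1:1 fine-tuning on a new dataset; returns (baseline, fine-tuned) test reports."""
    if not model.trained:
        raise ValueError("finetune_protocol requires a pre-trained model")
    if len(dataset) < 11:
        raise ValueError("dataset too small for a 9:1:1 split")
    # 9:1:1 = train 9/11 of the data, validation and test 1/11 each
    labelled = split_records(dataset, 10.0 / 11.0, 0.1, cfg.rng_seed)
    test = labelled.split("test")
    corrupted_test = corrupt_set(test, cfg.corruption_length, cfg.rng_seed)
    mvpa_cfg = cfg.mvpa_cfg or MvpaConfig.for_axis(test.records[0].axis_kind)

    baseline_report = compute_report(
        test, zidcae.impute_set(model, corrupted_test), corrupted_test.masks, mvpa_cfg
    )

    tuned = zidcae.ZIDCAE(model.spec, model.rng_seed)
    tuned.restore(model.snapshot())
    tuned.scale_max = model.scale_max
    tuned.trained = True
    if finetune_epochs > 0:
        tuned = _continue_training(tuned, labelled, cfg, finetune_epochs)
    tuned_report = compute_report(
        test, zidcae.impute_set(tuned, corrupted_test), corrupted_test.masks, mvpa_cfg
    )
    return baseline_report, tuned_report


def _continue_training(
    model: zidcae.ZIDCAE, labelled: RecordSet, cfg: ExperimentConfig, epochs: int
) -> zidcae.ZIDCAE:
    """Continue Adam training from the current weights, early-stopping on the
    new validation split; keeps the pre-training scale so counts stay comparable."""
    train_cfg = cfg.train_cfg or zidcae.TrainConfig(rng_seed=cfg.rng_seed)
    train_cfg = dc_replace(
        train_cfg,
        max_epochs=epochs,
        corruption_length=cfg.corruption_length,
        train_scale_max=model.scale_max,
    )
    x_train = labelled.split("train").values_matrix()
    x_val = labelled.split("validation").values_matrix()
    scale = model.scale_max
    root = np.random.default_rng(train_cfg.rng_seed)
    optimizer = zidcae.nn.Adam(model.net.parameters(), lr=train_cfg.learning_rate)
    val_rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
    val_corrupted, val_flags = zidcae._fresh_corruption(x_val, train_cfg.corruption_length, val_rng)
    val_prepared = zidcae.prepare_input(val_corrupted, val_flags, scale).astype(zidcae.nn.DTYPE)
    target = np.clip(x_train / scale, 0.0, 1.0).astype(zidcae.nn.DTYPE)

    best_val = zidcae._validation_partial_rmse(model, x_val, val_prepared, val_flags, scale)
    best_state, since_best = model.snapshot(), 0
    m = x_train.shape[0]
    for _ in range(epochs):
        epoch_rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        corrupted, flags = zidcae._fresh_corruption(x_train, train_cfg.corruption_length, epoch_rng)
        prepared = zidcae.prepare_input(corrupted, flags, scale).astype(zidcae.nn.DTYPE)
        order = epoch_rng.permutation(m)
        for lo in range(0, m, train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            recon, _ = model.forward(prepared[idx], training=True)
            diff = recon - target[idx]
            loss = float(np.sqrt(np.mean(diff.astype(float) ** 2)))
            if not np.isfinite(loss):
                raise RuntimeError("fine-tuning diverged: non-finite loss")
            if loss > 0:
                model.backward(diff / (diff.size * loss))
                optimizer.step()
        val_prmse = zidcae._validation_partial_rmse(model, x_val, val_prepared, val_flags, scale)
        if val_prmse < best_val:
            best_val, best_state, since_best = val_prmse, model.snapshot(), 0
        else:
            since_best += 1
            if since_best >= train_cfg.early_stop_patience:
                break
    model.restore(best_state)
    return model
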