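"""End-to-end orchestration: featurize → train → predict → evaluate.

These helpers wire the package's stages together for the common experiment
shape: generate (or load) condition-annotated mapped reactions, build
compressed CGR-fragment descriptors with the compressor fitted on the
training split only, train a condition CVAE, rank sampled conditions per
test reaction, and score everything against the recorded conditions
alongside the Null/kNN/Bayes-oracle references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import knn_rank, null_rank
from .conditions import ConditionVector
from .evaluation import DEFAULT_K_GRID, EvaluationReport, evaluate_models
from .inference import predict_conditions
from .model import (ConditionCVAE, DecoderConfig, EncoderConfig, LossConfig,
                    TrainConfig)
from .reactions import (DescriptorCompressor, apply_compressor, build_cgr,
                        enumerate_fragments, fit_compressor,
                        parse_mapped_reaction)
from .synthetic import GeneratorSpec, ReactionRecord, oracle_rank

__all__ = ["featurize", "ExperimentResult", "run_experiment"]


def featurize(smiles_list, compressor: DescriptorCompressor | None = None,
              min_len: int = 2, max_len: int = 4, charges: bool = True,
              target_variance: float = 0.95, max_dim: int = 500,
              ) -> tuple[np.ndarray, DescriptorCompressor]:
    """Map reaction SMILES to compressed CGR-fragment descriptor rows.

    When `compressor` is None one is fitted on the given corpus (training
    usage); otherwise the frozen compressor transforms the input (test
    usage — no leakage). Repeated SMILES are parsed once.
    """
    unique = list(dict.fromkeys(smiles_list))
    tables = {s: enumerate_fragments(build_cgr(parse_mapped_reaction(s)),
                                     min_len, max_len, charges)
              for s in unique}
    if compressor is None:
        compressor = fit_compressor([tables[s] for s in unique],
                                    target_variance, max_dim)
    X = np.stack([apply_compressor(compressor, tables[s]) for s in smiles_list])
    return X, compressor


@dataclass
class ExperimentResult:
    model: ConditionCVAE
    compressor: DescriptorCompressor
    reports: dict[str, EvaluationReport]
    truths: dict[str, set]
    predictions: dict[str, dict]
    n_train: int
    n_test: int


def _records_matrix(records: list[ReactionRecord], scheme) -> tuple[np.ndarray, np.ndarray]:
    Y = np.stack([r.condition.as_array() for r in records])
    mask = np.array([r.tp_mask for r in records], dtype=bool)
    return Y, mask


def run_experiment(train: list[ReactionRecord], test: list[ReactionRecord],
                   spec: GeneratorSpec, family: str = "gaussian",
                   epochs: int = 50, n_draws: int = 1000, seed: int = 0,
                   k_grid=DEFAULT_K_GRID, latent_dim: int = 32,
                   f_pretrain_epochs: int = 50, max_dim: int = 500,
                   include_oracle: bool = True, log_stream=None,
                   ) -> ExperimentResult:
    """Train one CVAE on `train` and score it (plus references) on `test`.

    `test` must hold one record per transformation with known T/P (the
    single-condition split contract). Deterministic given `seed`.
    """
    scheme = spec.scheme
    X_train, compressor = featurize([r.smiles for r in train], max_dim=max_dim)
    Y_train, mask_train = _records_matrix(train, scheme)

    model = ConditionCVAE(
        scheme, compressor.dim,
        encoder=EncoderConfig(latent_dim=latent_dim, family=family),
        decoder=DecoderConfig(f_pretrain_epochs=f_pretrain_epochs),
        train=TrainConfig(epochs=epochs, seed=seed))
    model.fit(X_train, Y_train, mask_train, log_stream=log_stream)

    by_key: dict[str, ReactionRecord] = {r.transformation_key: r for r in test}
    test_keys = sorted(by_key)
    X_test, _ = featurize([by_key[k].smiles for k in test_keys], compressor)
    truths: dict[str, set] = {}
    for r in test:
        truths.setdefault(r.transformation_key, set()).add(r.condition)

    train_conditions = [r.condition for r in train if r.condition is not None]
    complete_train = [r for r in train
                      if r.condition is not None and r.is_complete]
    X_knn = X_train[[i for i, r in enumerate(train)
                     if r.condition is not None and r.is_complete]]

    cvae_preds, null_preds, knn_preds, oracle_preds = {}, {}, {}, {}
    null_list = null_rank(train_conditions)
    for i, key in enumerate(test_keys):
        cvae_preds[key] = predict_conditions(model, X_test[i], n_draws,
                                             seed=seed + i, query_id=key)
        null_preds[key] = null_list
        knn_preds[key] = knn_rank(X_test[i], X_knn,
                                  [r.condition for r in complete_train],
                                  query_id=key)
        if include_oracle:
            oracle_preds[key] = oracle_rank(by_key[key].template, spec, key)

    reports = {
        "cvae": evaluate_models(cvae_preds, truths, k_grid),
        "null": evaluate_models(null_preds, truths, k_grid),
        "knn": evaluate_models(knn_preds, truths, k_grid),
    }
    predictions = {"cvae": cvae_preds, "null": null_preds, "knn": knn_preds}
    if include_oracle:
        reports["oracle"] = evaluate_models(oracle_preds, truths, k_grid)
        predictions["oracle"] = oracle_preds
    return ExperimentResult(model=model, compressor=compressor,
                            reports=reports, truths=truths,
                            predictions=predictions,
                            n_train=len(train), n_test=len(truths))
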