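"""End-to-end plumbing shared by the CLI, the tests and the acceptance script.

These helpers wire the modules together: records + tracks -> encoded arrays,
split -> train -> evaluate, without adding behavior of their own.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .encoder import encode_dataset, stack_images
from .epitracks import IntervalSet, build_annotation
from .evaluation import evaluate_predictions
from .io_formats import TargetRecord
from .network import ModelConfig, PrimeNet
from .training import SplitSpec, TrainConfig, split_dataset, train

__all__ = ["encode_records", "run_recovery_pipeline", "dataset_digest"]


def encode_records(records, dnase: IntervalSet | None, methyl: IntervalSet | None):
    """Encode a record table into (X, y, kept_records, failures)."""
    encoded, failures = encode_dataset(records, dnase, methyl)
    X, y = stack_images(encoded)
    failed = set(failures)
    kept = [r for r in records if r.record_id not in failed]
    return X, y, kept, failures


@dataclass
class PipelineResult:
    model: PrimeNet
    history: list
    report: "object"
    test_pred: np.ndarray
    test_obs: np.ndarray
    test_records: list
    test_X: np.ndarray
    split_sizes: tuple


def run_recovery_pipeline(
    records,
    dnase: IntervalSet | None,
    methyl: IntervalSet | None,
    seed: int = 0,
    max_epochs: int = 20,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> PipelineResult:
    """Encode -> 8:1:1 split -> train -> evaluate on the held-out test set."""
    X, y, kept, _ = encode_records(records, dnase, methyl)
    idx_train, idx_val, idx_test = split_dataset(
        list(range(len(kept))), SplitSpec(seed=seed)
    )
    tc = train_config or TrainConfig(max_epochs=max_epochs, seed=seed)
    model = PrimeNet(model_config or ModelConfig(), seed=seed)
    model, history = train(
        model, (X[idx_train], y[idx_train]), (X[idx_val], y[idx_val]), tc
    )
    pred = model.predict(X[idx_test])
    obs = y[idx_test]
    report = evaluate_predictions(pred, obs)
    return PipelineResult(
        model=model,
        history=history,
        report=report,
        test_pred=pred,
        test_obs=obs,
        test_records=[kept[i] for i in idx_test],
        test_X=X[idx_test],
        split_sizes=(len(idx_train), len(idx_val), len(idx_test)),
    )


def dataset_digest(records: list[TargetRecord]) -> str:
    """Stable content hash of a record table, for run manifests."""
    h = hashlib.sha256()
    for r in records:
        h.update(json.dumps(
            [r.record_id, r.wild_seq, r.edited_seq,
             list(r.spans.protospacer), list(r.spans.pam),
             list(r.spans.pbs), list(r.spans.rt)],
        ).encode())
    return h.hexdigest()[:16]
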