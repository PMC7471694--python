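"""Factorial training grid: architecture x padding x task x fold.

Three architectures are benchmarked as configurable contracts:

* ``only_denses`` — feed-forward layers only (the baseline),
* ``1_conv``      — one length-preserving 1D convolution (64 filters of
  size 5 by default) before the dense stack,
* ``stack_conv``  — five parallel 1D convolutions whose outputs are
  concatenated on the filter axis before the dense stack.

Task 1 is enzyme/non-enzyme (sigmoid head); task 2 is the enzyme class
1-7 (softmax head, trained and evaluated on enzymes only).  Models are
trained with Adam (lr 1e-4, beta1 0.9, beta2 0.999) and the weights of
the epoch with the highest validation accuracy are kept.

The ``aug`` padding mode trains on the 7-fold expanded training set (all
seven single-mode variants of every training sequence) and scores each
test sequence by averaging the predicted probabilities of its 7 variants.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .codec import Alphabet, default_alphabet
from .data import LabeledSample, SplitPlan, task_label
from .padding import ALL_MODES, SINGLE_MODES, PaddingConfig, augment, pad

logger = logging.getLogger(__name__)

ARCHITECTURES = ("only_denses", "1_conv", "stack_conv")


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural contract for one model family."""

    name: str
    dense_layer_sizes: tuple[int, ...] = (128, 64)
    conv_filters: int = 64
    conv_kernel: int = 5
    n_parallel_convs: int = 5
    dropout_rate: float = 0.3

    def __post_init__(self):
        if self.name not in ARCHITECTURES:
            raise BenchmarkError(f"unknown architecture {self.name!r}")
        if self.name == "stack_conv" and self.n_parallel_convs < 2:
            raise BenchmarkError("stack_conv needs >= 2 parallel convolutions")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; defaults follow the benchmark protocol
    (Adam 1e-4/0.9/0.999, batch 54) at a desk-scale epoch count."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 10
    batch_size: int = 54
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise BenchmarkError("epochs and batch_size must be >= 1")


@dataclass
class RunRecord:
    """Raw test-set predictions for one grid cell."""

    task: int
    architecture: str
    padding: str
    fold: int
    test_ids: list[str]
    probabilities: np.ndarray       # (B,) task 1, (B, 7) task 2
    selected_epoch: int             # 1-based epoch with best val accuracy
    val_accuracy: float


def config_from_file(path) -> tuple[ArchitectureSpec, TrainingConfig]:
    """Read architecture + training settings from a JSON key-value file.

    Keys matching ArchitectureSpec fields (``name`` required) configure the
    architecture; keys matching TrainingConfig fields configure training;
    unknown keys are an error.
    """
    raw = json.loads(Path(path).read_text())
    arch_fields = {f for f in ArchitectureSpec.__dataclass_fields__}
    train_fields = {f for f in TrainingConfig.__dataclass_fields__}
    unknown = set(raw) - arch_fields - train_fields
    if unknown:
        raise BenchmarkError(f"unknown config keys: {sorted(unknown)}")
    arch_kw = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in raw.items() if k in arch_fields}
    train_kw = {k: v for k, v in raw.items() if k in train_fields}
    return ArchitectureSpec(**arch_kw), TrainingConfig(**train_kw)


def build_model(arch: ArchitectureSpec, input_shape: tuple[int, int],
                task: int, seed: int = 0) -> nn.Network:
    """Assemble a trainable network for one-hot input ``(n+1, T)``.

    Convolution stages preserve the temporal length ``T``, so first-conv
    activations have shape ``(conv_filters, T)`` per sample.
    """
    C, T = input_shape
    rng = np.random.default_rng(seed)
    layers: list = []
    width_after = None
    if arch.name == "1_conv":
        layers += [nn.Conv1D(C, arch.conv_filters, arch.conv_kernel, rng), nn.ReLU()]
        width_after = arch.conv_filters * T
    elif arch.name == "stack_conv":
        branches = [nn.Conv1D(C, arch.conv_filters, arch.conv_kernel, rng)
                    for _ in range(arch.n_parallel_convs)]
        layers += [nn.ParallelConv(branches), nn.ReLU()]
        width_after = arch.n_parallel_convs * arch.conv_filters * T
    else:
        width_after = C * T
    layers.append(nn.Flatten())
    n_in = width_after
    for size in arch.dense_layer_sizes:
        layers += [nn.Dense(n_in, size, rng), nn.ReLU(),
                   nn.Dropout(arch.dropout_rate, rng)]
        n_in = size
    if task == 1:
        layers.append(nn.Dense(n_in, 1, rng))
        head = "sigmoid"
    elif task == 2:
        layers.append(nn.Dense(n_in, 7, rng))
        head = "softmax"
    else:
        raise BenchmarkError(f"task must be 1 or 2, got {task}")
    return nn.Network(layers, head)


def encode_batch(padded_symbols: list[str], alphabet: Alphabet) -> np.ndarray:
    """One-hot encode equal-length padded strings to ``(B, n+1, T)`` float32."""
    if not padded_symbols:
        raise BenchmarkError("empty batch")
    T = len(padded_symbols[0])
    idx = np.empty((len(padded_symbols), T), dtype=np.int64)
    for i, s in enumerate(padded_symbols):
        idx[i] = alphabet.indices(s)
    eye = np.eye(alphabet.size, dtype=np.float32)
    return eye[idx].transpose(0, 2, 1)


def _accuracy(model: nn.Network, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)
    pred = (p >= 0.5).astype(int) if model.head == "sigmoid" else p.argmax(axis=1)
    return float(np.mean(pred == y))


def train(model: nn.Network, X_train, y_train, X_val, y_val, X_test,
          config: TrainingConfig, meta: dict | None = None) -> RunRecord:
    """Minibatch-train; restore the best-validation-accuracy epoch's weights.

    Ties keep the earliest epoch.  Raises :class:`nn.TrainingDiverged` on a
    non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  beta1=config.beta1, beta2=config.beta2)
    best_acc, best_epoch, best_weights = -1.0, 0, model.get_weights()
    n = len(X_train)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            loss = model.loss_and_backward(X_train[sel], y_train[sel])
            if not np.isfinite(loss):
                raise nn.TrainingDiverged(epoch)
            opt.step()
        val_acc = _accuracy(model, X_val, y_val)
        if val_acc > best_acc:
            best_acc, best_epoch, best_weights = val_acc, epoch, model.get_weights()
    model.set_weights(best_weights)
    meta = meta or {}
    return RunRecord(
        task=meta.get("task", 1), architecture=meta.get("architecture", ""),
        padding=meta.get("padding", ""), fold=meta.get("fold", 0),
        test_ids=meta.get("test_ids", []),
        probabilities=model.predict_proba(X_test),
        selected_epoch=best_epoch, val_accuracy=best_acc)


def _partition(samples: list[LabeledSample], assignment: dict[str, str],
               task: int) -> dict[str, list[LabeledSample]]:
    parts: dict[str, list[LabeledSample]] = {"train": [], "val": [], "test": []}
    for s in samples:
        if task == 2 and s.task1_label != 1:
            continue
        parts[assignment[s.id]].append(s)
    return parts


def _padded_strings(samples: list[LabeledSample], mode: str, T: int,
                    seed: int) -> list[str]:
    cfg_cache = PaddingConfig(T=T, mode=mode, seed=seed)
    return [pad(s.residues, cfg_cache, source_id=s.origin_id or s.id).symbols
            for s in samples]


def prepare_cell_arrays(samples, assignment, task: int, mode: str, T: int,
                        alphabet: Alphabet, seed: int):
    """Encoded arrays for one grid cell; handles aug expansion/evaluation.

    Returns ``(X_train, y_train, X_val, y_val, X_test, y_test, test_ids,
    n_test_variants)`` where ``n_test_variants`` is 7 for aug (each test
    sequence appears once per single mode, probabilities to be averaged)
    and 1 otherwise.
    """
    parts = _partition(samples, assignment, task)
    for name in ("train", "val", "test"):
        if not parts[name]:
            raise BenchmarkError(f"empty {name} partition for task {task}")

    def labels(ss):
        y = np.array([task_label(s, task) for s in ss])
        return y - 1 if task == 2 else y   # softmax classes 0..6

    if mode == "aug":
        def expanded(ss):
            return [v.symbols for s in ss
                    for v in augment(s.residues, T, seed=seed,
                                     source_id=s.origin_id or s.id).values()]
        X_train = encode_batch(expanded(parts["train"]), alphabet)
        y_train = np.repeat(labels(parts["train"]), len(SINGLE_MODES))
        X_val = encode_batch(expanded(parts["val"]), alphabet)
        y_val = np.repeat(labels(parts["val"]), len(SINGLE_MODES))
        X_test = encode_batch(expanded(parts["test"]), alphabet)
        y_test = labels(parts["test"])
        n_variants = len(SINGLE_MODES)
    else:
        X_train = encode_batch(_padded_strings(parts["train"], mode, T, seed), alphabet)
        y_train = labels(parts["train"])
        X_val = encode_batch(_padded_strings(parts["val"], mode, T, seed), alphabet)
        y_val = labels(parts["val"])
        X_test = encode_batch(_padded_strings(parts["test"], mode, T, seed), alphabet)
        y_test = labels(parts["test"])
        n_variants = 1
    test_ids = [s.id for s in parts["test"]]
    return X_train, y_train, X_val, y_val, X_test, y_test, test_ids, n_variants


def run_cell(samples, plan: SplitPlan, task: int, arch: ArchitectureSpec,
             mode: str, fold: int, T: int, config: TrainingConfig,
             alphabet: Alphabet | None = None) -> tuple[RunRecord, np.ndarray, nn.Network]:
    """Train and evaluate one (task, architecture, padding, fold) cell.

    Returns the record, the aligned true test labels and the trained model.
    """
    alphabet = alphabet or default_alphabet()
    if mode not in ALL_MODES:
        raise BenchmarkError(f"unknown padding mode {mode!r}")
    (X_tr, y_tr, X_va, y_va, X_te, y_te, test_ids,
     n_var) = prepare_cell_arrays(samples, plan.assignments[fold], task, mode,
                                  T, alphabet, config.seed)
    cell_tag = zlib.crc32(f"task{task}|{arch.name}|{mode}".encode())
    cell_seed = (config.seed * 1009 + fold * 101 + cell_tag) % (2**31)
    model = build_model(arch, (alphabet.size, T), task, seed=cell_seed)
    record = train(model, X_tr, y_tr, X_va, y_va, X_te,
                   replace(config, seed=cell_seed),
                   meta=dict(task=task, architecture=arch.name, padding=mode,
                             fold=fold, test_ids=test_ids))
    if n_var > 1:  # average the per-variant probabilities per test sequence
        p = record.probabilities
        p = p.reshape(len(test_ids), n_var, *p.shape[1:]).mean(axis=1)
        record.probabilities = p
    return record, y_te, model


def run_grid(samples, plan: SplitPlan, tasks, archs, modes, folds, T: int,
             config: TrainingConfig, alphabet: Alphabet | None = None,
             out_dir=None, keep_models: bool = False):
    """Run the factorial grid; persists/resumes per-cell results.

    Yields ``(RunRecord, y_true)`` per cell (and the model if
    ``keep_models``); failures are logged and the grid continues.
    """
    alphabet = alphabet or default_alphabet()
    results = []
    models = {}
    for task in tasks:
        for arch in archs:
            spec = arch if isinstance(arch, ArchitectureSpec) else ArchitectureSpec(arch)
            for mode in modes:
                for fold in folds:
                    key = f"task{task}_{spec.name}_{mode}_fold{fold}"
                    if out_dir is not None:
                        meta_path = Path(out_dir) / f"{key}.json"
                        if meta_path.exists():
                            rec, y = load_run_record(Path(out_dir), key)
                            results.append((rec, y))
                            continue
                    try:
                        rec, y, model = run_cell(samples, plan, task, spec, mode,
                                                 fold, T, config, alphabet)
                    except nn.TrainingDiverged as err:
                        logger.error("cell %s failed: %s", key, err)
                        continue
                    if out_dir is not None:
                        save_run_record(rec, y, Path(out_dir), key)
                    if keep_models:
                        models[(task, spec.name, mode, fold)] = model
                    results.append((rec, y))
    return (results, models) if keep_models else results


def save_run_record(rec: RunRecord, y_true: np.ndarray, out_dir: Path, key: str):
    out_dir.mkdir(parents=True, exist_ok=True)
    probs = rec.probabilities
    header = "id,y_true," + ",".join(
        [f"p{i+1}" for i in range(probs.shape[1])] if probs.ndim == 2 else ["p"])
    lines = [header]
    for i, sid in enumerate(rec.test_ids):
        row = probs[i] if probs.ndim == 2 else [probs[i]]
        lines.append(",".join([sid, str(int(y_true[i]))] + [f"{v:.8g}" for v in np.atleast_1d(row)]))
    (out_dir / f"{key}.csv").write_text("\n".join(lines) + "\n")
    meta = dict(task=rec.task, architecture=rec.architecture, padding=rec.padding,
                fold=rec.fold, selected_epoch=rec.selected_epoch,
                val_accuracy=rec.val_accuracy)
    (out_dir / f"{key}.json").write_text(json.dumps(meta, indent=1))


def load_run_record(out_dir: Path, key: str) -> tuple[RunRecord, np.ndarray]:
    meta = json.loads((out_dir / f"{key}.json").read_text())
    rows = (out_dir / f"{key}.csv").read_text().strip().split("\n")
    ids, ys, ps = [], [], []
    for line in rows[1:]:
        fields = line.split(",")
        ids.append(fields[0])
        ys.append(int(fields[1]))
        ps.append([float(v) for v in fields[2:]])
    probs = np.array(ps)
    if probs.shape[1] == 1:
        probs = probs[:, 0]
    rec = RunRecord(task=meta["task"], architecture=meta["architecture"],
                    padding=meta["padding"], fold=meta["fold"], test_ids=ids,
                    probabilities=probs, selected_epoch=meta["selected_epoch"],
                    val_accuracy=meta["val_accuracy"])
    return rec, np.array(ys)
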