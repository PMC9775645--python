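"""Supervised training, EasyEnsemble aggregation, cross-validation, the
small-dataset subsampling harness and batch prediction.

Every routine is fully determined by (seed, config, data): all random draws
(parameter init, batch order, dropout masks, splits, subsampling) derive
from the seed in the relevant config.  Training uses Adam with early
stopping on a held-out validation fraction; the best-validation weights are
restored before a model is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import metrics
from .capsnet import EcapsPNet, NetworkConfig
from .encoders import GloVeModel, PhysChemTable, encode_windows
from .peptides import (SiteDataset, candidate_sites, easy_ensemble_split,
                       extract_window)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    ensemble_k: int = 5
    patience: int = 5
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("epochs", "batch_size", "learning_rate", "optimizer",
                 "seed", "ensemble_k", "patience", "val_fraction")}


class Adam:
    """Adam over a named parameter dict."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def dataset_arrays(dataset: SiteDataset, scheme: str = "OneHot",
                   table: PhysChemTable | None = None,
                   glove_model: GloVeModel | None = None):
    """Encode a SiteDataset into (X, y, origins)."""
    windows = dataset.positives + dataset.negatives
    y = np.array([1] * len(dataset.positives) + [0] * len(dataset.negatives))
    X = encode_windows(windows, scheme, table, glove_model)
    origins = np.array([w.origin[0] for w in windows])
    return X, y, origins


def _stratified_holdout(y, fraction, rng):
    """Index split (train, held) keeping the label ratio; deterministic."""
    idx_train, idx_held = [], []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        cls_idx = cls_idx[rng.permutation(len(cls_idx))]
        n_held = int(round(fraction * len(cls_idx)))
        idx_held.extend(cls_idx[:n_held])
        idx_train.extend(cls_idx[n_held:])
    return np.sort(np.array(idx_train, dtype=int)), \
        np.sort(np.array(idx_held, dtype=int))


def fit_arrays(X: np.ndarray, y: np.ndarray, net_config: NetworkConfig,
               train_config: TrainConfig):
    """Core training loop on encoded arrays; returns (net, history).

    History records per-epoch mean training loss and validation loss; the
    returned network carries the best-validation weights.  A non-finite
    loss aborts with a diagnostic rather than silently diverging.
    """
    tc = train_config
    rng = np.random.default_rng(tc.seed)
    net = EcapsPNet(net_config, input_dim=X.shape[2], seq_len=X.shape[1],
                    seed=int(rng.integers(2**31 - 1)))
    history = {"train_loss": [], "val_loss": []}
    if tc.epochs == 0:
        return net, history
    if tc.val_fraction > 0 and len(y) >= 10:
        tr_idx, val_idx = _stratified_holdout(y, tc.val_fraction, rng)
        if len(val_idx) == 0 or len(np.unique(y[val_idx])) < 2:
            tr_idx = np.arange(len(y))
            val_idx = tr_idx
    else:
        tr_idx = np.arange(len(y))
        val_idx = tr_idx
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    opt = Adam(net.params, lr=tc.learning_rate)
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(tc.epochs):
        perm = rng.permutation(len(ytr))
        losses, weights = [], []
        for start in range(0, len(ytr), tc.batch_size):
            sel = perm[start:start + tc.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            net.zero_grad()
            v, _, recon = net.forward(xb, training=True, rng=rng, labels=yb)
            loss = net.loss(v, recon, xb, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {start}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(sel))
        history["train_loss"].append(float(np.average(losses, weights=weights)))
        val_loss = _eval_loss(net, Xval, yval, tc.batch_size)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val, best_state, since_best = val_loss, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def _eval_loss(net: EcapsPNet, X, y, batch_size: int) -> float:
    total, n = 0.0, 0
    for start in range(0, len(y), batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        v, _, recon = net.forward(xb, training=False)
        total += float(net.loss(v, recon, xb, yb).data) * len(yb)
        n += len(yb)
    return total / max(n, 1)


def model_scores(net: EcapsPNet, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Positive-class probabilities in deterministic eval mode."""
    out = []
    for start in range(0, len(X), batch_size):
        _, s, _ = net.forward(X[start:start + batch_size], training=False)
        out.append(s)
    return np.concatenate(out) if out else np.zeros(0)


def train_model(dataset: SiteDataset, net_config: NetworkConfig,
                train_config: TrainConfig, scheme: str = "OneHot",
                table: PhysChemTable | None = None,
                glove_model: GloVeModel | None = None):
    """Train one network on a (balanced) dataset; returns (net, history)."""
    X, y, _ = dataset_arrays(dataset, scheme, table, glove_model)
    return fit_arrays(X, y, net_config, train_config)


@dataclass
class EnsembleModel:
    """EasyEnsemble aggregate: one member per balanced subset; the ensemble
    score is the arithmetic mean of member positive-class scores."""
    members: list[EcapsPNet]
    scheme: str = "OneHot"
    aggregation: str = "mean"

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.mean([model_scores(m, X) for m in self.members], axis=0)

    def member_origin_sets(self, splits) -> list[set]:
        return [{w.origin for w in s.negatives} for s in splits.subsets]


def train_ensemble(dataset: SiteDataset, k: int, net_config: NetworkConfig,
                   train_config: TrainConfig, scheme: str = "OneHot",
                   table: PhysChemTable | None = None,
                   glove_model: GloVeModel | None = None):
    """Train k members on EasyEnsemble subsets; returns (ensemble, histories)."""
    if k < 1:
        raise ValueError("ensemble size k must be >= 1")
    split = easy_ensemble_split(dataset, k, train_config.seed)
    rng = np.random.default_rng(train_config.seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=k)
    members, histories = [], []
    for subset, seed in zip(split.subsets, member_seeds):
        tc = TrainConfig(**{**train_config.to_dict(), "seed": int(seed)})
        net, hist = train_model(subset, net_config, tc, scheme, table,
                                glove_model)
        members.append(net)
        histories.append(hist)
    return EnsembleModel(members, scheme=scheme), histories


def _default_train_fn(net_config: NetworkConfig, train_config: TrainConfig):
    def fn(Xtr, ytr, seed):
        tc = TrainConfig(**{**train_config.to_dict(), "seed": int(seed)})
        net, _ = fit_arrays(Xtr, ytr, net_config, tc)
        return lambda X: model_scores(net, X)
    return fn


def cross_validate(dataset: SiteDataset, folds: int = 5,
                   net_config: NetworkConfig | None = None,
                   train_config: TrainConfig | None = None,
                   scheme: str = "OneHot",
                   table: PhysChemTable | None = None,
                   glove_model: GloVeModel | None = None,
                   protein_disjoint: bool = False,
                   train_fn=None):
    """Stratified k-fold cross-validation.

    *train_fn(X_train, y_train, seed) -> scorer* may replace the default
    network training (e.g. to evaluate a reference or null classifier with
    the same fold machinery).  With ``protein_disjoint`` folds never split
    one protein's sites across train and test.  Returns (reports, summary)
    where summary maps each metric to (mean, sd) over folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(dataset) < folds:
        raise ValueError("dataset smaller than the number of folds")
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    X, y, origins = dataset_arrays(dataset, scheme, table, glove_model)
    if protein_disjoint:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=train_config.seed)
        fold_iter = splitter.split(X, y, groups=origins)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=train_config.seed)
        fold_iter = splitter.split(X, y)
    train_fn = train_fn or _default_train_fn(net_config, train_config)
    reports = []
    for i, (tr, te) in enumerate(fold_iter):
        if protein_disjoint:
            assert not set(origins[tr]) & set(origins[te]), \
                "protein leakage across folds"
        else:
            assert not set(tr) & set(te), "index leakage across folds"
        scorer = train_fn(X[tr], y[tr], train_config.seed + i)
        reports.append(metrics.evaluate(scorer(X[te]), y[te]))
    keys = ("acc", "sn", "sp", "mcc", "auc")
    summary = {k: (float(np.mean([getattr(r, k) for r in reports])),
                   float(np.std([getattr(r, k) for r in reports])))
               for k in keys}
    return reports, summary


def subsample_harness(dataset: SiteDataset,
                      ratios=(0.1, 0.2, 0.4, 0.7, 1.0),
                      repeats: int = 50,
                      net_config: NetworkConfig | None = None,
                      train_config: TrainConfig | None = None,
                      scheme: str = "OneHot",
                      table: PhysChemTable | None = None,
                      glove_model: GloVeModel | None = None,
                      test_fraction: float = 0.2):
    """Learning-size protocol: hold out a fixed stratified test split, then
    for each training-set ratio draw that fraction of the remaining data
    (stratified, fresh draw per repeat), train, and record test accuracy.

    Returns {ratio: [acc, ...]} with ``repeats`` entries per ratio.  The
    test split depends only on the base seed; at ratio 1.0 every repeat
    sees identical training data and only model initialisation varies.
    """
    for r in ratios:
        if not 0.0 < r <= 1.0:
            raise ValueError(f"ratio {r} outside (0, 1]")
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    X, y, _ = dataset_arrays(dataset, scheme, table, glove_model)
    rng = np.random.default_rng(train_config.seed)
    tr_idx, te_idx = _stratified_holdout(y, test_fraction, rng)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xte, yte = X[te_idx], y[te_idx]
    results: dict[float, list[float]] = {}
    for r in ratios:
        accs = []
        for rep in range(repeats):
            data_rng = np.random.default_rng([train_config.seed, rep, 1])
            if r < 1.0:
                keep, _ = _stratified_holdout(ytr, 1.0 - r, data_rng)
            else:
                keep = np.arange(len(ytr))
            model_seed = int(np.random.default_rng(
                [train_config.seed, rep, 7]).integers(2**31 - 1))
            tc = TrainConfig(**{**train_config.to_dict(), "seed": model_seed})
            net, _ = fit_arrays(Xtr[keep], ytr[keep], net_config, tc)
            scores = model_scores(net, Xte)
            accs.append(metrics.accuracy(metrics.confusion(scores, yte)))
        results[float(r)] = accs
    return results


def predict(model, records, sites=None, scheme: str = "OneHot",
            table: PhysChemTable | None = None,
            glove_model: GloVeModel | None = None,
            threshold: float = 0.5) -> pd.DataFrame:
    """Score candidate sites of the given proteins.

    *model* is an :class:`EcapsPNet` or :class:`EnsembleModel`.  When
    *sites* is None, every S/T/Y residue is a candidate (prediction mode has
    no positive-protein restriction).  Returns one row per site:
    protein_id, position, residue, score, label.
    """
    if sites is None:
        sites = [s for rec in records for s in candidate_sites(rec)]
    idx = {rec.id: rec for rec in records}
    rows = []
    windows = []
    for s in sites:
        windows.append(extract_window(idx[s.protein_id], s.position))
        rows.append((s.protein_id, s.position, s.residue))
    if not windows:
        return pd.DataFrame(columns=["protein_id", "position", "residue",
                                     "score", "label"])
    X = encode_windows(windows, scheme, table, glove_model)
    if isinstance(model, EnsembleModel):
        scores = model.scores(X)
    else:
        scores = model_scores(model, X)
    df = pd.DataFrame(rows, columns=["protein_id", "position", "residue"])
    df["score"] = scores
    df["label"] = np.where(scores >= threshold, "positive", "negative")
    return df


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, scheme: str, residue_type: str,
                    glove_model: GloVeModel | None = None,
                    train_config: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    """Write a single-file archive holding config, weights and the encoder
    context (scheme, residue type, GloVe vocabulary/embeddings)."""
    import json

    members = model.members if isinstance(model, EnsembleModel) else [model]
    meta = {
        "kind": "ensemble" if isinstance(model, EnsembleModel) else "single",
        "n_members": len(members),
        "config": members[0].config.to_dict(),
        "input_dim": members[0].input_dim,
        "seq_len": members[0].seq_len,
        "scheme": scheme,
        "residue_type": residue_type,
        "train_config": train_config.to_dict() if train_config else None,
        "glove": None,
        "extra": extra or {},
    }
    arrays = {}
    if glove_model is not None:
        order = sorted(glove_model.vocabulary, key=glove_model.vocabulary.get)
        meta["glove"] = {"tokens": order, "dim": glove_model.dim,
                         "ngram": glove_model.ngram}
        arrays["glove_emb"] = glove_model.embeddings
    for i, net in enumerate(members):
        for k, v in net.state_dict().items():
            arrays[f"m{i}/{k}"] = v
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (model, meta, glove)."""
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = NetworkConfig.from_dict(meta["config"])
    members = []
    for i in range(meta["n_members"]):
        net = EcapsPNet(cfg, input_dim=meta["input_dim"],
                        seq_len=meta["seq_len"])
        prefix = f"m{i}/"
        net.load_state_dict({k[len(prefix):]: v for k, v in arrays.items()
                             if k.startswith(prefix)})
        members.append(net)
    glove = None
    if meta.get("glove"):
        g = meta["glove"]
        glove = GloVeModel({t: j for j, t in enumerate(g["tokens"])},
                           np.zeros((len(g["tokens"]), len(g["tokens"]))),
                           dim=g["dim"], ngram=g["ngram"],
                           embeddings=arrays["glove_emb"])
    if meta["kind"] == "ensemble":
        model = EnsembleModel(members, scheme=meta["scheme"])
    else:
        model = members[0]
    return model, meta, glove
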