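"""Peptide-window encodings: One-Hot, AAindex, AAPCA, GloVe and AAglove.

Each scheme maps a 33-residue window to a numeric matrix:

==========  ==========  =======================================================
scheme      shape       content
==========  ==========  =======================================================
OneHot      (33, 21)    one bit per residue, slot 21 for the null/gap symbol
AAindex     (33, 10)    nine min-max-normalised physicochemical properties
                        plus a gap-indicator tenth column
AAPCA       (33, 6)     five principal-component descriptors plus gap flag
GloVe       (33, d)     per-position subword embeddings from a co-occurrence
                        model trained on the peptide corpus (default d=10)
AAglove     (33, 10, 2) channel 1 = AAindex, channel 2 = 10-d GloVe
==========  ==========  =======================================================

Gap positions contribute zeros to all value channels and a one only to the
explicit gap indicator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .peptides import AMINO_ACIDS, GAP, PeptideWindow

SCHEMES = ("OneHot", "GloVe", "AAPCA", "AAindex", "AAglove")
ONEHOT_DIM = 21
AAINDEX_DIM = 10
AAPCA_DIM = 6

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class EncodedPeptide:
    values: np.ndarray
    scheme: str


@dataclass(frozen=True)
class PhysChemTable:
    """Per-residue property vectors: 20x9 normalised AAindex-style scales and
    the 20x5 principal-component descriptors, rows in AMINO_ACIDS order."""
    aaindex: np.ndarray   # (20, 9), min-max normalised to [0, 1] per column
    aapca: np.ndarray     # (20, 5)
    property_names: tuple[str, ...]

    def __post_init__(self):
        if self.aaindex.shape != (20, 9) or self.aapca.shape != (20, 5):
            raise ValueError("physicochemical tables must be 20x9 and 20x5")
        if not (np.isfinite(self.aaindex).all() and np.isfinite(self.aapca).all()):
            raise ValueError("physicochemical tables contain non-finite values")


def _read_packaged_tsv(name: str) -> tuple[list[str], dict[str, np.ndarray]]:
    text = (importlib.resources.files("ecapsp") / "data" / name).read_text()
    header: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not header:
            header = parts[1:]
            continue
        rows[parts[0]] = np.array([float(x) for x in parts[1:]])
    return header, rows


def load_physchem_table() -> PhysChemTable:
    """Load the packaged property tables, min-max normalising each AAindex
    property column to [0, 1]."""
    names, aaidx = _read_packaged_tsv("aaindex_properties.tsv")
    _, pca = _read_packaged_tsv("aapca_descriptors.tsv")
    raw = np.stack([aaidx[aa] for aa in AMINO_ACIDS])
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    norm = (raw - lo) / (hi - lo)
    return PhysChemTable(norm, np.stack([pca[aa] for aa in AMINO_ACIDS]),
                         tuple(names))


_DEFAULT_TABLE: PhysChemTable | None = None


def default_table() -> PhysChemTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_physchem_table()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# fixed encodings
# ---------------------------------------------------------------------------

def encode_onehot(window: PeptideWindow) -> EncodedPeptide:
    """21-bit one-hot: 20 residues plus the null slot (last column)."""
    out = np.zeros((len(window.residues), ONEHOT_DIM))
    for i, ch in enumerate(window.residues):
        out[i, _AA_INDEX.get(ch, ONEHOT_DIM - 1)] = 1.0
    return EncodedPeptide(out, "OneHot")


def decode_onehot(values: np.ndarray) -> str:
    """Inverse of :func:`encode_onehot` (argmax per row)."""
    idx = values.argmax(axis=1)
    return "".join(AMINO_ACIDS[i] if i < 20 else GAP for i in idx)


def encode_aaindex(window: PeptideWindow,
                   table: PhysChemTable | None = None) -> EncodedPeptide:
    """Nine normalised property values per residue; the tenth column is 1
    for a gap (the property columns are then 0)."""
    table = table or default_table()
    out = np.zeros((len(window.residues), AAINDEX_DIM))
    for i, ch in enumerate(window.residues):
        if ch in _AA_INDEX:
            out[i, :9] = table.aaindex[_AA_INDEX[ch]]
        else:
            out[i, 9] = 1.0
    return EncodedPeptide(out, "AAindex")


def encode_aapca(window: PeptideWindow,
                 table: PhysChemTable | None = None) -> EncodedPeptide:
    """Five principal-component descriptors per residue; gap rows are
    [0, 0, 0, 0, 0, 1]."""
    table = table or default_table()
    out = np.zeros((len(window.residues), AAPCA_DIM))
    for i, ch in enumerate(window.residues):
        if ch in _AA_INDEX:
            out[i, :5] = table.aapca[_AA_INDEX[ch]]
        else:
            out[i, 5] = 1.0
    return EncodedPeptide(out, "AAPCA")


# ---------------------------------------------------------------------------
# GloVe
# ---------------------------------------------------------------------------

@dataclass
class GloVeModel:
    """A co-occurrence model over protein subwords (n-grams).

    Built in two stages: :func:`build_cooccurrence` fills the symmetric count
    matrix; :func:`train_glove` fits embeddings by the weighted least-squares
    objective  sum_ij f(X_ij) (w_i.w~_j + b_i + b~_j - log X_ij)^2  with
    f(x) = min(1, (x/x_max)^alpha), optimised full-batch with AdaGrad.
    The final embedding of a token is w + w~.
    """
    vocabulary: dict[str, int]
    cooccurrence: np.ndarray
    dim: int = 10
    context_window: int = 5
    x_max: float = 10.0
    alpha: float = 0.75
    ngram: int = 1
    embeddings: np.ndarray | None = None
    history: list[float] = field(default_factory=list)

    def vector(self, token: str) -> np.ndarray:
        """Embedding of *token*; zeros when out of vocabulary (incl. gaps)."""
        if self.embeddings is None:
            raise ValueError("model has no trained embeddings")
        i = self.vocabulary.get(token)
        return np.zeros(self.dim) if i is None else self.embeddings[i]

    def save(self, path) -> None:
        if self.embeddings is None:
            raise ValueError("model has no trained embeddings")
        order = sorted(self.vocabulary, key=self.vocabulary.get)
        with open(path, "w") as fh:
            fh.write(f"# dim={self.dim} ngram={self.ngram}\n")
            for tok in order:
                vec = "\t".join(repr(float(v))
                                for v in self.embeddings[self.vocabulary[tok]])
                fh.write(f"{tok}\t{vec}\n")

    @classmethod
    def load(cls, path) -> "GloVeModel":
        vocab, vecs, meta = {}, [], {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    meta = dict(kv.split("=") for kv in line[1:].split())
                    continue
                parts = line.rstrip("\n").split("\t")
                vocab[parts[0]] = len(vocab)
                vecs.append([float(x) for x in parts[1:]])
        emb = np.array(vecs)
        return cls(vocab, np.zeros((len(vocab), len(vocab))),
                   dim=int(meta.get("dim", emb.shape[1])),
                   ngram=int(meta.get("ngram", 1)), embeddings=emb)


def tokenize(residues: str, ngram: int = 1) -> list[str]:
    """Split a peptide into overlapping n-gram subwords, skipping any that
    contain the gap symbol."""
    toks = [residues[i:i + ngram] for i in range(len(residues) - ngram + 1)]
    return [t for t in toks if GAP not in t]


def build_cooccurrence(corpus, context_window: int = 5,
                       ngram: int = 1) -> GloVeModel:
    """Count token co-occurrences within *context_window* positions.

    *corpus* items are token lists, whitespace-separated strings, or
    :class:`PeptideWindow` objects (tokenised to n-grams).  The matrix is
    symmetric by construction: each ordered pair within range adds one.
    """
    sequences: list[list[str]] = []
    for item in corpus:
        if isinstance(item, PeptideWindow):
            sequences.append(tokenize(item.residues, ngram))
        elif isinstance(item, str):
            sequences.append(item.split())
        else:
            sequences.append(list(item))
    vocab: dict[str, int] = {}
    for seq in sequences:
        for tok in seq:
            vocab.setdefault(tok, len(vocab))
    if not vocab:
        raise ValueError("empty vocabulary: corpus has no tokens")
    X = np.zeros((len(vocab), len(vocab)))
    for seq in sequences:
        idx = [vocab[t] for t in seq]
        for i, ti in enumerate(idx):
            for j in range(max(0, i - context_window), i):
                X[ti, idx[j]] += 1.0
                X[idx[j], ti] += 1.0
    return GloVeModel(vocab, X, context_window=context_window, ngram=ngram)


def train_glove(model: GloVeModel, dim: int = 10, epochs: int = 50,
                seed: int = 0, learning_rate: float = 0.05) -> GloVeModel:
    """Fit GloVe embeddings on the model's co-occurrence counts (in place).

    Full-batch AdaGrad over the nonzero count cells; the objective value per
    epoch is recorded in ``model.history``.  Deterministic given *seed*.
    """
    if dim < 1:
        raise ValueError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(model.vocabulary)
    rows, cols = np.nonzero(model.cooccurrence)
    if rows.size == 0:
        # degenerate corpus (single token): zero embeddings
        model.dim, model.embeddings, model.history = dim, np.zeros((n, dim)), []
        return model
    logx = np.log(model.cooccurrence[rows, cols])
    weight = np.minimum(1.0, (model.cooccurrence[rows, cols] / model.x_max)
                        ** model.alpha)
    scale = 0.5 / dim
    w = rng.uniform(-scale, scale, (n, dim))
    wt = rng.uniform(-scale, scale, (n, dim))
    b = np.zeros(n)
    bt = np.zeros(n)
    gw, gwt = np.ones_like(w), np.ones_like(wt)
    gb, gbt = np.ones_like(b), np.ones_like(bt)
    history = []
    for _ in range(epochs):
        diff = (np.einsum("kd,kd->k", w[rows], wt[cols])
                + b[rows] + bt[cols] - logx)
        history.append(float(np.sum(weight * diff ** 2)))
        g = 2.0 * weight * diff
        grad_w = np.zeros_like(w)
        grad_wt = np.zeros_like(wt)
        np.add.at(grad_w, rows, g[:, None] * wt[cols])
        np.add.at(grad_wt, cols, g[:, None] * w[rows])
        grad_b = np.bincount(rows, weights=g, minlength=n)
        grad_bt = np.bincount(cols, weights=g, minlength=n)
        gw += grad_w ** 2
        gwt += grad_wt ** 2
        gb += grad_b ** 2
        gbt += grad_bt ** 2
        w -= learning_rate * grad_w / np.sqrt(gw)
        wt -= learning_rate * grad_wt / np.sqrt(gwt)
        b -= learning_rate * grad_b / np.sqrt(gb)
        bt -= learning_rate * grad_bt / np.sqrt(gbt)
    model.dim = dim
    model.embeddings = w + wt
    model.history = history
    return model


def glove_objective(model: GloVeModel, w=None) -> float:
    """Current value of the weighted least-squares objective (diagnostic)."""
    return model.history[-1] if model.history else float("nan")


def encode_glove(window: PeptideWindow, model: GloVeModel) -> EncodedPeptide:
    """Per-position subword embedding; gap/out-of-vocabulary positions get
    the zero vector.  For n-grams > 1 the subword starting at each position
    is used (trailing positions without a full n-gram are zero)."""
    if model.embeddings is None:
        raise ValueError("GloVe model must be trained before encoding")
    L = len(window.residues)
    out = np.zeros((L, model.dim))
    for i in range(L):
        sub = window.residues[i:i + model.ngram]
        if len(sub) == model.ngram and GAP not in sub:
            out[i] = model.vector(sub)
    return EncodedPeptide(out, "GloVe")


def encode_aaglove(window: PeptideWindow, table: PhysChemTable | None = None,
                   model: GloVeModel | None = None) -> EncodedPeptide:
    """Two-channel encoding: channel 1 the AAindex matrix, channel 2 the
    GloVe matrix.  Requires a 10-dimensional GloVe model so the channels
    have the same width."""
    if model is None:
        raise ValueError("AAglove requires a trained GloVe model")
    if model.dim != AAINDEX_DIM:
        raise ValueError(
            f"AAglove needs a {AAINDEX_DIM}-d GloVe model, got {model.dim}-d")
    phys = encode_aaindex(window, table).values
    emb = encode_glove(window, model).values
    return EncodedPeptide(np.stack([phys, emb], axis=-1), "AAglove")


def encode_window(window: PeptideWindow, scheme: str,
                  table: PhysChemTable | None = None,
                  model: GloVeModel | None = None) -> EncodedPeptide:
    """Dispatch on scheme name."""
    if scheme == "OneHot":
        return encode_onehot(window)
    if scheme == "AAindex":
        return encode_aaindex(window, table)
    if scheme == "AAPCA":
        return encode_aapca(window, table)
    if scheme == "GloVe":
        if model is None:
            raise ValueError("GloVe encoding requires a trained model")
        return encode_glove(window, model)
    if scheme == "AAglove":
        return encode_aaglove(window, table, model)
    raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {SCHEMES}")


def network_input(encoded: EncodedPeptide) -> np.ndarray:
    """Flatten a possibly two-channel encoding to the (33, D) matrix the
    network consumes (AAglove channels are spliced along the feature axis)."""
    v = encoded.values
    if v.ndim == 3:
        return np.concatenate([v[..., c] for c in range(v.shape[-1])], axis=-1)
    return v


def encode_windows(windows, scheme: str, table: PhysChemTable | None = None,
                   model: GloVeModel | None = None) -> np.ndarray:
    """Encode a list of windows into a (N, 33, D) network-ready array."""
    return np.stack([network_input(encode_window(w, scheme, table, model))
                     for w in windows])
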