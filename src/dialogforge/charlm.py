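"""Character-level recurrent language model for utterance generation.

The model is the classic three-layer stack: a character embedding lookup
(256 dimensions), a single recurrent layer (LSTM by default, GRU
configurable) with dropout on its outputs, and a dense softmax over the
character vocabulary trained with categorical cross-entropy.  Training
text is the corpus with every utterance terminated by a newline; it is cut
into non-overlapping fixed-length windows whose targets are the inputs
shifted by one character.  Generation feeds sampled characters back in
autoregressively, drawing from the temperature-scaled softmax until a
newline or a length cap.

Everything runs on NumPy with Adam and global-norm gradient clipping, so
training is bit-reproducible per seed on a single thread.  Two
configuration profiles are provided: the full profile (1024 recurrent
units) and a desk profile (256 units) for routine runs at small scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "CharVocab",
    "WindowedDataset",
    "CharLMConfig",
    "CharLM",
    "IntegrityError",
    "build_vocab",
    "make_windows",
    "init_charlm",
    "train_charlm",
    "evaluate_charlm",
    "sample",
    "save_charlm",
    "load_charlm",
]


class IntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class CharVocab:
    """Bijective character <-> integer mapping.

    The newline terminator maps to id 0 when present; remaining characters
    are ordered by descending frequency, ties by codepoint — a fixed rule
    so the mapping is deterministic for any training text.
    """

    char_to_id: Dict[str, int]
    id_to_char: Tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.id_to_char)

    @property
    def newline_id(self) -> Optional[int]:
        return self.char_to_id.get("\n")

    def encode(self, text: str) -> np.ndarray:
        unknown = sorted({ch for ch in text if ch not in self.char_to_id})
        if unknown:
            raise ValueError(f"characters not in vocabulary: {unknown!r}")
        return np.array([self.char_to_id[ch] for ch in text], dtype=np.int64)

    def decode(self, ids) -> str:
        return "".join(self.id_to_char[int(i)] for i in ids)


def build_vocab(text: str) -> CharVocab:
    if not text:
        raise ValueError("training text must be non-empty")
    freq: Dict[str, int] = {}
    for ch in text:
        freq[ch] = freq.get(ch, 0) + 1
    chars = sorted((c for c in freq if c != "\n"), key=lambda c: (-freq[c], ord(c)))
    ordered = (["\n"] if "\n" in freq else []) + chars
    return CharVocab(
        char_to_id={c: i for i, c in enumerate(ordered)},
        id_to_char=tuple(ordered),
    )


@dataclass
class WindowedDataset:
    inputs: np.ndarray  # (n, L) int
    targets: np.ndarray  # (n, L) int, inputs shifted by one
    vocab_size: int

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_windows(text: str, vocab: CharVocab, L: int = 100) -> WindowedDataset:
    """Cut the id-encoded text into non-overlapping stride-``L`` windows
    with one-step-shifted targets."""
    if len(text) <= L:
        raise ValueError(f"text length {len(text)} must exceed window length {L}")
    ids = vocab.encode(text)
    starts = range(0, len(ids) - L, L)
    inputs = np.stack([ids[s:s + L] for s in starts])
    targets = np.stack([ids[s + 1:s + L + 1] for s in starts])
    return WindowedDataset(inputs=inputs, targets=targets, vocab_size=vocab.size)


@dataclass(frozen=True)
class CharLMConfig:
    embed_dim: int = 256
    units: int = 1024
    dropout: float = 0.2
    batch_size: int = 64
    epochs: int = 30
    window: int = 100
    cell: str = "lstm"  # "lstm" | "gru"
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.embed_dim, self.units, self.batch_size, self.epochs, self.window) <= 0:
            raise ValueError("all sizes must be positive")
        if self.cell not in ("lstm", "gru"):
            raise ValueError("cell must be 'lstm' or 'gru'")

    @staticmethod
    def desk(**overrides) -> "CharLMConfig":
        """Small-scale profile: 256 recurrent units, otherwise identical."""
        return replace(CharLMConfig(units=256), **overrides)


@dataclass
class CharLM:
    cfg: CharLMConfig
    vocab_size: int
    params: Dict[str, np.ndarray]

    def gate_width(self) -> int:
        return 4 * self.cfg.units if self.cfg.cell == "lstm" else 3 * self.cfg.units


def _glorot(rng, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def init_charlm(vocab_size: int, cfg: CharLMConfig) -> CharLM:
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    H, D = cfg.units, cfg.embed_dim
    G = 4 * H if cfg.cell == "lstm" else 3 * H
    params = {
        "E": rng.uniform(-0.05, 0.05, size=(vocab_size, D)).astype(np.float32),
        "Wx": _glorot(rng, D, G),
        "Wh": _glorot(rng, H, G),
        "b": np.zeros(G, dtype=np.float32),
        "Wy": _glorot(rng, H, vocab_size),
        "by": np.zeros(vocab_size, dtype=np.float32),
    }
    if cfg.cell == "lstm":
        params["b"][H:2 * H] = 1.0  # forget-gate bias
    return CharLM(cfg=cfg, vocab_size=vocab_size, params=params)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _recurrent_forward(model: CharLM, xb: np.ndarray):
    """Run embedding + recurrent layer over a batch; returns hidden outputs
    and the cached tensors the backward pass needs."""
    p, cfg = model.params, model.cfg
    B, L = xb.shape
    H = cfg.units
    X = p["E"][xb]  # (B, L, D)
    Zx = X.reshape(B * L, -1) @ p["Wx"] + p["b"]
    Zx = Zx.reshape(B, L, -1)
    h = np.zeros((B, H), dtype=np.float32)
    cache: Dict[str, np.ndarray] = {"X": X}
    Hs = np.empty((B, L, H), dtype=np.float32)
    Hprev = np.empty((B, L, H), dtype=np.float32)
    if cfg.cell == "lstm":
        c = np.zeros((B, H), dtype=np.float32)
        I = np.empty((B, L, H), dtype=np.float32)
        F = np.empty_like(I)
        Gt = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        Cprev = np.empty_like(I)
        for t in range(L):
            z = Zx[:, t] + h @ p["Wh"]
            sig = _sigmoid(np.concatenate([z[:, :2 * H], z[:, 3 * H:]], axis=1))
            i, f, o = sig[:, :H], sig[:, H:2 * H], sig[:, 2 * H:]
            g = np.tanh(z[:, 2 * H:3 * H])
            Hprev[:, t] = h
            Cprev[:, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            I[:, t], F[:, t], Gt[:, t], O[:, t], C[:, t], Hs[:, t] = i, f, g, o, c, h
        cache.update(I=I, F=F, G=Gt, O=O, C=C, Cprev=Cprev, Hprev=Hprev)
    else:  # gru
        Z = np.empty((B, L, H), dtype=np.float32)
        R = np.empty_like(Z)
        Nn = np.empty_like(Z)
        Nh = np.empty_like(Z)
        for t in range(L):
            zh = h @ p["Wh"]
            z = _sigmoid(Zx[:, t, :H] + zh[:, :H])
            r = _sigmoid(Zx[:, t, H:2 * H] + zh[:, H:2 * H])
            nh = zh[:, 2 * H:]
            n = np.tanh(Zx[:, t, 2 * H:] + r * nh)
            Hprev[:, t] = h
            h = (1.0 - z) * n + z * h
            Z[:, t], R[:, t], Nn[:, t], Nh[:, t], Hs[:, t] = z, r, n, nh, h
        cache.update(Z=Z, R=R, N=Nn, Nh=Nh, Hprev=Hprev)
    cache["Hs"] = Hs
    return Hs, cache


def _recurrent_backward(model: CharLM, xb: np.ndarray, dH: np.ndarray, cache) -> Dict[str, np.ndarray]:
    p, cfg = model.params, model.cfg
    B, L = xb.shape
    H = cfg.units
    Wh = p["Wh"]
    dZx = np.empty((B, L, Wh.shape[1]), dtype=np.float32)
    dWh = np.zeros_like(Wh)
    dh_next = np.zeros((B, H), dtype=np.float32)
    if cfg.cell == "lstm":
        I, F, Gt, O, C, Cprev = (cache[k] for k in ("I", "F", "G", "O", "C", "Cprev"))
        dc_next = np.zeros((B, H), dtype=np.float32)
        dz = np.empty((B, 4 * H), dtype=np.float32)
        for t in range(L - 1, -1, -1):
            dh = dH[:, t] + dh_next
            i, f, g, o, c, cp = I[:, t], F[:, t], Gt[:, t], O[:, t], C[:, t], Cprev[:, t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            np.multiply(dc * g, i * (1 - i), out=dz[:, :H])
            np.multiply(dc * cp, f * (1 - f), out=dz[:, H:2 * H])
            np.multiply(dc * i, 1 - g * g, out=dz[:, 2 * H:3 * H])
            np.multiply(do, o * (1 - o), out=dz[:, 3 * H:])
            dZx[:, t] = dz
            dWh += cache["Hprev"][:, t].T @ dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
    else:
        Z, R, Nn, Nh = (cache[k] for k in ("Z", "R", "N", "Nh"))
        for t in range(L - 1, -1, -1):
            dh = dH[:, t] + dh_next
            z, r, n, nh, hp = Z[:, t], R[:, t], Nn[:, t], Nh[:, t], cache["Hprev"][:, t]
            dz_gate = dh * (hp - n)
            dn = dh * (1.0 - z)
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * nh
            dnh = dn_pre * r
            dz_pre = dz_gate * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            dZx[:, t] = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
            dZh = np.concatenate([dz_pre, dr_pre, dnh], axis=1)
            dWh += hp.T @ dZh
            dh_next = dZh @ Wh.T + dh * z
    X = cache["X"]
    D = X.shape[2]
    dWx = X.reshape(B * L, D).T @ dZx.reshape(B * L, -1)
    db = dZx.sum(axis=(0, 1))
    dX = dZx.reshape(B * L, -1) @ p["Wx"].T
    # scatter-add via one-hot matmul (small vocab; much faster than add.at)
    flat = xb.ravel()
    onehot = np.zeros((flat.size, p["E"].shape[0]), dtype=np.float32)
    onehot[np.arange(flat.size), flat] = 1.0
    dE = onehot.T @ dX
    return {"E": dE, "Wx": dWx, "Wh": dWh, "b": db}


def _batch_forward_backward(model: CharLM, xb, yb, dropout_mask=None, compute_grads=True):
    p = model.params
    B, L = xb.shape
    Hs, cache = _recurrent_forward(model, xb)
    Hd = Hs if dropout_mask is None else Hs * dropout_mask
    logits = Hd.reshape(B * L, -1) @ p["Wy"] + p["by"]
    logits -= logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    probs = exp / exp.sum(axis=1, keepdims=True)
    flat_y = yb.ravel()
    idx = np.arange(B * L)
    loss = float(-np.log(np.maximum(probs[idx, flat_y], 1e-12)).mean())
    correct = int((probs.argmax(axis=1) == flat_y).sum())
    if not compute_grads:
        return loss, correct, None
    dlogits = probs
    dlogits[idx, flat_y] -= 1.0
    dlogits /= B * L
    dlogits = dlogits.astype(np.float32)
    grads = {
        "Wy": Hd.reshape(B * L, -1).T @ dlogits,
        "by": dlogits.sum(axis=0),
    }
    dHd = (dlogits @ p["Wy"].T).reshape(B, L, -1)
    if dropout_mask is not None:
        dHd = dHd * dropout_mask
    grads.update(_recurrent_backward(model, xb, dHd, cache))
    return loss, correct, grads


def _clip(grads: Dict[str, np.ndarray], max_norm: float) -> None:
    total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = np.float32(max_norm / (total + 1e-12))
        for g in grads.values():
            g *= scale


def train_charlm(
    d: WindowedDataset,
    cfg: CharLMConfig,
    model: Optional[CharLM] = None,
) -> Tuple[CharLM, Dict[str, List[float]]]:
    """Train with Adam; returns the model and per-epoch training loss and
    next-character accuracy (running averages over each epoch's batches,
    measured before each batch's update)."""
    if len(d) == 0:
        raise ValueError("dataset is empty")
    if int(d.inputs.max()) >= d.vocab_size or int(d.targets.max()) >= d.vocab_size:
        raise IntegrityError("dataset ids exceed the declared vocabulary size")
    if model is None:
        model = init_charlm(d.vocab_size, cfg)
    elif model.vocab_size != d.vocab_size:
        raise IntegrityError(
            f"model vocabulary ({model.vocab_size}) does not match dataset ({d.vocab_size})"
        )
    p = model.params
    rng = np.random.default_rng((cfg.seed + 1) & 0x7FFFFFFF)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(w) for k, w in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-7
    step = 0
    history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    n = len(d)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_loss = 0.0
        tot_correct = 0
        tot_chars = 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            xb, yb = d.inputs[sel], d.targets[sel]
            mask = None
            if cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (rng.random((xb.shape[0], xb.shape[1], cfg.units)) < keep)
                mask = mask.astype(np.float32) / np.float32(keep)
            loss, correct, grads = _batch_forward_backward(model, xb, yb, dropout_mask=mask)
            chars = xb.size
            tot_loss += loss * chars
            tot_correct += correct
            tot_chars += chars
            _clip(grads, cfg.clip_norm)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * (g * g)
                p[k] -= (lr_t * m[k] / (np.sqrt(v[k]) + eps)).astype(p[k].dtype)
        history["loss"].append(tot_loss / tot_chars)
        history["accuracy"].append(tot_correct / tot_chars)
    return model, history


def evaluate_charlm(d: WindowedDataset, model: CharLM, batch_size: int = 64) -> Tuple[float, float]:
    """Mean next-character cross-entropy and accuracy without updates or
    dropout."""
    tot_loss = 0.0
    tot_correct = 0
    tot_chars = 0
    for lo in range(0, len(d), batch_size):
        xb, yb = d.inputs[lo:lo + batch_size], d.targets[lo:lo + batch_size]
        loss, correct, _ = _batch_forward_backward(model, xb, yb, compute_grads=False)
        tot_loss += loss * xb.size
        tot_correct += correct
        tot_chars += xb.size
    return tot_loss / tot_chars, tot_correct / tot_chars


# ---------------------------------------------------------------------------
# sampling

def _step(model: CharLM, char_id: int, state):
    """One autoregressive step; state is (h, c) for LSTM, (h,) for GRU."""
    p, cfg = model.params, model.cfg
    H = cfg.units
    x = p["E"][np.array([char_id])]
    z = x @ p["Wx"] + p["b"]
    if cfg.cell == "lstm":
        h, c = state
        z = z + h @ p["Wh"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        state = (h, c)
    else:
        (h,) = state
        zh = h @ p["Wh"]
        zg = _sigmoid(z[:, :H] + zh[:, :H])
        r = _sigmoid(z[:, H:2 * H] + zh[:, H:2 * H])
        n = np.tanh(z[:, 2 * H:] + r * zh[:, 2 * H:])
        h = (1.0 - zg) * n + zg * h
        state = (h,)
    logits = (state[0] @ p["Wy"] + p["by"])[0]
    return logits, state


def sample(
    model: CharLM,
    vocab: CharVocab,
    seed_text: str,
    temperature: float = 1.0,
    max_len: int = 200,
    seed: int = 0,
) -> str:
    """Generate one utterance by temperature sampling.

    The seed text is fed through the network, then characters are drawn
    from the temperature-scaled softmax and fed back until a newline or
    ``max_len`` characters; the (newline-free) text including the seed is
    returned.  ``temperature`` below 1e-6 is treated as the greedy argmax
    limit.  Reproducible per ``seed``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if not seed_text:
        raise ValueError("seed_text must be non-empty")
    ids = vocab.encode(seed_text)  # raises listing any OOV characters
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    H = model.cfg.units
    state = (np.zeros((1, H), dtype=np.float32),)
    if model.cfg.cell == "lstm":
        state = (state[0], np.zeros((1, H), dtype=np.float32))
    logits = None
    for cid in ids:
        logits, state = _step(model, int(cid), state)
    out = list(seed_text)
    newline = vocab.newline_id
    while len(out) < max_len:
        if temperature < 1e-6:
            nxt = int(np.argmax(logits))
        else:
            scaled = logits.astype(np.float64) / temperature
            scaled -= scaled.max()
            probs = np.exp(scaled)
            probs /= probs.sum()
            nxt = int(rng.choice(len(probs), p=probs))
        if newline is not None and nxt == newline:
            break
        out.append(vocab.id_to_char[nxt])
        logits, state = _step(model, nxt, state)
    return "".join(out)


# ---------------------------------------------------------------------------
# checkpointing

def save_charlm(model: CharLM, vocab: CharVocab, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **model.params)
    meta = {
        "config": {k: getattr(model.cfg, k) for k in (
            "embed_dim", "units", "dropout", "batch_size", "epochs",
            "window", "cell", "learning_rate", "clip_norm", "seed")},
        "vocab_size": model.vocab_size,
        "vocab": list(vocab.id_to_char),
    }
    (d / "metadata.json").write_text(json.dumps(meta, ensure_ascii=False, indent=1), encoding="utf-8")


def load_charlm(directory) -> Tuple[CharLM, CharVocab]:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text(encoding="utf-8"))
    cfg = CharLMConfig(**meta["config"])
    with np.load(d / "weights.npz") as z:
        params = {k: z[k] for k in z.files}
    chars = meta["vocab"]
    vocab = CharVocab(char_to_id={c: i for i, c in enumerate(chars)}, id_to_char=tuple(chars))
    return CharLM(cfg=cfg, vocab_size=meta["vocab_size"], params=params), vocab
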