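import numpy as np
import pytest

from dialogforge import builtin_fixture, generate_corpus, GenerationConfig
from dialogforge.charlm import CharLMConfig, build_vocab, init_charlm, make_windows, train_charlm
from dialogforge.embeddings import VectorTable


@pytest.fixture(scope="session")
def fixture_ontology():
    return builtin_fixture()


@pytest.fixture(scope="session")
def small_corpus(fixture_ontology):
    """A small generated corpus (30 utterances per intent) shared by
    feature/labeling/evaluation tests."""
    cfg = GenerationConfig(budgets={i.name: 30 for i in fixture_ontology.intents})
    return generate_corpus(fixture_ontology, cfg, seed=11)


@pytest.fixture()
def toy_table():
    """Hand-set 2-D vectors for exact similarity arithmetic."""
    vecs = {
        "pressure": np.array([1.0, 0.0]),
        "tension": np.array([1.0, 0.1]),
        "noodles": np.array([0.0, 1.0]),
        "supper": np.array([-1.0, 0.0]),
    }
    return VectorTable(dimension=2, vectors=vecs)


# --- shared overfit character model ---------------------------------------

OVERFIT_WINDOW = 40

_BASE_UTTS = [
    "add pressure with 103 mmhg",
    "clean dentures with water",
    "help to use urinals at loo",
    "prepare noodles for supper",
    "wash mouth with dish soap",
    "set temperature with 39 c",
    "make udon for breakfasts",
    "change nappies at bathroom",
    "brush teeth with the floss",
    "put this weight on records",
]


def overfit_utterances():
    """Ten distinct-prefix utterances padded to exactly window length - 1
    characters so stride-L windows align with utterance starts (the
    sampling-time zero state then matches the training condition)."""
    out = []
    for u in _BASE_UTTS:
        assert len(u) < OVERFIT_WINDOW
        out.append(u + "-" * (OVERFIT_WINDOW - 1 - len(u)))
    return out


@pytest.fixture(scope="session")
def overfit_lm():
    """Character model memorising ten fixed utterances (desk profile
    units, no dropout, enough epochs to overfit)."""
    utts = overfit_utterances()
    text = "".join(u + "\n" for u in utts) * 8
    vocab = build_vocab(text)
    windows = make_windows(text, vocab, L=OVERFIT_WINDOW)
    cfg = CharLMConfig.desk(epochs=120, dropout=0.0, seed=3, learning_rate=3e-3)
    model = init_charlm(vocab.size, cfg)
    model, history = train_charlm(windows, cfg, model=model)
    return {
        "utterances": utts,
        "text": text,
        "vocab": vocab,
        "windows": windows,
        "model": model,
        "history": history,
        "config": cfg,
    }
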