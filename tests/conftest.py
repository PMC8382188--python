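import numpy as np
import pytest

from kbdiffuse.encoding import TokenSettings
from kbdiffuse.store import DataItem, KnowledgeBase


@pytest.fixture
def settings():
    return TokenSettings(k=6)


@pytest.fixture
def toy_kb(settings):
    """Three-item single-collection store with IC weighting."""
    items = [
        DataItem(id="i0", title="vascular skin lesion", body="vascular lesion of the skin"),
        DataItem(id="i1", title="myocarditis", body="cardiac muscle inflammation"),
        DataItem(id="i2", title="rash", body="skin rash and lesion"),
    ]
    return KnowledgeBase.build({"main": items}, settings, c0=0.0, c1=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_items(rng, n_items, vocab_size=60, prefix="r"):
    """Random word-salad items over a small shared vocabulary."""
    vocab = [f"w{j:03d}x" for j in range(vocab_size)]
    items = []
    for i in range(n_items):
        k = int(rng.integers(3, 9))
        words = rng.choice(vocab, size=k, replace=False)
        items.append(DataItem(id=f"{prefix}{i:04d}", title="", body=" ".join(words)))
    return items
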