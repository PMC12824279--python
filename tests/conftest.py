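import numpy as np
import pytest

from divbench.embeddings import EmbeddingTable


@pytest.fixture
def ortho_table():
    """Seven words mapped to the standard basis of R^7 (all pairs orthogonal)."""
    words = ["river", "stone", "cloud", "piano", "ember", "fox", "lens"]
    vocab = {w: np.eye(7)[i] for i, w in enumerate(words)}
    return EmbeddingTable(vocab=vocab, dim=7, name="ortho"), words


@pytest.fixture
def random_table():
    """A 60-word random unit-vector table at dim 32 (seeded)."""
    rng = np.random.default_rng(2024)
    vocab = {}
    for i in range(60):
        v = rng.standard_normal(32)
        vocab[f"word{chr(97 + i // 26)}{chr(97 + i % 26)}"] = v / np.linalg.norm(v)
    return EmbeddingTable(vocab=vocab, dim=32, name="random")


@pytest.fixture
def glove_file(tmp_path):
    """A tiny plain-text vector file in the GloVe dialect."""
    path = tmp_path / "vectors.txt"
    path.write_text(
        "river 0.1 0.2 0.3 0.4\n"
        "stone -0.5 0.25 0.0 1.0\n"
        "cloud 1.0 -1.0 0.5 -0.25\n",
        encoding="utf-8",
    )
    return path
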