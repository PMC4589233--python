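import pytest

import homotype as ht


@pytest.fixture(scope="session")
def scoring():
    return ht.ScoringScheme()


@pytest.fixture(scope="session")
def family4():
    """Small flat 4-class dataset: 6 members per class, clearly separable."""
    cfg = ht.SynthConfig(n_classes=4, per_class=6, seq_length=150,
                         intra_identity=0.9, inter_identity_max=0.5, seed=7)
    ds, manifest = ht.generate(cfg)
    return ds, manifest


@pytest.fixture(scope="session")
def family11():
    """Hierarchical 11-class dataset emulating the curated subtype set at
    reduced scale: 6 subfamilies per class, 12 members per class, length
    240.  The per-class subfamily redundancy matters: identity reduction
    keeps several representatives per class, as it does on real subtype
    data, so non-stratified folds cannot isolate an entire class."""
    cfg = ht.SynthConfig(n_classes=11, per_class=12, seq_length=240,
                         intra_identity=0.9, inter_identity_max=0.5,
                         n_subfamilies=6, subfamily_identity=0.6, seed=11)
    ds, manifest = ht.generate(cfg)
    return ds, manifest


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file, return its path."""

    def _write(text, name="test.fa"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
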