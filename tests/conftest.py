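import numpy as np
import pytest

from coicap import Lineage, ReferenceDB, TaxonRecord, generate_synthetic_clade


def make_record(accession, species, genus=None, family="unknown",
                order="unknown", sequence="ACGT" * 40):
    genus = genus or species.split("_")[0]
    return TaxonRecord(accession, Lineage(species, genus, family, order), sequence)


@pytest.fixture
def tiny_db():
    """Three records, two species, two genera (one species unnamed)."""
    rng = np.random.default_rng(7)
    seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 200)) for _ in range(3)]
    return ReferenceDB([
        make_record("AC001", "Brycon_amazonicus", "Brycon", sequence=seqs[0]),
        make_record("AC002", "Brycon_amazonicus", "Brycon", sequence=seqs[1]),
        make_record("AC003", "Pimelodus_sp._3", "Pimelodus", sequence=seqs[2]),
    ])


@pytest.fixture
def lineage_db():
    """A database with a full four-rank hierarchy for LCA tests.

    Two orders; order O1 holds families F1 (genera G1: s1, s2; G2: s3) and
    F2 (G3: s4); order O2 holds family F3 (G4: s5).
    """
    rows = [
        ("L001", "s1", "G1", "F1", "O1"),
        ("L002", "s2", "G1", "F1", "O1"),
        ("L003", "s3", "G2", "F1", "O1"),
        ("L004", "s4", "G3", "F2", "O1"),
        ("L005", "s5", "G4", "F3", "O2"),
    ]
    rng = np.random.default_rng(11)
    return ReferenceDB([
        make_record(acc, sp, g, f, o,
                    sequence="".join("ACGT"[c] for c in rng.integers(0, 4, 300)))
        for acc, sp, g, f, o in rows
    ])


@pytest.fixture(scope="session")
def clade20():
    """20-species synthetic clade at mean pairwise divergence 0.2."""
    return generate_synthetic_clade(20, seq_length=650,
                                    mean_pairwise_distance=0.2, seed=42)
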