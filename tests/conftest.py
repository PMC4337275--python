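import pytest

from portrace.curation import ReferenceAnchor, simple_substitution_matrix
from portrace.records import SequenceRecord
from portrace.simulate import simulate_por_family


def make_toy_reference() -> str:
    """A 90-residue reference with motifs at known positions and no
    spurious motif residues anywhere else.  The background is aperiodic so
    pairwise alignments against it have a unique optimal register."""
    import random

    rng = random.Random(20240917)
    seq = [rng.choice("LVISERTANQDFHMPW") for _ in range(90)]  # no G/Y/K/C
    # Rossman G-x-x-x-G-x-G at 10..16
    seq[9] = "G"
    seq[13] = "G"
    seq[15] = "G"
    # Y-x-x-x-K at 40..44
    seq[39] = "Y"
    seq[43] = "K"
    # catalytic C at 60
    seq[59] = "C"
    return "".join(seq)


TOY_ROSSMAN, TOY_TYR, TOY_LYS, TOY_CYS = 10, 40, 44, 60


@pytest.fixture(scope="session")
def toy_anchor() -> ReferenceAnchor:
    reference = SequenceRecord(
        id="ref", residues=make_toy_reference(),
        taxon_name="reference cyanobacterium", lineage="cyanobacteria",
    )
    return ReferenceAnchor(reference, TOY_ROSSMAN, TOY_TYR, TOY_LYS, TOY_CYS)


@pytest.fixture(scope="session")
def unit_matrix():
    """Match +1 / mismatch -1 substitution table."""
    return simple_substitution_matrix()


@pytest.fixture(scope="session")
def labelled_family():
    """A simulated POR family with decoys and fragments, plus truth."""
    return simulate_por_family(
        groups=(("cyanobacteria", 10), ("stramenopile", 10)),
        n_decoys=10,
        n_fragments=3,
        seed=11,
    )
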