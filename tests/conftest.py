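import numpy as np
import pytest

from san1score import AnnotatedProtein, ProteinRecord, ResidueTrack

AA = "ACDEFGHIKLMNPQRSTVWY"
NON_K = AA.replace("K", "")


def make_annotated(
    pid: str,
    sequence: str,
    disorder,
    anchor,
) -> AnnotatedProtein:
    """Assemble an AnnotatedProtein from raw arrays."""
    return AnnotatedProtein(
        record=ProteinRecord(id=pid, sequence=sequence),
        disorder=ResidueTrack(pid, "disorder_consensus", np.asarray(disorder, float)),
        anchor=ResidueTrack(pid, "anchor", np.asarray(anchor, float)),
    )


def random_sequence(rng: np.random.Generator, n: int, k_freq: float = 0.058) -> str:
    letters = [
        "K" if rng.random() < k_freq else NON_K[rng.integers(0, len(NON_K))]
        for _ in range(n)
    ]
    return "".join(letters)


def random_annotated(rng: np.random.Generator, n: int, pid: str = "p") -> AnnotatedProtein:
    """A protein with i.i.d. uniform tracks — deliberately rougher than the
    generator's smooth tracks, to stress run/window logic."""
    return make_annotated(pid, random_sequence(rng, n), rng.random(n), rng.random(n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160225)
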