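import numpy as np
import pytest

from phagenet import HostRecord, IncidenceMatrix


@pytest.fixture
def toy_matrix() -> IncidenceMatrix:
    """Hosts a, b, c; phage p1 infects a+b, phage p2 infects a+c."""
    return IncidenceMatrix(
        np.array([[1, 1], [1, 0], [0, 1]]), ["a", "b", "c"], ["p1", "p2"]
    )


@pytest.fixture
def toy_hosts() -> list[HostRecord]:
    return [
        HostRecord("a", "S. aureus", "Epidermidis-Aureus", "CoPS", "human", "resistant"),
        HostRecord("b", "S. epidermidis", "Epidermidis-Aureus", "CoNS", "veterinary", "susceptible"),
        HostRecord("c", "S. sciuri", "Sciuri", "CoNS", "environmental", "MDR"),
    ]


def random_binary(rng: np.random.Generator, max_side: int = 8, min_side: int = 2,
                  density: float | None = None) -> np.ndarray:
    n = int(rng.integers(min_side, max_side + 1))
    m = int(rng.integers(min_side, max_side + 1))
    p = density if density is not None else rng.uniform(0.1, 0.9)
    return (rng.random((n, m)) < p).astype(np.int8)


def as_matrix(a: np.ndarray) -> IncidenceMatrix:
    return IncidenceMatrix(
        a,
        [f"h{i}" for i in range(a.shape[0])],
        [f"p{j}" for j in range(a.shape[1])],
    )
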