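import random

import pytest
from hypothesis import settings

from glycomark import builtin_profiles, builtin_structure
from glycomark.topology import GlycanTopology, Residue

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def raa():
    """The arabinose-containing structure, as analyzed by NMR (alditol)."""
    return builtin_structure("Raa")


@pytest.fixture(scope="session")
def raa_free():
    """Same structure with a free reducing end (the MALDI species)."""
    return builtin_structure("Raa", reduced=False)


@pytest.fixture(scope="session")
def now():
    """The xylose-containing structure (free reducing end)."""
    return builtin_structure("Now")


@pytest.fixture(scope="session")
def muxf3():
    return builtin_structure("MUXF3")


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


_IDENTITIES = ["Man", "Glc", "GlcNAc", "Ara", "Xyl", "Fuc"]


def random_topology(seed: int, max_residues: int = 6) -> GlycanTopology:
    """Small random glycan tree for property tests (deterministic per seed)."""
    rng = random.Random(seed)
    n = rng.randint(1, max_residues)

    def build(budget: list[int]) -> Residue:
        budget[0] -= 1
        identity = rng.choice(_IDENTITIES)
        free = [2, 3, 4, 6]
        rng.shuffle(free)
        children = []
        while budget[0] > 0 and free and rng.random() < 0.6:
            pos = free.pop()
            child = build(budget)
            children.append(
                Residue(
                    identity=child.identity,
                    ring=child.ring,
                    anomeric=child.anomeric,
                    o_methyl=child.o_methyl,
                    link_to_parent=pos,
                    children=child.children,
                )
            )
        methyl = frozenset(rng.sample(free, k=1)) if free and rng.random() < 0.3 else frozenset()
        return Residue(
            identity=identity,
            ring=rng.choice("pf"),
            anomeric=rng.choice("ab"),
            o_methyl=methyl,
            children=tuple(children),
        )

    root = build([n])
    return GlycanTopology(root=root, reduced=rng.random() < 0.5, name=f"random-{seed}")
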