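import numpy as np
import pytest

import morphplace as mp


@pytest.fixture
def quartet_tree():
    return mp.read_newick("((A,B),(C,D));")


@pytest.fixture
def cherry_tree():
    return mp.read_newick("(A,B);")


def make_matrix(taxa, columns, *, ordered=(), kinds=None):
    """Build a CharacterMatrix from per-character {taxon: cell} dicts.

    Discrete cells may be ints (singleton state), sets, MISSING/INAPPLICABLE;
    floats are continuous.
    """
    defs, cells = [], [[] for _ in taxa]
    for j, col in enumerate(columns):
        kind = kinds[j] if kinds else (
            "continuous" if any(isinstance(v, float) for v in col.values())
            else "discrete")
        if kind == "continuous":
            defs.append(mp.CharacterDefinition(char_id=j + 1, kind="continuous",
                                               n_states=0))
            for i, t in enumerate(taxa):
                cells[i].append(col.get(t, mp.MISSING))
        else:
            observed = set()
            for v in col.values():
                if isinstance(v, int):
                    observed.add(v)
                elif isinstance(v, (set, frozenset)):
                    observed |= set(v)
            n_states = max(2, max(observed) + 1 if observed else 2)
            defs.append(mp.CharacterDefinition(
                char_id=j + 1, kind="discrete", n_states=n_states,
                ordered=(j + 1) in ordered and n_states >= 3))
            for i, t in enumerate(taxa):
                v = col.get(t, mp.MISSING)
                if isinstance(v, int):
                    v = frozenset({v})
                elif isinstance(v, (set, frozenset)):
                    v = frozenset(v)
                cells[i].append(v)
    return mp.CharacterMatrix(taxa=list(taxa), definitions=defs, cells=cells)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def small_fixture():
    """40-tip seeded synthetic fixture with planted markers (session-wide)."""
    return mp.default_study_fixture(seed=11, n_extant=40, n_discrete=30,
                                    n_continuous=2, n_planted=6, n_fossils=3)
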