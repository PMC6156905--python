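import numpy as np
import pytest

from famethyl.pedigree import FEMALE, MALE, Individual, Pedigree


def make_random_pedigree(seed: int, max_members: int = 12) -> Pedigree:
    """Random valid single-family pedigree for property tests.

    Starts from 2-4 founders and repeatedly adds either a founder or a child
    of a random existing male/female pair, so arbitrary depth, half-sibs and
    (occasionally) inbreeding loops arise.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_members + 1))
    inds = [
        Individual("I1", "F1", sex=MALE),
        Individual("I2", "F1", sex=FEMALE),
    ]
    for k in range(3, n + 1):
        males = [i.iid for i in inds if i.sex == MALE]
        females = [i.iid for i in inds if i.sex == FEMALE]
        sex = MALE if rng.random() < 0.5 else FEMALE
        if rng.random() < 0.35 or not males or not females:
            inds.append(Individual(f"I{k}", "F1", sex=sex))
        else:
            fa = males[int(rng.integers(len(males)))]
            mo = females[int(rng.integers(len(females)))]
            inds.append(Individual(f"I{k}", "F1", father=fa, mother=mo, sex=sex))
    return Pedigree(inds)


@pytest.fixture(scope="session")
def three_generation_pedigree() -> Pedigree:
    """Grandparents -> parents -> grandchild toy pedigree."""
    return Pedigree(
        [
            Individual("gpa", "F1", sex=MALE),
            Individual("gma", "F1", sex=FEMALE),
            Individual("dad", "F1", father="gpa", mother="gma", sex=MALE),
            Individual("uncle", "F1", father="gpa", mother="gma", sex=MALE),
            Individual("mom", "F1", sex=FEMALE),
            Individual("kid", "F1", father="dad", mother="mom", sex=FEMALE),
        ]
    )
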