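import numpy as np
import pandas as pd
import pytest

from sadige.pedigree import Pedigree
from sadige.sad import CrossSADSpec, PolyFn, SADSpec, TimeGrid


@pytest.fixture
def grid3():
    return TimeGrid((1, 2, 3))


@pytest.fixture
def grid5():
    return TimeGrid((1, 2, 3, 4, 5))


@pytest.fixture
def sad1_const():
    """SAD1 with constant theta = 0.5 and unit innovation variance."""
    return SADSpec((PolyFn((0.5,)),), PolyFn((0.0,)))


def random_sad_spec(rng: np.random.Generator, max_order=2, max_degree=2):
    """Random admissible SAD spec with bounded coefficients."""
    order = int(rng.integers(0, max_order + 1))
    fns = []
    for _ in range(order):
        deg = int(rng.integers(0, max_degree + 1))
        fns.append(PolyFn(tuple(rng.uniform(-0.4, 0.4, deg + 1))))
    lv_deg = int(rng.integers(0, max_degree + 1))
    lv = PolyFn(tuple(rng.uniform(-0.3, 0.3, lv_deg + 1)))
    return SADSpec(tuple(fns), lv)


def random_cross_spec(rng: np.random.Generator):
    deg = int(rng.integers(0, 2))
    return CrossSADSpec(
        random_sad_spec(rng, max_order=1),
        random_sad_spec(rng, max_order=1),
        PolyFn(tuple(rng.uniform(-0.5, 0.5, deg + 1))),
    )


@pytest.fixture
def toy_pedigree():
    """3 generations: 4 founders, 2 full-sib parents, 2 grandkids."""
    frame = pd.DataFrame(
        {
            "animal": ["f1", "f2", "f3", "f4", "p1", "p2", "k1", "k2"],
            "sire": [0, 0, 0, 0, "f1", "f3", "p1", "p1"],
            "dam": [0, 0, 0, 0, "f2", "f4", "p2", "p2"],
        }
    )
    return Pedigree.from_frame(frame)


def toy_cage_records(
    rng: np.random.Generator,
    n_cages: int = 3,
    cage_size: int = 8,
    weeks=(1,),
):
    """Small phenotype table: complete cages, arbitrary ADG values."""
    rows = []
    a = 0
    for c in range(n_cages):
        for _ in range(cage_size):
            for w in weeks:
                rows.append(
                    {
                        "animal": f"a{a}",
                        "group": f"c{c}",
                        "week": w,
                        "adg": float(rng.normal(35.0, 8.0)),
                    }
                )
            a += 1
    return pd.DataFrame(rows)


def founder_pedigree(animals):
    n = len(animals)
    return Pedigree(
        tuple(animals),
        np.full(n, -1, dtype=np.int64),
        np.full(n, -1, dtype=np.int64),
    )
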