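import numpy as np
import pandas as pd
import pytest

from diffindex import TimeCourse


@pytest.fixture
def worked_course() -> TimeCourse:
    """The hand-solvable 3-stage course: X = (0,0,0),(1,0,0),(1,1,0) in a
    4-gene space; its co-bisector is v=(1,1,0,0) with c=1."""
    X = pd.DataFrame(
        {"t0": [0, 0, 0, 0], "t1": [1, 0, 0, 0], "t2": [1, 1, 0, 0]},
        index=["pA", "pB", "pC", "pD"],
        dtype=float,
    )
    return TimeCourse(values=X)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20110101)


def random_course(rng: np.random.Generator, n: int, t: int) -> TimeCourse:
    vals = pd.DataFrame(
        rng.normal(size=(n, t)),
        index=[f"G{i:04d}" for i in range(n)],
        columns=[f"t{j}" for j in range(t)],
    )
    return TimeCourse(values=vals)


@pytest.fixture
def tsv_matrix(tmp_path):
    """Write a small probe x sample TSV and return its path and frame."""
    frame = pd.DataFrame(
        {"S1": [1.0, 3.0, 7.0], "S2": [2.0, 2.0, 2.0]},
        index=pd.Index(["P1", "P2", "P3"], name="probe_id"),
    )
    path = tmp_path / "matrix.tsv"
    frame.to_csv(path, sep="\t")
    return path, frame
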