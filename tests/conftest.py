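import numpy as np
import pandas as pd
import pytest

from nsum import (
    GeneralSurveyTable,
    KnownSubpopulation,
    RDSTable,
    RRTDesign,
    StudyFrame,
    SyntheticTruth,
    default_frame,
)

# printed study-region constants reused across tests
T_PAPER = 4_531_429
E0_PAPER = 302_251
ADULT_POP_PAPER = 2_820_541


@pytest.fixture(scope="session")
def paper_frame() -> StudyFrame:
    """48 in-band subpopulations whose sizes sum exactly to the published e0."""
    sizes = [6297] * 47 + [E0_PAPER - 47 * 6297]
    known = tuple(
        KnownSubpopulation(label=f"L{i + 1:02d}", size=s) for i, s in enumerate(sizes)
    )
    frame = StudyFrame(t=T_PAPER, adult_pop=ADULT_POP_PAPER, known=known)
    assert frame.e0 == E0_PAPER
    return frame


@pytest.fixture(scope="session")
def small_frame() -> StudyFrame:
    known = (
        KnownSubpopulation("a", 1000),
        KnownSubpopulation("b", 1500),
        KnownSubpopulation("c", 2000),
    )
    return StudyFrame(t=1_000_000, adult_pop=700_000, known=known)


@pytest.fixture(scope="session")
def design() -> RRTDesign:
    return RRTDesign(p1=0.8, p2=0.2)


@pytest.fixture(scope="session")
def synth_frame() -> StudyFrame:
    return default_frame(seed=1)


@pytest.fixture(scope="session")
def truth(synth_frame) -> SyntheticTruth:
    """Truth tuned so Monte-Carlo error is small relative to the quantities tested."""
    return SyntheticTruth(
        frame=synth_frame,
        N_H=45_000,
        c_true=120.0,
        delta_true=0.75,
        tau_true=0.9,
        mu_unrelated=2.0,
        nonresponse_rate=0.05,
    )


def make_general_table(row_sums, labels=("a", "b", "c"), answered=None,
                       rrt_group=None, rrt_answer=None):
    """Tiny general-survey table whose first name column carries the row sums."""
    n = len(row_sums)
    df = pd.DataFrame({"id": [f"g{i}" for i in range(n)]})
    df["name_" + labels[0]] = np.asarray(row_sums, dtype=float)
    for lab in labels[1:]:
        df["name_" + lab] = 0.0
    df["rrt_group"] = rrt_group if rrt_group is not None else ([1, 2] * n)[:n]
    df["rrt_answer"] = rrt_answer if rrt_answer is not None else 0.0
    df["answered"] = answered if answered is not None else True
    return GeneralSurveyTable(df)


def make_rds_table(known, aware, recruiter=None, wave=None):
    """Tiny RDS table from explicit count matrices (n_rows x n_names)."""
    known = np.asarray(known)
    aware = np.asarray(aware)
    n, k = known.shape
    ids = [f"r{i}" for i in range(n)]
    df = pd.DataFrame({
        "id": ids,
        "recruiter_id": recruiter if recruiter is not None else [None] * n,
        "wave": wave if wave is not None else [0] * n,
    })
    for j in range(k):
        df[f"name_x{j}"] = known[:, j]
    for j in range(k):
        df[f"aware_x{j}"] = aware[:, j]
    return RDSTable(df)
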