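import numpy as np
import pytest

from leadmap import (
    Actor,
    AdviceMatrix,
    CohortConfig,
    LikertBlock,
    NominationRecord,
    Role,
    StyleRating,
    SurveyDataset,
    generate_cohort,
)


def make_matrix(edges, actor_roles, boundary="full"):
    """AdviceMatrix from {(src, dst): freq} over [(id, Role), ...]."""
    ids = tuple(a for a, _ in actor_roles)
    roles = tuple(r for _, r in actor_roles)
    idx = {a: i for i, a in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=int)
    for (s, t), f in edges.items():
        m[idx[s], idx[t]] = f
    return AdviceMatrix(actor_ids=ids, roles=roles, matrix=m, boundary=boundary)


def full_block(actor_id, score=4):
    return LikertBlock(actor_id=actor_id, item_scores=(score,) * 8)


@pytest.fixture
def tiny_ds():
    """Four actors (1 preceptor, 3 residents) with a small advice network."""
    actors = [
        Actor("p1", Role.PRECEPTOR, "female", ">10", ">10"),
        Actor("a", Role.R1, "male", "<1", "<1"),
        Actor("b", Role.R2, "female", "1-2", "1-2"),
        Actor("c", Role.R2, "male", "1-2", "<1"),
    ]
    nominations = [
        NominationRecord("a", "p1", 3),
        NominationRecord("a", "b", 2),
        NominationRecord("b", "c", 1),
        NominationRecord("c", "p1", 2),
    ]
    likert = [full_block("p1", 5), full_block("a", 2), full_block("b", 4), full_block("c", 3)]
    ratings = [
        StyleRating(
            "p1",
            (("relational", 1), ("transformational", 2), ("adaptive", 3), ("resilient", 4)),
        )
    ]
    return SurveyDataset(actors=actors, nominations=nominations, likert=likert, ratings=ratings)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=1))
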