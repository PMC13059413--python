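import dataclasses

import numpy as np
import pytest

from leadmap import (
    Actor,
    CohortConfig,
    LikertBlock,
    NominationRecord,
    Quadrant,
    Role,
    StyleRating,
    SurveyDataset,
    boundary_sensitivity,
    build_adjacency,
    classify,
    classify_cohort,
    compute_cutoffs,
    compute_style_weights,
    distribution_table,
    generate_cohort,
    resident_shares,
    restrict_boundary,
    score_cohort,
    share_pct,
)
from leadmap.errors import ValidationError
from leadmap.leadership_scoring import LeadershipProfile
from leadmap.quadrant_mapping import Cutoffs, QuadrantAssignment
from leadmap.survey_ingest import RESIDENT_ROLES

STUDY_CUTOFFS = Cutoffs(lai_cutoff=4.20, lad_cutoff=2.22, boundary="full")


def lp(actor_id, lad, lai, role=Role.R1):
    return LeadershipProfile(
        actor_id=actor_id,
        role=role,
        lad_score=lad,
        lad_components={},
        lad_sd=0.0,
        lai_defined=lai is not None,
        lai_score=lai,
    )


def test_cutoffs_are_sample_means():
    cut = compute_cutoffs([lp("a", 2.0, 4.0), lp("b", 3.0, 5.0)], "full")
    assert cut.lai_cutoff == pytest.approx(4.5)
    assert cut.lad_cutoff == pytest.approx(2.5)


def test_cutoffs_ignore_lai_ineligible_for_lai_axis():
    cut = compute_cutoffs([lp("a", 2.0, 4.0), lp("b", 4.0, None)], "full")
    assert cut.lai_cutoff == pytest.approx(4.0)
    assert cut.lad_cutoff == pytest.approx(3.0)


def test_cutoffs_require_scores():
    with pytest.raises(ValidationError):
        compute_cutoffs([lp("a", 2.0, None)], "full")


@pytest.mark.parametrize(
    "lai,lad,expected",
    [
        (4.20, 2.22, Quadrant.ESTABLISHED),  # boundary-inclusive: at-cutoff is high
        (3.0, 1.5, Quadrant.LATENT),
        (4.5, 2.0, Quadrant.ASPIRATIONAL),
        (3.5, 3.0, Quadrant.HUMBLE),
        (5.0, 5.0, Quadrant.ESTABLISHED),
    ],
)
def test_classification_rules(lai, lad, expected):
    a = classify(lp("x", lad, lai), STUDY_CUTOFFS)
    assert a.quadrant is expected


def test_classify_requires_lai():
    with pytest.raises(ValidationError):
        classify(lp("x", 3.0, None), STUDY_CUTOFFS)
    assignments = classify_cohort([lp("a", 3.0, 4.5), lp("b", 3.0, None)], STUDY_CUTOFFS)
    assert [a.actor_id for a in assignments] == ["a"]


def test_share_pct_half_up_one_decimal():
    assert share_pct(7, 46) == 15.2
    assert share_pct(18, 46) == 39.1
    assert share_pct(68, 77) == 88.3
    assert share_pct(35, 46) == 76.1


def assignments_with_counts(counts):
    """Build one resident assignment per label according to counts."""
    out = []
    i = 0
    for label, n in counts.items():
        for _ in range(n):
            out.append(
                QuadrantAssignment(f"r{i}", Role.R1, Quadrant(label), 4.0, 2.0, STUDY_CUTOFFS)
            )
            i += 1
    return out


def test_resident_shares_match_hand_arithmetic():
    assignments = assignments_with_counts(
        {"established": 7, "humble": 11, "aspirational": 10, "latent": 18}
    )
    shares = resident_shares(assignments)
    assert shares == {
        "established": 15.2, "humble": 23.9, "aspirational": 21.7, "latent": 39.1,
    }


def test_distribution_counts_partition():
    assignments = assignments_with_counts({"established": 3, "latent": 2})
    table = distribution_table(assignments)
    assert table["n"].sum() == 5
    assert table.loc["established", "pct_of_all"] == 60.0
    assert table.loc["humble", "n"] == 0


def test_single_quadrant_distribution():
    assignments = assignments_with_counts({"humble": 4})
    table = distribution_table(assignments)
    assert table.loc["humble", "pct_of_all"] == 100.0
    assert table.loc["established", "pct_of_all"] == 0.0


def test_increasing_lad_moves_only_upward():
    """With fixed cutoffs, raising LAD can only move latent->humble or
    aspirational->established."""
    allowed = {
        Quadrant.LATENT: {Quadrant.LATENT, Quadrant.HUMBLE},
        Quadrant.ASPIRATIONAL: {Quadrant.ASPIRATIONAL, Quadrant.ESTABLISHED},
        Quadrant.HUMBLE: {Quadrant.HUMBLE},
        Quadrant.ESTABLISHED: {Quadrant.ESTABLISHED},
    }
    rng = np.random.default_rng(4)
    for _ in range(200):
        lai, lad = rng.uniform(1, 5, size=2)
        before = classify(lp("x", lad, lai), STUDY_CUTOFFS).quadrant
        after = classify(lp("x", lad + rng.uniform(0, 2), lai), STUDY_CUTOFFS).quadrant
        assert after in allowed[before]


def test_boundary_sensitivity_conserves_residents(default_cohort):
    ds, _ = default_cohort
    w = compute_style_weights(ds.ratings)
    tt = boundary_sensitivity(ds, w)
    assert tt.counts.values.sum() == 46
    assert len(tt.per_resident) == 46
    assert 0.0 <= tt.stability_share <= 1.0
    assert tt.stability_share == pytest.approx(np.trace(tt.counts.values) / 46)


def test_boundary_sensitivity_full_equals_direct_run(default_cohort):
    ds, _ = default_cohort
    w = compute_style_weights(ds.ratings)
    tt = boundary_sensitivity(ds, w)
    A = build_adjacency(ds)
    profiles = score_cohort(ds, A, w)
    direct = classify_cohort(profiles, compute_cutoffs(profiles, A.boundary))
    assert {a.actor_id: a.quadrant for a in tt.full_assignments} == {
        a.actor_id: a.quadrant for a in direct
    }


def test_lai_values_frozen_across_boundaries(default_cohort):
    ds, _ = default_cohort
    w = compute_style_weights(ds.ratings)
    tt = boundary_sensitivity(ds, w)
    full_lai = {a.actor_id: a.lai for a in tt.full_assignments}
    for a in tt.residents_assignments:
        assert a.lai == pytest.approx(full_lai[a.actor_id])
    # but the cut-offs are boundary-specific
    assert tt.residents_assignments[0].cutoffs != tt.full_assignments[0].cutoffs


def test_residents_only_cutoffs_differ_with_preceptor_attraction():
    ds, _ = generate_cohort(CohortConfig(preceptor_attraction=3.0, seed=6))
    w = compute_style_weights(ds.ratings)
    tt = boundary_sensitivity(ds, w)
    assert tt.residents_assignments[0].cutoffs.lad_cutoff != pytest.approx(
        tt.full_assignments[0].cutoffs.lad_cutoff
    )


def test_detached_preceptors_with_clear_cut_residents_are_stable():
    """When preceptors are network isolates and residents sit far from both
    cut-offs, removing preceptors relabels nobody."""
    actors = [Actor(f"p{i}", Role.PRECEPTOR) for i in range(2)]
    actors += [Actor(f"r{i}", Role.R1) for i in range(6)]
    # r0, r1 heavily nominated; r5 isolated; others in between
    noms = []
    for src in range(2, 8):
        for dst in (0, 1):
            if src != dst + 2:
                noms.append(NominationRecord(f"r{src - 2}", f"r{dst}", 3))
    likert = [LikertBlock(f"r{i}", (5,) * 8 if i < 3 else (1,) * 8) for i in range(6)]
    likert += [LikertBlock(f"p{i}", (3,) * 8) for i in range(2)]
    ratings = [
        StyleRating(
            "p0",
            (("relational", 1), ("transformational", 2), ("adaptive", 3), ("resilient", 4)),
        )
    ]
    ds = SurveyDataset(actors=actors, nominations=noms, likert=likert, ratings=ratings)
    tt = boundary_sensitivity(ds, compute_style_weights(ratings))
    assert tt.stability_share == 1.0


def test_residents_only_dataset_restriction_is_identity(default_cohort):
    """On a dataset that already contains only residents, restricting the
    boundary changes nothing about scores or labels."""
    ds, _ = default_cohort
    resident_ids = {a.actor_id for a in ds.actors if a.role is not Role.PRECEPTOR}
    res_ds = SurveyDataset(
        actors=[a for a in ds.actors if a.actor_id in resident_ids],
        nominations=[
            n for n in ds.nominations
            if n.source_id in resident_ids and n.target_id in resident_ids
        ],
        likert=[b for b in ds.likert if b.actor_id in resident_ids],
        ratings=ds.ratings,
    )
    w = compute_style_weights(ds.ratings)
    A = build_adjacency(res_ds)
    R = restrict_boundary(A, RESIDENT_ROLES)
    p1 = score_cohort(res_ds, A, w)
    p2 = score_cohort(res_ds, R, w)
    assert {p.actor_id: p.lad_score for p in p1} == pytest.approx(
        {p.actor_id: p.lad_score for p in p2}
    )
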