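"""Four-quadrant leadership classification and boundary sensitivity.

Actors are placed on a plane with the self-assessed LAI score on one axis
and the network-derived LAD score on the other.  The sample means of the
two scores serve as cut-offs; a score exactly at its cut-off counts as
"high" (the quadrant definitions use >=).  The quadrants:

* **established** — high LAI, high LAD: self-identified and network-granted;
* **humble** — low LAI, high LAD: central in the advice network without
  seeing themselves as leaders;
* **aspirational** — high LAI, low LAD: claim leadership not (yet) granted
  by peers;
* **latent** — low LAI, low LAD.

The boundary sensitivity analysis reruns the whole network pipeline on the
residents-only subnetwork — centralities and their Likert rescaling, LAD,
and both cut-offs are recomputed over residents, while each resident's LAI
value is unchanged (self-perception does not depend on who is in the
network) — and tabulates quadrant transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .advice_network import (
    BOUNDARY_RESIDENTS,
    AdviceMatrix,
    build_adjacency,
    restrict_boundary,
)
from .errors import ValidationError
from .leadership_scoring import LeadershipProfile, StyleWeights, round_half_up, score_cohort
from .survey_ingest import RESIDENT_ROLES, Role, SurveyDataset

logger = logging.getLogger("leadmap")


class Quadrant(str, Enum):
    ESTABLISHED = "established"
    HUMBLE = "humble"
    ASPIRATIONAL = "aspirational"
    LATENT = "latent"


QUADRANT_ORDER = [Quadrant.ESTABLISHED, Quadrant.HUMBLE, Quadrant.ASPIRATIONAL, Quadrant.LATENT]


@dataclass(frozen=True)
class Cutoffs:
    """Sample-mean cut-offs separating 'low' from 'high' scores."""

    lai_cutoff: float
    lad_cutoff: float
    boundary: str


@dataclass(frozen=True)
class QuadrantAssignment:
    actor_id: str
    role: Role
    quadrant: Quadrant
    lai: float
    lad: float
    cutoffs: Cutoffs


@dataclass
class TransitionTable:
    """Per-resident quadrant labels under both boundaries, with aggregates."""

    per_resident: pd.DataFrame  # actor_id, full_quadrant, residents_only_quadrant
    counts: pd.DataFrame  # 4x4, rows = full boundary, cols = residents-only
    stability_share: float
    full_assignments: list[QuadrantAssignment]
    residents_assignments: list[QuadrantAssignment]


def compute_cutoffs(profiles: list[LeadershipProfile], boundary: str) -> Cutoffs:
    """Mean LAI over LAI-eligible actors; mean LAD over all boundary actors."""
    lads = [p.lad_score for p in profiles]
    lais = [p.lai_score for p in profiles if p.lai_defined]
    if len(lads) < 2 or len(lais) < 1:
        raise ValidationError("cut-offs need at least 2 scored actors and 1 LAI-eligible actor")
    return Cutoffs(
        lai_cutoff=float(np.mean(lais)), lad_cutoff=float(np.mean(lads)), boundary=boundary
    )


def classify(profile: LeadershipProfile, cutoffs: Cutoffs) -> QuadrantAssignment:
    """Quadrant label for one actor; scores at a cut-off classify as high."""
    if not profile.lai_defined:
        raise ValidationError(f"actor {profile.actor_id!r} has no LAI score; cannot classify")
    high_lai = profile.lai_score >= cutoffs.lai_cutoff
    high_lad = profile.lad_score >= cutoffs.lad_cutoff
    if high_lai and high_lad:
        quadrant = Quadrant.ESTABLISHED
    elif high_lad:
        quadrant = Quadrant.HUMBLE
    elif high_lai:
        quadrant = Quadrant.ASPIRATIONAL
    else:
        quadrant = Quadrant.LATENT
    return QuadrantAssignment(
        actor_id=profile.actor_id,
        role=profile.role,
        quadrant=quadrant,
        lai=float(profile.lai_score),
        lad=float(profile.lad_score),
        cutoffs=cutoffs,
    )


def classify_cohort(
    profiles: list[LeadershipProfile], cutoffs: Cutoffs
) -> list[QuadrantAssignment]:
    """Classify every LAI-eligible profile; ineligible actors are logged and skipped."""
    out = []
    for p in profiles:
        if not p.lai_defined:
            logger.info("actor %s excluded from quadrant mapping (no LAI)", p.actor_id)
            continue
        out.append(classify(p, cutoffs))
    return out


def share_pct(numerator: int, denominator: int) -> float:
    """Percentage share displayed to 1 decimal, rounded half-up."""
    if denominator == 0:
        raise ValidationError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, 1)


def distribution_table(assignments: list[QuadrantAssignment]) -> pd.DataFrame:
    """Quadrant x role counts with within-quadrant and within-role percentages."""
    if not assignments:
        raise ValidationError("no assignments to tabulate")
    roles_present = sorted({a.role for a in assignments}, key=lambda r: r.value)
    n_total = len(assignments)
    rows = []
    for q in QUADRANT_ORDER:
        in_q = [a for a in assignments if a.quadrant is q]
        row: dict = {
            "quadrant": q.value,
            "n": len(in_q),
            "pct_of_all": share_pct(len(in_q), n_total),
        }
        for role in roles_present:
            n_role_q = sum(1 for a in in_q if a.role is role)
            row[f"n_{role.value}"] = n_role_q
            row[f"pct_within_quadrant_{role.value}"] = (
                share_pct(n_role_q, len(in_q)) if in_q else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("quadrant")


def resident_shares(assignments: list[QuadrantAssignment]) -> dict[str, float]:
    """Quadrant shares computed over residents only (counts / n_residents, 1 dp)."""
    residents = [a for a in assignments if a.role in RESIDENT_ROLES]
    if not residents:
        raise ValidationError("no residents among assignments")
    return {
        q.value: share_pct(sum(1 for a in residents if a.quadrant is q), len(residents))
        for q in QUADRANT_ORDER
    }


def boundary_sensitivity(
    ds: SurveyDataset,
    w: StyleWeights,
    closeness_variant: str = "harmonic",
) -> TransitionTable:
    """Full-vs-residents-only quadrant comparison for every resident.

    Both runs execute the complete pipeline (adjacency -> centralities with
    boundary-specific rescaling -> LAD -> cut-offs -> classification); the
    style weights come from preceptor ratings and are shared between runs.
    """
    roles = ds.roles()
    if not any(r is Role.PRECEPTOR for r in roles.values()):
        raise ValidationError("boundary sensitivity requires preceptors in the dataset")
    if not any(r in RESIDENT_ROLES for r in roles.values()):
        raise ValidationError("boundary sensitivity requires residents in the dataset")

    A_full = build_adjacency(ds)
    full_profiles = score_cohort(ds, A_full, w, closeness_variant)
    full_cut = compute_cutoffs(full_profiles, A_full.boundary)
    full_assign = classify_cohort(full_profiles, full_cut)

    A_res = restrict_boundary(A_full, RESIDENT_ROLES)
    res_profiles = score_cohort(ds, A_res, w, closeness_variant)
    res_cut = compute_cutoffs(res_profiles, BOUNDARY_RESIDENTS)
    res_assign = classify_cohort(res_profiles, res_cut)

    full_by_id = {a.actor_id: a for a in full_assign}
    res_by_id = {a.actor_id: a for a in res_assign}
    resident_ids = [a.actor_id for a in res_assign if a.actor_id in full_by_id]

    records = [
        {
            "actor_id": aid,
            "full_quadrant": full_by_id[aid].quadrant.value,
            "residents_only_quadrant": res_by_id[aid].quadrant.value,
        }
        for aid in resident_ids
    ]
    per_resident = pd.DataFrame(records)
    labels = [q.value for q in QUADRANT_ORDER]
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for rec in records:
        counts.loc[rec["full_quadrant"], rec["residents_only_quadrant"]] += 1
    n_stable = int(np.trace(counts.values))
    stability = n_stable / len(records) if records else float("nan")
    return TransitionTable(
        per_resident=per_resident,
        counts=counts,
        stability_share=stability,
        full_assignments=full_assign,
        residents_assignments=res_assign,
    )
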