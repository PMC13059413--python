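"""Style importance weights and the LAD / LAI composite scores.

Preceptors rank each of the four leadership styles from 1 (most important)
to 4 (least important).  Each rank is mapped to a reciprocal value —
1 -> 1.00, 2 -> 0.50, 3 -> 0.33, 4 -> 0.25 — the values are summed per
style across raters, and the sums are normalized by their grand total into
weights w_i with sum(w_i) = 1.  The published rounded constant 0.33 (not
1/3) is used deliberately, so that aggregated totals match hand-computed
tables.

Leadership-as-Done (LAD) for actor k is the composite Leadership Score

    LS_k = sum_i w_i * n_ik

where n_ik is the rescaled centrality proxy of style i.  Leadership-as-
Imagined (LAI) replaces n_ik by the mean of the two Likert self-rating
items of style i.  Both scores are convex combinations of values in
[1, 5], hence themselves in [1, 5].  The per-score dispersion is the sample
standard deviation (n-1 denominator) of the four weighted components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .advice_network import AdviceMatrix
from .centrality_engine import CentralityProfile, centrality_profiles
from .errors import ValidationError
from .survey_ingest import STYLES, LikertBlock, StyleRating, SurveyDataset

#: Reciprocal-rank values for importance ranks 1..4, as printed constants.
RANK_VALUES: dict[int, float] = {1: 1.00, 2: 0.50, 3: 0.33, 4: 0.25}


@dataclass(frozen=True)
class StyleWeights:
    """Normalized importance weights for the four styles."""

    weights: dict[str, float]
    aggregated_scores: dict[str, float]
    grand_total: float

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"style weights must sum to 1, got {total}")
        if any(not 0.0 < w < 1.0 for w in self.weights.values()):
            raise ValidationError("each style weight must lie in (0, 1)")

    def __getitem__(self, style: str) -> float:
        return self.weights[style]

    @classmethod
    def from_aggregated(cls, aggregated: dict[str, float]) -> "StyleWeights":
        if set(aggregated) != set(STYLES):
            raise ValidationError(f"aggregated scores must cover styles {STYLES}")
        grand = sum(aggregated.values())
        if grand <= 0:
            raise ValidationError("grand total of aggregated scores must be positive")
        return cls(
            weights={s: aggregated[s] / grand for s in STYLES},
            aggregated_scores={s: float(aggregated[s]) for s in STYLES},
            grand_total=float(grand),
        )

    @classmethod
    def equal(cls) -> "StyleWeights":
        return cls.from_aggregated({s: 1.0 for s in STYLES})


def compute_style_weights(ratings: list[StyleRating]) -> StyleWeights:
    """Aggregate preceptor importance ratings into normalized weights."""
    if not ratings:
        raise ValidationError("cannot derive style weights from an empty rating list")
    aggregated = {s: 0.0 for s in STYLES}
    for rating in ratings:
        for style, rank in rating.as_dict().items():
            if rank not in RANK_VALUES:
                raise ValidationError(
                    f"rating {rank!r} by {rating.rater_id!r} outside 1..4"
                )
            aggregated[style] += RANK_VALUES[rank]
    return StyleWeights.from_aggregated(aggregated)


@dataclass
class LeadershipProfile:
    """Per-actor LAD and (when defined) LAI scores with component dispersions."""

    actor_id: str
    role: object
    lad_score: float
    lad_components: dict[str, float]
    lad_sd: float
    lai_defined: bool = False
    lai_score: float | None = None
    lai_components: dict[str, float] | None = None
    lai_sd: float | None = None


def _component_sd(components: dict[str, float]) -> float:
    vals = np.array(list(components.values()), dtype=float)
    return float(vals.std(ddof=1))


def lad_score(profile: CentralityProfile, w: StyleWeights) -> tuple[float, dict[str, float], float]:
    """Weighted sum of the style-keyed rescaled centralities (Leadership Score)."""
    components = {}
    for style in STYLES:
        if style not in profile.rescaled:
            raise ValidationError(f"profile of {profile.actor_id!r} lacks rescaled metric for {style!r}")
        components[style] = w[style] * profile.rescaled[style]
    score = sum(components.values())
    return score, components, _component_sd(components)


def lai_score(block: LikertBlock, w: StyleWeights) -> tuple[float, dict[str, float], float]:
    """Weighted sum of per-style Likert item means (self-assessed leadership)."""
    means = block.style_means()
    components = {style: w[style] * means[style] for style in STYLES}
    score = sum(components.values())
    return score, components, _component_sd(components)


def score_cohort(
    ds: SurveyDataset,
    A: AdviceMatrix,
    w: StyleWeights,
    closeness_variant: str = "harmonic",
) -> list[LeadershipProfile]:
    """One :class:`LeadershipProfile` per actor of ``A``'s boundary.

    LAD is computed for every actor of the matrix; LAI only for actors with
    a complete 8-item Likert block.
    """
    blocks = {b.actor_id: b for b in ds.likert}
    out: list[LeadershipProfile] = []
    for cp in centrality_profiles(A, closeness_variant=closeness_variant):
        lad, lad_comp, lad_sd = lad_score(cp, w)
        profile = LeadershipProfile(
            actor_id=cp.actor_id,
            role=cp.role,
            lad_score=lad,
            lad_components=lad_comp,
            lad_sd=lad_sd,
        )
        block = blocks.get(cp.actor_id)
        if block is not None and block.complete:
            lai, lai_comp, lai_sd = lai_score(block, w)
            profile.lai_defined = True
            profile.lai_score = lai
            profile.lai_components = lai_comp
            profile.lai_sd = lai_sd
        out.append(profile)
    return out


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Display rounding: round half away from zero at ``ndigits`` decimals."""
    factor = 10**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
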