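"""Synthetic sociometric cohorts with planted leadership structure.

The generator emulates an internal-medicine advice-seeking survey: 68
physicians by default (22 preceptors, 22 first-year, 23 second-year and one
third-year resident), a dense directed advice network whose in-ties
concentrate on a planted subset of hubs (and, more weakly, on preceptors),
Likert self-ratings whose actor-level means can be coupled to network
position with a configurable correlation, and a preceptor panel rating the
relative importance of the four leadership styles.

The planted truth records, per actor, whether it is a hub and which
leadership quadrant it is expected to occupy when self-perception is
perfectly aligned with network position; downstream recovery tests compare
the pipeline's classification against this truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .survey_ingest import (
    STYLES,
    Actor,
    LikertBlock,
    NominationRecord,
    Role,
    StyleRating,
    SurveyDataset,
)

# Demographic band frequencies of the emulated cohort (counts out of 68).
_GENDER_P = {"male": 42 / 68, "female": 26 / 68}
_YEARS_DOCTOR_P = {"<1": 11, "1-2": 21, "2-3": 7, "3-5": 5, "6-10": 5, ">10": 19}
_YEARS_SPECIALTY_P = {"<1": 29, "1-2": 21, "2-3": 1, "3-5": 3, "6-10": 5, ">10": 9}

#: Canonical importance ordering used to concentrate synthetic preceptor
#: ratings: relational most important, resilient least.
_CANONICAL_RANK = {"relational": 1, "transformational": 2, "adaptive": 3, "resilient": 4}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Tie probabilities follow a planted-hub Bernoulli digraph: each ordered
    pair (j, k), j != k, receives a tie with probability
    ``base_tie_prob * hub_tie_multiplier^[k is hub] * preceptor_attraction^[k is preceptor]``,
    capped at 0.99.  ``alignment_rho`` couples the rank of an actor's
    planted incoming-tie propensity to the rank of its realized Likert mean.
    """

    n_preceptors: int = 22
    n_R1: int = 22
    n_R2: int = 23
    n_R3: int = 1
    base_tie_prob: float = 0.06
    hub_fraction: float = 0.2
    hub_tie_multiplier: float = 6.0
    preceptor_attraction: float = 1.5
    frequency_model: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.20, 4: 0.12, 5: 0.08}
    )
    alignment_rho: float = 0.5
    likert_noise_sd: float = 0.5
    rating_concentration: float = 1.0
    n_raters: int = 19
    seed: int = 0

    @property
    def n_actors(self) -> int:
        return self.n_preceptors + self.n_R1 + self.n_R2 + self.n_R3

    def validate(self) -> None:
        if min(self.n_preceptors, self.n_R1, self.n_R2, self.n_R3) < 0:
            raise ConfigurationError("role counts must be nonnegative")
        if self.n_actors < 2:
            raise ConfigurationError("cohort needs at least 2 actors")
        if not 0.0 <= self.base_tie_prob < 1.0:
            raise ConfigurationError("base_tie_prob must lie in [0, 1)")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ConfigurationError("hub_fraction must lie in [0, 1]")
        if self.hub_tie_multiplier < 1.0 or self.preceptor_attraction < 1.0:
            raise ConfigurationError("tie multipliers must be >= 1")
        if not -1.0 <= self.alignment_rho <= 1.0:
            raise ConfigurationError("alignment_rho must lie in [-1, 1]")
        freqs = self.frequency_model
        if not freqs or any(p < 0 for p in freqs.values()) or sum(freqs.values()) <= 0:
            raise ConfigurationError("frequency_model must be a nonempty categorical")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        if "frequency_model" in data:
            data["frequency_model"] = {int(k): float(v) for k, v in data["frequency_model"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PlantedTruth:
    """Per-actor generative ground truth for recovery tests."""

    actor_ids: list[str]
    hub: dict[str, bool]
    propensity: dict[str, float]
    likert_mean: dict[str, float]
    high_self: dict[str, bool]
    expected_quadrant: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "actor_id": self.actor_ids,
                "hub": [self.hub[a] for a in self.actor_ids],
                "expected_quadrant": [self.expected_quadrant[a] for a in self.actor_ids],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _expected_quadrant(is_hub: bool, is_high_self: bool) -> str:
    if is_hub and is_high_self:
        return "established"
    if is_hub:
        return "humble"
    if is_high_self:
        return "aspirational"
    return "latent"


def _draw_band(rng: np.random.Generator, weights: dict[str, float]) -> str:
    labels = list(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def generate_cohort(config: CohortConfig) -> tuple[SurveyDataset, PlantedTruth]:
    """Generate a synthetic :class:`SurveyDataset` and its planted truth.

    Fully reproducible: identical ``config`` (including ``seed``) yields an
    identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    role_blocks = [
        (Role.PRECEPTOR, "P", config.n_preceptors),
        (Role.R1, "R1.", config.n_R1),
        (Role.R2, "R2.", config.n_R2),
        (Role.R3, "R3.", config.n_R3),
    ]
    actor_ids: list[str] = []
    roles: list[Role] = []
    for role, prefix, count in role_blocks:
        for i in range(1, count + 1):
            actor_ids.append(f"{prefix}{i}")
            roles.append(role)
    n = len(actor_ids)

    actors = [
        Actor(
            actor_id=aid,
            role=role,
            gender=_draw_band(rng, _GENDER_P),
            years_doctor_band=_draw_band(rng, _YEARS_DOCTOR_P),
            years_specialty_band=_draw_band(rng, _YEARS_SPECIALTY_P),
        )
        for aid, role in zip(actor_ids, roles)
    ]

    # Planted hubs: a fixed-size random subset across all roles.
    n_hubs = int(round(config.hub_fraction * n))
    hub_idx = set(rng.choice(n, size=n_hubs, replace=False).tolist()) if n_hubs else set()
    is_hub = np.array([i in hub_idx for i in range(n)])
    is_preceptor = np.array([r is Role.PRECEPTOR for r in roles])

    # Incoming-tie probability of each target, capped below 1.
    p_in = np.full(n, config.base_tie_prob)
    p_in[is_hub] *= config.hub_tie_multiplier
    p_in[is_preceptor] *= config.preceptor_attraction
    p_in = np.minimum(p_in, 0.99)

    # Continuous centrality propensity: incoming odds with a small
    # multiplicative jitter to break ties within hub/role classes.
    propensity = p_in * np.exp(rng.normal(0.0, 0.05, size=n))

    # Directed ties: Bernoulli per ordered pair, frequency per realized tie.
    freq_values = sorted(config.frequency_model)
    freq_p = np.array([config.frequency_model[v] for v in freq_values], dtype=float)
    freq_p = freq_p / freq_p.sum()
    uniforms = rng.random((n, n))
    nominations: list[NominationRecord] = []
    for j in range(n):
        for k in range(n):
            if j == k or uniforms[j, k] >= p_in[k]:
                continue
            freq = int(freq_values[rng.choice(len(freq_values), p=freq_p)])
            nominations.append(NominationRecord(actor_ids[j], actor_ids[k], freq))

    # Likert blocks: draw item blocks around latent actor means, then
    # rank-couple realized block means to centrality propensity.
    mu = np.clip(rng.normal(4.2, 0.55, size=n), 1.0, 5.0)
    items = np.clip(np.rint(rng.normal(mu[:, None], config.likert_noise_sd, size=(n, 8))), 1, 5)
    items = items.astype(int)
    realized = items.mean(axis=1)

    rho = config.alignment_rho
    prop_rank = np.argsort(np.argsort(propensity)).astype(float)
    z = (prop_rank - prop_rank.mean()) / (prop_rank.std() or 1.0)
    coupling = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(size=n)
    # Actor with the r-th largest coupling score receives the block with the
    # r-th largest realized mean.
    block_order = np.argsort(realized, kind="stable")
    actor_order = np.argsort(coupling, kind="stable")
    assigned = np.empty(n, dtype=int)
    assigned[actor_order] = block_order
    likert = [
        LikertBlock(actor_id=actor_ids[i], item_scores=tuple(items[assigned[i]].tolist()))
        for i in range(n)
    ]
    actor_mean = realized[assigned]

    # Preceptor importance ratings: independent 1-4 draws per style, ties
    # allowed, concentrated around the canonical ordering.
    preceptor_ids = [aid for aid, r in zip(actor_ids, roles) if r is Role.PRECEPTOR]
    n_raters = min(config.n_raters, len(preceptor_ids))
    rater_ids = (
        sorted(rng.choice(preceptor_ids, size=n_raters, replace=False).tolist())
        if n_raters
        else []
    )
    ratings: list[StyleRating] = []
    for rater in rater_ids:
        vals = []
        for style in STYLES:
            c = _CANONICAL_RANK[style]
            logits = -config.rating_concentration * np.abs(np.arange(1, 5) - c)
            p = np.exp(logits)
            vals.append((style, int(rng.choice(4, p=p / p.sum()) + 1)))
        ratings.append(StyleRating(rater_id=rater, ratings=tuple(vals)))

    # The self-perception axis involves no network inference: the expected
    # "high self-rating" flag is the LAI classification itself — weighted
    # style means (under this cohort's elicited weights) at or above the
    # cohort mean.  Recovery tests therefore probe the network (LAD) axis.
    from .leadership_scoring import StyleWeights, compute_style_weights, lai_score

    w = compute_style_weights(ratings) if ratings else StyleWeights.equal()
    lai_by_id = {b.actor_id: lai_score(b, w)[0] for b in likert}
    lai_cut = float(np.mean(list(lai_by_id.values()))) if lai_by_id else 0.0
    truth = PlantedTruth(
        actor_ids=list(actor_ids),
        hub={aid: bool(is_hub[i]) for i, aid in enumerate(actor_ids)},
        propensity={aid: float(propensity[i]) for i, aid in enumerate(actor_ids)},
        likert_mean={aid: float(actor_mean[i]) for i, aid in enumerate(actor_ids)},
        high_self={aid: bool(lai_by_id[aid] >= lai_cut) for aid in actor_ids},
        expected_quadrant={
            aid: _expected_quadrant(bool(is_hub[i]), bool(lai_by_id[aid] >= lai_cut))
            for i, aid in enumerate(actor_ids)
        },
    )

    dataset = SurveyDataset(
        actors=actors,
        nominations=nominations,
        likert=likert,
        ratings=ratings,
        ingest_log={"synthetic": True, "seed": config.seed},
    )
    return dataset, truth


def expected_quadrants(truth: PlantedTruth) -> dict[str, str]:
    """Deterministic actor -> expected-quadrant mapping from the planted truth."""
    return dict(truth.expected_quadrant)
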