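"""Pipeline orchestration, artifact writers and figure rendering.

`run_pipeline` executes ingest (or synthesis) -> network -> weights ->
scores -> quadrants (-> boundary sensitivity), writing CSV/JSON artifacts,
a run log and figures into an output directory.  A failing stage aborts the
run with the stage name and removes the partial outputs it wrote.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .advice_network import (
    BOUNDARY_FULL,
    BOUNDARY_RESIDENTS,
    AdviceMatrix,
    build_adjacency,
    restrict_boundary,
    write_edge_list,
    write_graphml,
    write_ucinet_dl,
)
from .errors import ConfigurationError, PipelineError, ValidationError
from .leadership_scoring import (
    LeadershipProfile,
    StyleWeights,
    compute_style_weights,
    round_half_up,
    score_cohort,
)
from .quadrant_mapping import (
    Cutoffs,
    QuadrantAssignment,
    TransitionTable,
    boundary_sensitivity,
    classify_cohort,
    compute_cutoffs,
    distribution_table,
    resident_shares,
)
from .survey_ingest import (
    RESIDENT_ROLES,
    Role,
    SurveyDataset,
    read_survey,
    validate_dataset,
)
from .synthetic_cohort import CohortConfig, generate_cohort

logger = logging.getLogger("leadmap")

BOUNDARIES = (BOUNDARY_FULL, BOUNDARY_RESIDENTS, "both")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: the two survey CSV paths, or a
    synthetic :class:`CohortConfig`.
    """

    survey_path: str | None = None
    ratings_path: str | None = None
    cohort: CohortConfig | None = None
    boundary: str = "both"
    closeness_variant: str = "harmonic"
    binarize: bool = True
    out_dir: str = "leadmap_out"
    seed: int | None = None
    display_precision: int = 2

    def validate(self) -> None:
        has_files = self.survey_path is not None and self.ratings_path is not None
        has_cohort = self.cohort is not None
        if has_files == has_cohort:
            raise ConfigurationError(
                "exactly one of (survey_path & ratings_path, cohort) must be given"
            )
        if self.boundary not in BOUNDARIES:
            raise ConfigurationError(f"boundary must be one of {BOUNDARIES}")
        if self.closeness_variant not in ("harmonic", "freeman"):
            raise ConfigurationError("closeness_variant must be 'harmonic' or 'freeman'")


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the artifact paths written."""

    dataset: SurveyDataset
    weights: StyleWeights
    adjacency: AdviceMatrix
    profiles: list[LeadershipProfile]
    cutoffs: Cutoffs
    assignments: list[QuadrantAssignment]
    transition: TransitionTable | None
    summary: dict
    files: list[Path] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Survey dataset writer (inverse of survey_ingest.read_survey)


def write_survey(ds: SurveyDataset, survey_path: str | Path, ratings_path: str | Path) -> None:
    """Write a dataset in the two-table CSV schema read by ``read_survey``."""
    blocks = {b.actor_id: b for b in ds.likert}
    noms: dict[str, list[str]] = {a.actor_id: [] for a in ds.actors}
    for rec in ds.nominations:
        noms[rec.source_id].append(f"{rec.target_id}:{rec.frequency}")
    rows = []
    for a in ds.actors:
        row = {
            "actor_id": a.actor_id,
            "role": a.role.value,
            "gender": a.gender,
            "years_doctor_band": a.years_doctor_band,
            "years_specialty_band": a.years_specialty_band,
            "consent": "Yes",
            "nominations": ";".join(noms[a.actor_id]),
        }
        block = blocks.get(a.actor_id)
        for i in range(1, 9):
            row[f"likert_{i}"] = (
                block.item_scores[i - 1] if block and i <= len(block.item_scores) else ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(survey_path, index=False)

    rating_rows = [
        {"rater_id": r.rater_id, **r.as_dict()} for r in ds.ratings
    ]
    pd.DataFrame(
        rating_rows, columns=["rater_id", "relational", "transformational", "adaptive", "resilient"]
    ).to_csv(ratings_path, index=False)


# ---------------------------------------------------------------------------
# Artifact writers


def _profiles_frame(profiles: list[LeadershipProfile], precision: int) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "actor_id": p.actor_id,
                "role": p.role.value if isinstance(p.role, Role) else str(p.role),
                "lai": round_half_up(p.lai_score, precision) if p.lai_defined else "",
                "lai_sd": round_half_up(p.lai_sd, precision) if p.lai_defined else "",
                "lad": round_half_up(p.lad_score, precision),
                "lad_sd": round_half_up(p.lad_sd, precision),
                "lai_defined": p.lai_defined,
            }
        )
    return pd.DataFrame(rows)


def _weights_frame(w: StyleWeights) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "style": list(w.weights),
            "aggregated_score": [w.aggregated_scores[s] for s in w.weights],
            "weight": [w.weights[s] for s in w.weights],
        }
    )


def render_scatter(
    assignments: list[QuadrantAssignment], cutoffs: Cutoffs, path: str | Path
) -> Path:
    """LAI (x) vs LAD (y) scatter with quadrant reference lines at the cut-offs."""
    if not assignments:
        raise ValidationError("cannot render a scatter without classified actors")
    fig, ax = plt.subplots(figsize=(6, 6))
    markers = {True: ("s", "tab:blue", "preceptors"), False: ("o", "tab:red", "residents")}
    for is_preceptor, (marker, color, label) in markers.items():
        pts = [a for a in assignments if (a.role is Role.PRECEPTOR) == is_preceptor]
        if pts:
            ax.scatter(
                [a.lai for a in pts], [a.lad for a in pts],
                marker=marker, c=color, label=label, alpha=0.75, edgecolors="k", linewidths=0.3,
            )
    ax.axvline(cutoffs.lai_cutoff, color="grey", ls="--", lw=1)
    ax.axhline(cutoffs.lad_cutoff, color="grey", ls="--", lw=1)
    ax.set_xlim(1, 5)
    ax.set_ylim(1, 5)
    ax.set_xlabel("LAI (self-assessed leadership)")
    ax.set_ylabel("LAD (leadership score from advice network)")
    ax.set_title(f"Leadership quadrants ({cutoffs.boundary} boundary)")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def render_sociogram(A: AdviceMatrix, path: str | Path, seed: int = 0) -> Path:
    """Directed sociogram: square markers for preceptors, circles for residents."""
    if A.n == 0 or not A.matrix.any():
        raise ValidationError("cannot render an empty network")
    g = A.to_digraph(binary=True)
    pos = nx.spring_layout(g, seed=seed)
    fig, ax = plt.subplots(figsize=(7, 7))
    preceptors = [a for a, r in zip(A.actor_ids, A.roles) if r is Role.PRECEPTOR]
    residents = [a for a, r in zip(A.actor_ids, A.roles) if r is not Role.PRECEPTOR]
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.2, arrowsize=6)
    if preceptors:
        nx.draw_networkx_nodes(
            g, pos, nodelist=preceptors, node_shape="s", node_color="tab:blue", node_size=90, ax=ax
        )
    if residents:
        nx.draw_networkx_nodes(
            g, pos, nodelist=residents, node_shape="o", node_color="tab:red", node_size=90, ax=ax
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the configured pipeline end to end and write all artifacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, **kwargs) -> Path:
        p = out / name
        df.to_csv(p, **kwargs)
        written.append(p)
        return p

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    stage = "setup"
    try:
        stage = "ingest"
        if cfg.cohort is not None:
            cohort = cfg.cohort
            if cfg.seed is not None:
                cohort = dataclasses.replace(cohort, seed=cfg.seed)
            ds, truth = generate_cohort(cohort)
            truth.to_csv(out / "planted_truth.csv")
            written.append(out / "planted_truth.csv")
        else:
            ds = read_survey(cfg.survey_path, cfg.ratings_path)
        report = validate_dataset(ds)
        if not report.is_clean:
            logger.warning("validation report not clean: %s", report)

        stage = "network"
        A_full = build_adjacency(ds)
        write_edge_list(A_full, out / "edges_full.csv")
        write_ucinet_dl(A_full, out / "network_full.dl")
        write_graphml(A_full, out / "network_full.graphml")
        written += [out / "edges_full.csv", out / "network_full.dl", out / "network_full.graphml"]

        stage = "weights"
        w = compute_style_weights(ds.ratings)
        save_csv(_weights_frame(w), "style_weights.csv", index=False)

        stage = "scores"
        weighted = not cfg.binarize
        primary_boundary = cfg.boundary if cfg.boundary != "both" else BOUNDARY_FULL
        A = A_full if primary_boundary == BOUNDARY_FULL else restrict_boundary(A_full, RESIDENT_ROLES)
        profiles = score_cohort(ds, A, w, cfg.closeness_variant)
        save_csv(_profiles_frame(profiles, cfg.display_precision), "leadership_profiles.csv", index=False)

        stage = "quadrants"
        cutoffs = compute_cutoffs(profiles, A.boundary)
        assignments = classify_cohort(profiles, cutoffs)
        assign_df = pd.DataFrame(
            [
                {
                    "actor_id": a.actor_id,
                    "role": a.role.value,
                    "quadrant": a.quadrant.value,
                    "lai": round_half_up(a.lai, cfg.display_precision),
                    "lad": round_half_up(a.lad, cfg.display_precision),
                }
                for a in assignments
            ]
        )
        save_csv(assign_df, "quadrant_assignments.csv", index=False)
        save_csv(distribution_table(assignments), "quadrant_distribution.csv")
        seed = cfg.seed if cfg.seed is not None else 0
        written.append(render_scatter(assignments, cutoffs, out / "lai_lad_scatter.png"))
        written.append(render_sociogram(A_full, out / "sociogram.png", seed=seed))

        transition = None
        stability = None
        if cfg.boundary == "both":
            stage = "sensitivity"
            transition = boundary_sensitivity(ds, w, cfg.closeness_variant)
            counts = transition.counts.copy()
            counts.loc["stability_share"] = ""
            counts.iloc[-1, 0] = transition.stability_share
            save_csv(counts, "quadrant_transitions.csv")
            save_csv(transition.per_resident, "boundary_per_resident.csv", index=False)
            stability = transition.stability_share

        stage = "summary"
        quadrant_counts = assign_df["quadrant"].value_counts().to_dict()
        try:
            shares = resident_shares(assignments)
        except ValidationError:
            shares = None
        summary = {
            "boundary": cfg.boundary,
            "n_actors": len(ds.actors),
            "n_classified": len(assignments),
            "weights": w.weights,
            "cutoffs": {"lai": cutoffs.lai_cutoff, "lad": cutoffs.lad_cutoff},
            "quadrant_counts": quadrant_counts,
            "resident_shares_pct": shares,
            "stability_share": stability,
            "ingest_log": ds.ingest_log,
        }
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
        written.append(summary_path)

        return ReportBundle(
            dataset=ds,
            weights=w,
            adjacency=A,
            profiles=profiles,
            cutoffs=cutoffs,
            assignments=assignments,
            transition=transition,
            summary=summary,
            files=written,
        )
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
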