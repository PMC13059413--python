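"""Centrality metrics used as leadership-style proxies, on a 1-5 scale.

Four complementary metrics are computed on the binarized advice digraph and
mapped to leadership styles:

====================  =====================  =============================
style                 proxy metric           reading
====================  =====================  =============================
transformational      in-degree              trusted advisor
relational            betweenness            information broker
adaptive              out-closeness          rapid disseminator
resilient             in-closeness           efficient receiver
====================  =====================  =============================

Each raw metric is min-max rescaled onto [1, 5] across the actors of the
matrix's boundary, so that rescaled values are directly comparable to the
5-point Likert self-ratings.  Because the rescaling is affine, any positive
affine pre-normalization of a raw metric (e.g. dividing betweenness by
(n-1)(n-2)) leaves the rescaled values unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .advice_network import AdviceMatrix, binarize
from .errors import BoundaryError, ValidationError

logger = logging.getLogger("leadmap")

#: style -> (metric name, direction) proxy map.
STYLE_PROXIES: dict[str, str] = {
    "transformational": "in_degree",
    "relational": "betweenness",
    "adaptive": "out_closeness",
    "resilient": "in_closeness",
}

HARMONIC = "harmonic"
FREEMAN = "freeman"


@dataclass(frozen=True)
class CentralityProfile:
    """Raw and Likert-rescaled centralities of one actor."""

    actor_id: str
    role: object
    in_degree_raw: float
    betweenness_raw: float
    in_closeness_raw: float
    out_closeness_raw: float
    rescaled: dict[str, float]  # style -> value in [1, 5]


def _ordered(values: dict, A: AdviceMatrix) -> np.ndarray:
    return np.array([values[a] for a in A.actor_ids], dtype=float)


def _geodesic_graph(A: AdviceMatrix, weighted: bool) -> tuple[nx.DiGraph, str | None]:
    """Digraph plus the edge attribute to use as geodesic length.

    Default: binarized arcs of unit length.  The frequency-weighted variant
    treats a more frequent advice tie as a shorter distance (length = 1/x).
    """
    if not weighted:
        return binarize(A).to_digraph(binary=True), None
    g = A.to_digraph(binary=False)
    for _, _, data in g.edges(data=True):
        data["dist"] = 1.0 / data["weight"]
    return g, "dist"


def in_degree(A: AdviceMatrix, weighted: bool = False) -> np.ndarray:
    """Number of distinct nominators of each actor (column-wise nonzero count).

    With ``weighted=True``, the column-wise frequency sum instead.
    """
    if weighted:
        return A.matrix.sum(axis=0).astype(float)
    return (A.matrix > 0).sum(axis=0).astype(float)


def betweenness(A: AdviceMatrix, weighted: bool = False) -> np.ndarray:
    """Unnormalized directed betweenness on unit-length arcs.

    For node v: sum over ordered pairs (s, t), s != t != v, of the share of
    shortest s->t paths that pass through v; unreachable pairs contribute 0.
    """
    g, dist = _geodesic_graph(A, weighted)
    return _ordered(nx.betweenness_centrality(g, normalized=False, weight=dist), A)


def closeness(
    A: AdviceMatrix, direction: str, variant: str = HARMONIC, weighted: bool = False
) -> np.ndarray:
    """In- or out-closeness, normalized to [0, 1].

    The default harmonic variant gives node v, for ``direction="out"``,
    ``(1/(n-1)) * sum_{u != v} 1/d(v, u)`` with 1/inf = 0; ``direction="in"``
    reverses the distances.  This stays defined for actors with no incoming
    (or outgoing) paths.  The classic Freeman variant, computed on the
    reachable set with the Wasserman-Faust correction, is available for
    comparison with desktop SNA packages.
    """
    if A.n < 2:
        raise BoundaryError("closeness undefined for fewer than 2 actors")
    if direction not in ("in", "out"):
        raise ValidationError(f"direction must be 'in' or 'out', got {direction!r}")
    g, dist = _geodesic_graph(A, weighted)
    # networkx's harmonic/closeness centralities use *incoming* distances on
    # a DiGraph, so the "out" direction runs on the reversed graph.
    h = g if direction == "in" else g.reverse()
    if variant == HARMONIC:
        values = nx.harmonic_centrality(h, distance=dist)
        return _ordered(values, A) / (A.n - 1)
    if variant == FREEMAN:
        return _ordered(nx.closeness_centrality(h, distance=dist, wf_improved=True), A)
    raise ValidationError(f"unknown closeness variant {variant!r}")


def rescale_likert(raw: np.ndarray) -> np.ndarray:
    """Affine min-max rescale onto [1, 5]: ``x -> 1 + 4 (x - min)/(max - min)``.

    A constant vector maps to the mid-scale value 3 (with a logged warning)
    so that the composite score stays defined.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("cannot rescale an empty vector")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("degenerate constant metric: rescaling all %d values to 3", raw.size)
        return np.full_like(raw, 3.0)
    return 1.0 + 4.0 * (raw - lo) / (hi - lo)


def centrality_profiles(
    A: AdviceMatrix, closeness_variant: str = HARMONIC, weighted: bool = False
) -> list[CentralityProfile]:
    """All four raw metrics plus boundary-specific rescaled style values.

    Rescaling min/max are taken over the actors of ``A`` itself, so a
    residents-only matrix is rescaled within the residents-only boundary.
    """
    raw = {
        "in_degree": in_degree(A, weighted),
        "betweenness": betweenness(A, weighted),
        "out_closeness": closeness(A, "out", closeness_variant, weighted),
        "in_closeness": closeness(A, "in", closeness_variant, weighted),
    }
    rescaled = {metric: rescale_likert(vec) for metric, vec in raw.items()}
    profiles = []
    for i, (aid, role) in enumerate(zip(A.actor_ids, A.roles)):
        profiles.append(
            CentralityProfile(
                actor_id=aid,
                role=role,
                in_degree_raw=float(raw["in_degree"][i]),
                betweenness_raw=float(raw["betweenness"][i]),
                in_closeness_raw=float(raw["in_closeness"][i]),
                out_closeness_raw=float(raw["out_closeness"][i]),
                rescaled={
                    style: float(rescaled[metric][i]) for style, metric in STYLE_PROXIES.items()
                },
            )
        )
    return profiles
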