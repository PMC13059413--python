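"""Directed advice-seeking adjacency matrices and boundary restrictions.

Cell ``x[j, k]`` holds how frequently actor ``j`` sought advice from actor
``k``; the diagonal is structurally zero.  A matrix carries a boundary tag:
``full`` for the whole cohort, ``residents_only`` when restricted to the
resident roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BoundaryError, ValidationError
from .survey_ingest import RESIDENT_ROLES, Role, SurveyDataset

logger = logging.getLogger("leadmap")

BOUNDARY_FULL = "full"
BOUNDARY_RESIDENTS = "residents_only"


@dataclass(frozen=True)
class AdviceMatrix:
    """Directed nonnegative frequency matrix over an ordered actor index."""

    actor_ids: tuple[str, ...]
    roles: tuple[Role, ...]
    matrix: np.ndarray  # shape (n, n), nonnegative ints, zero diagonal
    boundary: str = BOUNDARY_FULL

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.actor_ids), len(self.actor_ids)):
            raise ValidationError("matrix dimensions must equal actor count")
        if np.any(np.diag(m) != 0):
            raise ValidationError("advice matrix must have a zero diagonal")
        if np.any(m < 0):
            raise ValidationError("advice frequencies must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.actor_ids)

    def index_of(self, actor_id: str) -> int:
        return self.actor_ids.index(actor_id)

    def to_digraph(self, binary: bool = True) -> nx.DiGraph:
        """networkx view; edge weight = frequency unless ``binary``."""
        g = nx.DiGraph()
        for aid, role in zip(self.actor_ids, self.roles):
            g.add_node(aid, role=role.value)
        rows, cols = np.nonzero(self.matrix)
        for j, k in zip(rows.tolist(), cols.tolist()):
            w = 1 if binary else int(self.matrix[j, k])
            g.add_edge(self.actor_ids[j], self.actor_ids[k], weight=w)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.actor_ids, columns=self.actor_ids)


def build_adjacency(ds: SurveyDataset) -> AdviceMatrix:
    """Assemble the full-boundary advice matrix from the nomination list.

    Duplicate (source, target) nominations are summed with a logged warning;
    the conservative merge for repeated data-entry rows.
    """
    actor_ids = tuple(ds.actor_ids)
    roles = tuple(a.role for a in ds.actors)
    index = {aid: i for i, aid in enumerate(actor_ids)}
    m = np.zeros((len(actor_ids), len(actor_ids)), dtype=int)
    n_duplicates = 0
    for rec in ds.nominations:
        if rec.source_id not in index or rec.target_id not in index:
            raise ValidationError(
                f"nomination references unknown actor: {rec.source_id} -> {rec.target_id}"
            )
        j, k = index[rec.source_id], index[rec.target_id]
        if m[j, k] != 0:
            n_duplicates += 1
        m[j, k] += rec.frequency
    if n_duplicates:
        logger.warning("summed %d duplicate nominations", n_duplicates)
    return AdviceMatrix(actor_ids=actor_ids, roles=roles, matrix=m, boundary=BOUNDARY_FULL)


def binarize(A: AdviceMatrix) -> AdviceMatrix:
    """Map every positive cell to 1; idempotent, preserves the boundary tag."""
    return replace(A, matrix=(A.matrix > 0).astype(int))


def restrict_boundary(A: AdviceMatrix, keep_roles: set[Role] | frozenset[Role]) -> AdviceMatrix:
    """Submatrix over the actors whose role is in ``keep_roles``."""
    keep_roles = frozenset(keep_roles)
    if not keep_roles:
        raise BoundaryError("keep_roles must be nonempty")
    keep = [i for i, r in enumerate(A.roles) if r in keep_roles]
    if not keep:
        raise BoundaryError(f"boundary restriction to {sorted(r.value for r in keep_roles)} is empty")
    tag = BOUNDARY_RESIDENTS if keep_roles == RESIDENT_ROLES else A.boundary
    if keep_roles == frozenset(Role):
        tag = A.boundary
    idx = np.array(keep)
    return AdviceMatrix(
        actor_ids=tuple(A.actor_ids[i] for i in keep),
        roles=tuple(A.roles[i] for i in keep),
        matrix=A.matrix[np.ix_(idx, idx)].copy(),
        boundary=tag,
    )


def tie_stats(A: AdviceMatrix) -> dict:
    """Arc counts, per-role involvement shares and binary density.

    Ties are counted as nonzero cells (binarized arcs); frequencies are kept
    separate.  The share for role ``r`` is the fraction of arcs whose source
    or target holds that role.
    """
    if A.n < 2:
        raise BoundaryError("density undefined for networks with fewer than 2 actors")
    rows, cols = np.nonzero(A.matrix)
    n_ties = len(rows)
    n_involving: dict[str, int] = {}
    share: dict[str, float] = {}
    for role in {r for r in A.roles}:
        involved = sum(
            1
            for j, k in zip(rows.tolist(), cols.tolist())
            if A.roles[j] is role or A.roles[k] is role
        )
        n_involving[role.value] = involved
        share[role.value] = involved / n_ties if n_ties else 0.0
    return {
        "n_ties": n_ties,
        "n_involving_role": n_involving,
        "share_involving_role": share,
        "density": n_ties / (A.n * (A.n - 1)),
    }


# ---------------------------------------------------------------------------
# Export / import


def write_edge_list(A: AdviceMatrix, path: str | Path) -> None:
    rows, cols = np.nonzero(A.matrix)
    df = pd.DataFrame(
        {
            "source": [A.actor_ids[j] for j in rows],
            "target": [A.actor_ids[k] for k in cols],
            "frequency": [int(A.matrix[j, k]) for j, k in zip(rows, cols)],
        }
    )
    df.to_csv(path, index=False)


def write_ucinet_dl(A: AdviceMatrix, path: str | Path) -> None:
    """Full-matrix UCINET DL export with embedded labels."""
    lines = [f"dl n={A.n} format=fullmatrix", "labels embedded", "data:"]
    lines.append(" ".join(A.actor_ids))
    for j in range(A.n):
        lines.append(A.actor_ids[j] + " " + " ".join(str(int(v)) for v in A.matrix[j]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ucinet_dl(path: str | Path, roles: dict[str, Role] | None = None) -> AdviceMatrix:
    """Parse a full-matrix DL file written by :func:`write_ucinet_dl`."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].lower().replace(",", " ").split()
    n = next(int(tok.split("=")[1]) for tok in header if tok.startswith("n="))
    data_at = next(i for i, ln in enumerate(lines) if ln.lower().startswith("data"))
    labels = lines[data_at + 1].split()
    m = np.zeros((n, n), dtype=int)
    for j, ln in enumerate(lines[data_at + 2 : data_at + 2 + n]):
        parts = ln.split()
        m[j] = [int(v) for v in parts[1:]]
    role_map = roles or {}
    resolved = tuple(role_map.get(lab, Role.R1) for lab in labels)
    return AdviceMatrix(actor_ids=tuple(labels), roles=resolved, matrix=m)


def write_graphml(A: AdviceMatrix, path: str | Path) -> None:
    nx.write_graphml(A.to_digraph(binary=False), path)
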