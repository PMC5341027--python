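"""Posterior summaries: effective groups, connectivity sites, temporal change.

These functions turn stored Gibbs draws into the quantities practitioners
report: how many groups the data support and who belongs to them, which
locations are visited by several groups (critical connectivity sites),
within-group location networks, between-period visitation-rate changes with
credible-interval significance, and origin shares for visitor data.

Group indices in all returned tables are 1-based, ordered by decreasing
posterior occupancy (the convention used after relabeling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .model import PosteriorSamples

__all__ = [
    "GroupSummary",
    "effective_groups",
    "mixed_membership_sites",
    "group_edges",
    "edge_table",
    "delta_visitation",
    "origin_shares",
    "cohort_composition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Posterior description of one effective group."""

    group: int                 # 1-based index after occupancy ordering
    occupancy: float           # posterior mean fraction of individuals
    beta_mean: float           # posterior mean stick-breaking weight
    psi_mean: np.ndarray       # posterior mean visitation-rate row
    members: tuple             # individual IDs assigned here at the posterior mode


def effective_groups(
    samples: PosteriorSamples, min_share: float = 0.01
) -> tuple[list[GroupSummary], float]:
    """Groups with non-negligible posterior occupancy, plus their coverage.

    A group is effective when its posterior mean fraction of individuals is
    at least ``min_share``.  Returns the summaries ordered by decreasing
    share and the total fraction of individuals they encompass.
    """
    if samples.n_draws == 0:
        raise InputValidationError("empty posterior sample set")
    if not 0 <= min_share < 1:
        raise InputValidationError("min_share must lie in [0, 1)")
    occ = samples.occupancy()
    beta_mean = samples.beta_mean()
    psi_mean = samples.psi_mean()
    mode = samples.mode_assignments()
    keep = np.flatnonzero(occ >= min_share) if min_share > 0 else np.flatnonzero(occ > 0)
    keep = keep[np.argsort(-occ[keep], kind="stable")]
    out = [
        GroupSummary(
            group=int(k) + 1,
            occupancy=float(occ[k]),
            beta_mean=float(beta_mean[k]),
            psi_mean=psi_mean[k],
            members=tuple(
                samples.row_labels[j] for j in np.flatnonzero(mode == k)
            ),
        )
        for k in keep
    ]
    coverage = float(occ[keep].sum())
    return out, coverage


def _group_indices(groups) -> np.ndarray:
    """Accept GroupSummary lists or 1-based indices; return 0-based indices."""
    if len(groups) == 0:
        raise InputValidationError("empty effective-group list")
    if isinstance(groups[0], GroupSummary):
        return np.asarray([g.group - 1 for g in groups])
    return np.asarray([int(g) - 1 for g in groups])


def mixed_membership_sites(
    psi_mean: np.ndarray,
    groups,
    cutoff: float = 0.02,
    col_labels=None,
) -> pd.DataFrame:
    """Classify each location as unvisited / single / mixed membership.

    A location is *mixed* when its posterior mean visitation rate exceeds
    ``cutoff`` for two or more effective groups, *single* for exactly one,
    and *unvisited* otherwise.  Mixed sites are the critical connectivity
    sites: they are where otherwise separate groups meet.
    """
    if not 0 <= cutoff < 1:
        raise InputValidationError("cutoff must lie in [0, 1)")
    psi_mean = np.asarray(psi_mean)
    idx = _group_indices(groups)
    visits = psi_mean[idx] > cutoff  # (G_eff, L)
    n_visiting = visits.sum(axis=0)
    labels = np.where(n_visiting >= 2, "mixed", np.where(n_visiting == 1, "single", "unvisited"))
    L = psi_mean.shape[1]
    col_labels = list(col_labels) if col_labels is not None else [f"loc{l}" for l in range(L)]
    return pd.DataFrame(
        {
            "location": col_labels,
            "classification": labels,
            "n_groups": n_visiting,
            "groups": [
                ",".join(str(int(idx[g]) + 1) for g in np.flatnonzero(visits[:, l]))
                for l in range(L)
            ],
        }
    )


def group_edges(
    psi_mean: np.ndarray, group: int, cutoff: float = 0.05, col_labels=None
) -> set[tuple]:
    """Within-group location network: the clique over above-cutoff sites.

    Returns all unordered location pairs whose posterior mean visitation
    rates under the (1-based) ``group`` both exceed ``cutoff``.
    """
    if not 0 <= cutoff < 1:
        raise InputValidationError("cutoff must lie in [0, 1)")
    psi_mean = np.asarray(psi_mean)
    if not 1 <= group <= psi_mean.shape[0]:
        raise InputValidationError(f"unknown group index {group}")
    L = psi_mean.shape[1]
    col_labels = list(col_labels) if col_labels is not None else [f"loc{l}" for l in range(L)]
    sites = [col_labels[l] for l in np.flatnonzero(psi_mean[group - 1] > cutoff)]
    return {tuple(sorted(pair)) for pair in combinations(sites, 2)}


def edge_table(psi_mean: np.ndarray, groups, cutoff: float = 0.05, col_labels=None) -> pd.DataFrame:
    """Edge lists for several groups, stacked into one table."""
    rows = []
    for k in _group_indices(groups) + 1:
        for a, b in sorted(group_edges(psi_mean, int(k), cutoff, col_labels)):
            rows.append({"source": a, "target": b, "group": int(k), "cutoff": cutoff})
    return pd.DataFrame(rows, columns=["source", "target", "group", "cutoff"])


def delta_visitation(
    samples_t1: PosteriorSamples,
    samples_t2: PosteriorSamples,
    level: float = 0.95,
    site_annotation: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Between-period change in visitation rate with credible intervals.

    For every (group, location) pair the posterior of
    ``delta = psi_t2 - psi_t1`` is formed by pairing draws by index (or by
    seeded independent resampling when the two chains stored different
    numbers of draws); the equal-tailed interval at ``level`` uses empirical
    percentiles, and a change is flagged significant when that interval
    excludes zero.  Both sample sets must share the group labeling — the
    second period is normally a conditional refit that froze the first
    period's assignments.
    """
    if not 0 < level < 1:
        raise InputValidationError("level must lie in (0, 1)")
    if samples_t1.col_labels != samples_t2.col_labels:
        raise InputValidationError("location labels differ between periods")
    psi1, psi2 = samples_t1.psi, samples_t2.psi
    if psi1.shape[0] == psi2.shape[0]:
        d = psi2 - psi1
    else:
        rng = np.random.default_rng(seed)
        S = max(psi1.shape[0], psi2.shape[0])
        d = (
            psi2[rng.integers(0, psi2.shape[0], size=S)]
            - psi1[rng.integers(0, psi1.shape[0], size=S)]
        )
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    mean = d.mean(axis=0)
    lo = np.percentile(d, lo_q, axis=0)
    hi = np.percentile(d, hi_q, axis=0)
    K, L = mean.shape
    labels = list(samples_t1.col_labels)
    ann = site_annotation or {}
    records = []
    for k in range(K):
        for l in range(L):
            records.append(
                {
                    "group": k + 1,
                    "location": labels[l],
                    "delta_mean": mean[k, l],
                    "lower": lo[k, l],
                    "upper": hi[k, l],
                    "significant": bool(lo[k, l] > 0 or hi[k, l] < 0),
                    "annotation": ann.get(labels[l], ""),
                }
            )
    return pd.DataFrame(records)


def origin_shares(
    psi_mean: np.ndarray,
    beta_mean: np.ndarray,
    groups,
    locations,
    col_labels=None,
) -> pd.DataFrame:
    """Estimated share of individuals originating from each location.

    For location ``l`` the share is the posterior mean weight of the group
    that visits ``l`` the most among the effective groups (argmax of the
    posterior mean visitation rate; ties go to the lowest group index, with
    a logged warning).
    """
    psi_mean = np.asarray(psi_mean)
    beta_mean = np.asarray(beta_mean)
    idx = _group_indices(groups)
    L = psi_mean.shape[1]
    col_labels = list(col_labels) if col_labels is not None else [f"loc{l}" for l in range(L)]
    pos = {c: l for l, c in enumerate(col_labels)}
    records = []
    for loc in locations:
        if loc not in pos:
            raise InputValidationError(f"unknown location label {loc!r}")
        col = psi_mean[idx, pos[loc]]
        best = np.flatnonzero(col == col.max())
        if best.size > 1:
            logger.warning("origin share tie at %r between groups %s; taking the lowest",
                           loc, (idx[best] + 1).tolist())
        k_star = int(idx[best[0]])
        records.append(
            {
                "location": loc,
                "group": k_star + 1,
                "psi": float(psi_mean[k_star, pos[loc]]),
                "share": float(beta_mean[k_star]),
            }
        )
    return pd.DataFrame(records)


def cohort_composition(
    assignments,
    attribute: dict | pd.Series,
    groups=None,
) -> pd.DataFrame:
    """Distribution of an individual-level attribute within each group.

    The attribute (e.g. year of birth, origin) is aligned to individuals by
    label; it was not part of the clustering input, so systematic
    differences between groups are emergent structure.  Categorical
    attributes yield per-category counts and fractions; numeric attributes
    a five-number summary per group.
    """
    from .model import Assignments

    if isinstance(assignments, Assignments):
        z, labels = assignments.z, assignments.labels
    else:
        z, labels = assignments
        z = np.asarray(z)
    if labels is None:
        raise InputValidationError("labelled assignments are required")
    attr = pd.Series(attribute)
    missing = [r for r in labels if r not in attr.index]
    if missing:
        raise InputValidationError(f"attribute missing for individuals: {missing[:5]}")
    values = attr.loc[list(labels)]
    df = pd.DataFrame({"group": z + 1, "value": values.to_numpy()})
    if groups is not None:
        df = df[df["group"].isin([int(g) for g in np.asarray(_group_indices(groups)) + 1])]
    if pd.api.types.is_numeric_dtype(df["value"]):
        out = df.groupby("group")["value"].describe(percentiles=[0.25, 0.5, 0.75])
        return out[["min", "25%", "50%", "75%", "max"]].reset_index()
    counts = df.groupby(["group", "value"]).size().rename("count").reset_index()
    totals = counts.groupby("group")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
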