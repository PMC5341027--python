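"""Synthetic movement-network benchmarks with known ground truth.

Datasets are drawn from the same generative model the sampler fits: each
individual belongs to one group, and its per-location observation counts
are a multinomial draw of size ``n_j`` from that group's visitation-rate
profile.  Presets construct the three benchmark designs used throughout the
test suite: two four-group networks on 50 locations differing in how many
locations are shared between groups (9 versus 27 mixed-membership sites),
and a two-period, two-community invasion design in which one community
expands onto the other community's locations in the second period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, write_counts
from .errors import InputValidationError

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "scenario_preset",
    "simulate_counts",
    "mixed_site_count",
    "PRESET_NAMES",
]

PRESET_NAMES = ("scenario1", "scenario2", "invasion_t1", "invasion_t2")

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth design for the generator.

    Parameters
    ----------
    n_locations
        Number of locations L.
    group_sizes
        Number of individuals per true group; their sum is the total J.
    true_profiles
        ``(G, L)`` matrix of true visitation rates; each row is a point on
        the simplex.
    effort
        Per-individual total observation count ``n_j``: either a single
        positive integer applied to everyone or an array of length J.
    label
        Scenario name.
    annotations
        Free-form design metadata (e.g. which locations are invaded in the
        second period of the invasion design).
    """

    n_locations: int
    group_sizes: tuple
    true_profiles: np.ndarray
    effort: object = 20
    label: str = "custom"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        profiles = np.asarray(self.true_profiles, dtype=float)
        group_sizes = tuple(int(g) for g in self.group_sizes)
        if profiles.ndim != 2 or profiles.shape != (len(group_sizes), self.n_locations):
            raise InputValidationError(
                "true_profiles must have shape (n_groups, n_locations)"
            )
        if np.any(profiles < 0):
            raise InputValidationError("true_profiles has negative entries")
        if np.any(np.abs(profiles.sum(axis=1) - 1.0) > 1e-9):
            raise InputValidationError("each true_profiles row must sum to 1")
        if any(g < 1 for g in group_sizes):
            raise InputValidationError("all group sizes must be >= 1")
        unreachable = np.flatnonzero(profiles.sum(axis=0) <= 0)
        if unreachable.size:
            # legal (those columns stay zero) but usually a design mistake
            logging.getLogger(__name__).warning(
                "locations %s are unreachable under every group",
                unreachable.tolist(),
            )
        object.__setattr__(self, "true_profiles", profiles)
        object.__setattr__(self, "group_sizes", group_sizes)
        effort = self.effort
        efforts = self.effort_vector()
        if np.any(efforts <= 0):
            j = int(np.flatnonzero(efforts <= 0)[0])
            raise InputValidationError(f"individual {j} has non-positive effort")
        object.__setattr__(self, "effort", effort)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.group_sizes))

    def effort_vector(self) -> np.ndarray:
        """Total observation count for every individual, length J."""
        if np.isscalar(self.effort):
            return np.full(self.n_individuals, int(self.effort), dtype=np.int64)
        eff = np.asarray(self.effort, dtype=np.int64)
        if eff.shape != (self.n_individuals,):
            raise InputValidationError("effort vector length must equal total individuals")
        return eff

    def true_assignments(self) -> np.ndarray:
        """Block assignment: the first J_1 individuals are group 0, etc."""
        return np.repeat(np.arange(self.n_groups), self.group_sizes)


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated count matrix together with its generating truth."""

    counts: CountMatrix
    true_assignments: np.ndarray
    spec: ScenarioSpec
    seed: int

    def write(self, out_prefix: str) -> tuple[str, str]:
        """Write counts and a truth table as comma-delimited text files."""
        counts_path = f"{out_prefix}_counts.csv"
        truth_path = f"{out_prefix}_truth.csv"
        write_counts(self.counts, counts_path)
        pd.DataFrame(
            {
                "individual": list(self.counts.row_labels),
                "true_group": self.true_assignments + 1,
            }
        ).to_csv(truth_path, index=False)
        return counts_path, truth_path


def simulate_counts(
    spec: ScenarioSpec, seed: int, random_assignment: bool = False
) -> SimulatedDataset:
    """Draw a count matrix from the generative model.

    Group membership is assigned deterministically in blocks by default so
    the realised group sizes match the design exactly; with
    ``random_assignment=True`` each individual's group is instead drawn from
    the categorical distribution proportional to the design group sizes.
    Identical ``(spec, seed)`` pairs yield bit-identical datasets.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise InputValidationError("seed must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    efforts = spec.effort_vector()
    if random_assignment:
        weights = np.asarray(spec.group_sizes, float)
        z = rng.choice(spec.n_groups, size=spec.n_individuals, p=weights / weights.sum())
    else:
        z = spec.true_assignments()
    rows = np.empty((spec.n_individuals, spec.n_locations), dtype=np.int64)
    for j in range(spec.n_individuals):
        rows[j] = rng.multinomial(efforts[j], spec.true_profiles[z[j]])
    counts = CountMatrix(
        rows,
        tuple(f"ind{j}" for j in range(spec.n_individuals)),
        tuple(f"loc{l}" for l in range(spec.n_locations)),
    )
    return SimulatedDataset(counts=counts, true_assignments=z, spec=spec, seed=int(seed))


def mixed_site_count(spec: ScenarioSpec, threshold: float = 0.0) -> int:
    """Number of locations used by two or more groups.

    A location counts as mixed-membership when its true visitation rate
    exceeds ``threshold`` under at least two groups.
    """
    if not 0 <= threshold < 1:
        raise InputValidationError("threshold must lie in [0, 1)")
    return int(np.sum((spec.true_profiles > threshold).sum(axis=0) >= 2))


def _profiles_from_supports(supports: list[list[int]], L: int) -> np.ndarray:
    """Uniform profile over each group's designed locations."""
    G = len(supports)
    psi = np.zeros((G, L))
    for g, sites in enumerate(supports):
        psi[g, sites] = 1.0 / len(sites)
    return psi


def _overlap_preset(
    label: str,
    singles_per_group: list[int],
    mixed_groups: list[tuple],
    n_per_group: int,
    effort,
) -> ScenarioSpec:
    """Four-group 50-location design from single-site counts and mixed-site group sets."""
    L = sum(singles_per_group) + len(mixed_groups)
    G = len(singles_per_group)
    supports: list[list[int]] = [[] for _ in range(G)]
    loc = 0
    for g, n_single in enumerate(singles_per_group):
        supports[g].extend(range(loc, loc + n_single))
        loc += n_single
    for groups in mixed_groups:
        for g in groups:
            supports[g].append(loc)
        loc += 1
    return ScenarioSpec(
        n_locations=L,
        group_sizes=tuple([n_per_group] * G),
        true_profiles=_profiles_from_supports(supports, L),
        effort=effort,
        label=label,
        annotations={"mixed_locations": list(range(sum(singles_per_group), L))},
    )


def scenario_preset(name: str, n_per_group: int = 100, effort: int = 20) -> ScenarioSpec:
    """Return one of the built-in benchmark designs.

    ``scenario1`` and ``scenario2`` are four-group networks on 50 locations
    with 9 and 27 mixed-membership locations respectively; the remaining
    locations each belong to a single group.  ``invasion_t1`` and
    ``invasion_t2`` describe the same two communities of individuals in two
    time periods: at t1 the communities use disjoint location sets, at t2
    the second (invading) community shifts half of its visitation mass onto
    ten of the first community's locations while the first community's
    profile is unchanged.
    """
    if name not in PRESET_NAMES:
        raise InputValidationError(
            f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    if name == "scenario1":
        # 41 single-membership sites, 9 shared between two groups.
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3), (0, 1), (1, 2), (2, 3)]
        return _overlap_preset("scenario1", [11, 10, 10, 10], pairs, n_per_group, effort)
    if name == "scenario2":
        # 23 single-membership sites, 27 shared (one by three groups).
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)] * 4
        pairs += [(0, 1), (0, 2), (0, 1, 2)]
        return _overlap_preset("scenario2", [6, 6, 6, 5], pairs, n_per_group, effort)

    L = 50
    resident = list(range(0, 25))
    invader_core = list(range(25, 50))
    invaded = list(range(0, 10))
    psi = np.zeros((2, L))
    psi[0, resident] = 1.0 / len(resident)
    if name == "invasion_t1":
        psi[1, invader_core] = 1.0 / len(invader_core)
        annotations = {"invaded_locations": []}
    else:
        psi[1, invader_core] = 0.5 / len(invader_core)
        psi[1, invaded] = 0.5 / len(invaded)
        annotations = {"invaded_locations": invaded}
    return ScenarioSpec(
        n_locations=L,
        group_sizes=(n_per_group, n_per_group),
        true_profiles=psi,
        effort=effort,
        label=name,
        annotations=annotations,
    )
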