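"""Stochastic growth of the shell by pairwise (dimer) addition.

A hypothesis engine, not fitted kinetics: the mechanism (growth by dimers,
one-sided vacancy) is taken as given, the contact weights are free
parameters whose default signs follow the interface-energy ordering
(trimer contact favourable, pentamer contact weakly unfavourable).

State space is the 2^30 set of occupied-dimer subsets, so every state
satisfies the dimer rule by construction.  The RNG is numpy's Philox
counter-based bit generator (documented, cross-platform stable stream for
a given ``rng_seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from shellkit.icosa_lattice import SubunitLattice

__all__ = [
    "AssemblyParams",
    "AssemblyStep",
    "AssemblyTrajectory",
    "simulate_dimer_assembly",
    "vacancy_is_single_patch",
    "trajectory_occupancy_stats",
    "state_energy",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Weights and controls of the dimer-addition simulator.

    More negative weight = more favourable contact.  ``allowed_dimers``
    restricts moves to a sub-lattice (used for exhaustively checkable toy
    systems).
    """

    w_trimer: float = -1.0
    w_pentamer: float = 0.25
    beta: float = 1.0
    seed_site: int | str = "random"  # dimer id or "random"
    allow_detachment: bool = False
    max_steps: int = 10_000
    rng_seed: int = 0
    allowed_dimers: frozenset | None = None
    stop_at_complete: bool = True  # False keeps sampling (equilibrium studies)

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class AssemblyStep:
    kind: str  # add | remove
    dimer_id: int
    new_trimer_contacts: int
    new_pentamer_contacts: int
    delta_energy: float
    n_candidates: int
    accepted: bool


@dataclass
class AssemblyTrajectory:
    states: list[frozenset]  # occupied site-id sets after each accepted move
    dimer_states: list[frozenset]  # occupied dimer-id sets
    steps: list[AssemblyStep]
    stalled: bool
    params: AssemblyParams
    rng_algorithm: str = "philox"

    @property
    def final_sites(self) -> frozenset:
        return self.states[-1] if self.states else frozenset()

    def state_at_size(self, n_sites: int) -> frozenset | None:
        """First state with exactly ``n_sites`` occupied sites."""
        for s in self.states:
            if len(s) == n_sites:
                return s
        return None


class _LatticeTables:
    """Cached per-dimer site/group index tables."""

    def __init__(self, lattice: SubunitLattice):
        self.lattice = lattice
        self.dimer_sites = np.array(
            [lattice.group_members("dimer", d) for d in range(30)]
        )
        self.trimer_of = lattice.trimer_of
        self.pentamer_of = lattice.pentamer_of


def _new_contacts(tables, tri_count, pen_count, dimer_id):
    s1, s2 = tables.dimer_sites[dimer_id]
    nt = int(tri_count[tables.trimer_of[s1]] + tri_count[tables.trimer_of[s2]])
    np_ = int(pen_count[tables.pentamer_of[s1]] + pen_count[tables.pentamer_of[s2]])
    return nt, np_


def state_energy(lattice: SubunitLattice, sites, w_trimer: float, w_pentamer: float) -> float:
    """Contact energy of a site set: pairwise contacts within each trimer
    and pentamer group (``C(k, 2)`` per group with ``k`` present)."""
    sites = list(sites)
    mask = np.zeros(lattice.n_sites, dtype=bool)
    mask[sites] = True
    e = 0.0
    for group_of, w, n in (
        (lattice.trimer_of, w_trimer, 20),
        (lattice.pentamer_of, w_pentamer, 12),
    ):
        k = np.bincount(group_of[mask], minlength=n)
        e += w * float((k * (k - 1) // 2).sum())
    return e


def simulate_dimer_assembly(
    lattice: SubunitLattice, params: AssemblyParams
) -> AssemblyTrajectory:
    """Kinetic Monte-Carlo growth over dimer ids.

    Without detachment, each step adds one absent dimer adjacent to the
    occupied set (sharing >= 1 trimer or pentamer group with an occupied
    site), chosen with probability proportional to ``exp(-beta * dE)``
    where ``dE = w_trimer * new trimer contacts + w_pentamer * new
    pentamer contacts``; ties at equal weight are resolved by the RNG
    stream, candidate order is lowest dimer id first.  With detachment a
    Metropolis-Hastings move set (uniform proposal over additions and
    reversible removals, candidate-count Hastings correction) makes the
    chain satisfy detailed balance with respect to
    ``exp(-beta * state_energy)``.

    Terminates at 30 occupied dimers or ``max_steps``; a state with no
    candidate move is flagged ``stalled``, not raised.
    """
    tables = _LatticeTables(lattice)
    rng = np.random.Generator(np.random.Philox(params.rng_seed))
    allowed = (
        np.arange(30)
        if params.allowed_dimers is None
        else np.array(sorted(params.allowed_dimers), dtype=int)
    )
    allowed_set = set(int(d) for d in allowed)

    occupied: set[int] = set()
    tri_count = np.zeros(20, dtype=int)
    pen_count = np.zeros(12, dtype=int)
    site_mask = np.zeros(60, dtype=bool)

    def apply(dimer_id, sign):
        for s in tables.dimer_sites[dimer_id]:
            site_mask[s] = sign > 0
            tri_count[tables.trimer_of[s]] += sign
            pen_count[tables.pentamer_of[s]] += sign

    def adjacent(dimer_id):
        s1, s2 = tables.dimer_sites[dimer_id]
        return (
            tri_count[tables.trimer_of[s1]] > 0
            or pen_count[tables.pentamer_of[s1]] > 0
            or tri_count[tables.trimer_of[s2]] > 0
            or pen_count[tables.pentamer_of[s2]] > 0
        )

    def add_candidates():
        if not occupied:
            # nucleation: any allowed dimer may seed (keeps the detachment
            # chain reversible through the empty state)
            return [int(d) for d in allowed]
        return [d for d in allowed if d not in occupied and adjacent(d)]

    def remove_candidates():
        out = []
        for d in sorted(occupied):
            if len(occupied) == 1:
                out.append(d)
                continue
            apply(d, -1)
            if adjacent(d):
                out.append(d)
            apply(d, +1)
        return out

    states: list[frozenset] = []
    dimer_states: list[frozenset] = []
    steps: list[AssemblyStep] = []
    stalled = False

    # nucleation: the seed dimer needs no adjacency
    if params.seed_site == "random":
        seed = int(allowed[rng.integers(len(allowed))])
    else:
        seed = int(params.seed_site)
        if seed not in allowed_set:
            raise ValueError(f"seed dimer {seed} not in the allowed sub-lattice")
    occupied.add(seed)
    apply(seed, +1)
    states.append(frozenset(np.flatnonzero(site_mask).tolist()))
    dimer_states.append(frozenset(occupied))
    steps.append(AssemblyStep("add", seed, 0, 0, 0.0, len(allowed), True))

    for _ in range(params.max_steps):
        if len(occupied) == len(allowed_set) and (
            params.stop_at_complete or not params.allow_detachment
        ):
            break
        adds = add_candidates()
        removes = remove_candidates() if params.allow_detachment else []
        if not adds and not removes:
            stalled = True
            break
        if params.allow_detachment:
            # uniform proposal over the combined move set + Hastings correction
            moves = [("add", d) for d in adds] + [("remove", d) for d in removes]
            n_here = len(moves)
            kind, d = moves[int(rng.integers(n_here))]
            sign = +1 if kind == "add" else -1
            if kind == "add":
                nt, np_ = _new_contacts(tables, tri_count, pen_count, d)
                de = params.w_trimer * nt + params.w_pentamer * np_
            else:
                apply(d, -1)
                nt, np_ = _new_contacts(tables, tri_count, pen_count, d)
                apply(d, +1)
                de = -(params.w_trimer * nt + params.w_pentamer * np_)
            # trial state candidate count
            apply(d, sign)
            occupied.add(d) if sign > 0 else occupied.remove(d)
            n_there = len(add_candidates()) + len(remove_candidates())
            ratio = np.exp(-params.beta * de) * (n_here / max(n_there, 1))
            accept = rng.random() < min(1.0, ratio)
            if not accept:
                occupied.remove(d) if sign > 0 else occupied.add(d)
                apply(d, -sign)
            steps.append(
                AssemblyStep(kind, int(d), nt, np_, float(de), n_here, accept)
            )
            if accept:
                states.append(frozenset(np.flatnonzero(site_mask).tolist()))
                dimer_states.append(frozenset(occupied))
        else:
            des = []
            contacts = []
            for d in adds:
                nt, np_ = _new_contacts(tables, tri_count, pen_count, d)
                contacts.append((nt, np_))
                des.append(params.w_trimer * nt + params.w_pentamer * np_)
            des = np.array(des)
            if np.isinf(params.beta):
                # greedy limit; ties broken towards the lowest dimer id
                k = int(np.argmin(des))
            else:
                w = np.exp(-params.beta * (des - des.min()))
                p = w / w.sum()
                k = int(rng.choice(len(adds), p=p))
            d = adds[k]
            occupied.add(d)
            apply(d, +1)
            states.append(frozenset(np.flatnonzero(site_mask).tolist()))
            dimer_states.append(frozenset(occupied))
            steps.append(
                AssemblyStep(
                    "add", int(d), contacts[k][0], contacts[k][1], float(des[k]),
                    len(adds), True,
                )
            )
    return AssemblyTrajectory(states, dimer_states, steps, stalled, params)


def vacancy_is_single_patch(lattice: SubunitLattice, occupied) -> bool:
    """True iff the unoccupied sites form one connected patch on the
    trimer+pentamer adjacency graph (vacuously true for the full shell)."""
    occ = {int(s) for s in occupied}
    if not occ <= set(range(lattice.n_sites)):
        raise ValueError("occupied must be a subset of sites 0..59")
    vacancy = set(range(lattice.n_sites)) - occ
    if not vacancy:
        return True
    g = nx.Graph()
    g.add_nodes_from(vacancy)
    g.add_edges_from(
        (i, j)
        for i, j, kind in lattice.adjacency
        if kind in ("trimer", "pentamer") and i in vacancy and j in vacancy
    )
    return nx.number_connected_components(g) == 1


def _added_dimer_relation(lattice: SubunitLattice, before: frozenset, after: frozenset) -> str:
    """Categorise how the dimers added between two states relate."""
    added_sites = sorted(after - before)
    added_dimers = sorted({int(lattice.dimer_of[s]) for s in added_sites})
    if len(added_dimers) < 2:
        return "single"
    for group_of in (lattice.trimer_of, lattice.pentamer_of):
        groups: dict[int, set] = {}
        for s in added_sites:
            groups.setdefault(int(group_of[s]), set()).add(int(lattice.dimer_of[s]))
        if any(len(ds) >= 2 for ds in groups.values()):
            return "shared_trimer" if group_of is lattice.trimer_of else "shared_pentamer"
    return "disjoint"


def trajectory_occupancy_stats(
    lattice: SubunitLattice,
    trajectories: list[AssemblyTrajectory],
    targets: dict[int, "OccupancyProfile"] | None = None,
    sizes: tuple[int, ...] = (48, 52, 54),
):
    """Per intermediate size: single-vacancy-patch fraction, target-profile
    match fraction, and the distribution of added-dimer placements between
    consecutive sampled sizes."""
    from shellkit.occupancy_pipeline import tabulate_occupancy

    if not trajectories:
        raise ValueError("need at least one trajectory")
    rows = []
    for size in sizes:
        hits = [t.state_at_size(size) for t in trajectories]
        present = [h for h in hits if h is not None]
        row = {"size": size, "n_trajectories": len(present)}
        if present:
            row["single_patch_fraction"] = float(
                np.mean([vacancy_is_single_patch(lattice, s) for s in present])
            )
            if targets and size in targets:
                row["profile_match_fraction"] = float(
                    np.mean(
                        [tabulate_occupancy(lattice, s).matches(targets[size]) for s in present]
                    )
                )
        rows.append(row)
    transitions: dict[str, int] = {}
    for a, b in zip(sizes[:-1], sizes[1:]):
        key = f"{a}->{b}"
        cats = []
        for t in trajectories:
            sa, sb = t.state_at_size(a), t.state_at_size(b)
            if sa is not None and sb is not None and sa <= sb:
                cats.append(_added_dimer_relation(lattice, sa, sb))
        transitions[key] = {c: cats.count(c) for c in sorted(set(cats))}
    import pandas as pd

    return pd.DataFrame(rows), transitions
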