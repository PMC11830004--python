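"""Per-subunit map-model cross-correlation, stability classification and
occupancy tabulation for partial shells.

The tabulation convention mirrors the published occupancy table: for each
interface class (dimer / trimer / pentamer) it reports the number of
*subunits* housed in groups with a given number of present members, e.g. a
trimer row "2" counts two subunits for every trimer with exactly two
members present.  Group counts are derivable and also emitted.

Classification thresholds follow the published captions: strictly
``cc > t_high`` is *fully_resolved*, the closed interval
``t_low <= cc <= t_high`` is *less_resolved*, and ``cc < t_low`` is
*absent*.  The original analysis excluded absent chains "together with
visual inspection"; here the threshold is the sole criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from shellkit import icosa_lattice
from shellkit.icosa_lattice import SubunitLattice
from shellkit.structure_io import DensityMap, ShellModel
from shellkit.synthetic_shells import simulate_density

__all__ = [
    "CLASS_SIZES",
    "ChainCCRecord",
    "OccupancyProfile",
    "OccupancyTable",
    "ProfileSearchResult",
    "OutOfFrameError",
    "PUBLISHED_INTERMEDIATE_PROFILES",
    "chain_map_cc",
    "classify_chain_states",
    "classify_model",
    "tabulate_occupancy",
    "find_subset_matching_profile",
    "select_dimer_operator_by_contact",
]

CLASS_SIZES = {"dimer": 2, "trimer": 3, "pentamer": 5}

T_HIGH_DEFAULT = 0.75
T_LOW_DEFAULT = 0.5


class OutOfFrameError(ValueError):
    """The requested chain lies outside the density-map frame."""


@dataclass(frozen=True)
class ChainCCRecord:
    chain_id: str
    site_id: int
    cc: float
    state: str | None = None  # fully_resolved | less_resolved | absent

    def __post_init__(self):
        if not np.isfinite(self.cc):
            raise ValueError("cc must be finite")


def _check_class_counts(name: str, counts: dict[int, int]) -> None:
    size = CLASS_SIZES[name]
    for k, subunits in counts.items():
        if not 1 <= k <= size:
            raise ValueError(f"{name} occupancy count {k} outside 1..{size}")
        if subunits % k:
            raise ValueError(
                f"{name} row {k} holds {subunits} subunits, not a multiple of {k}"
            )


@dataclass(frozen=True)
class OccupancyProfile:
    """A target occupancy pattern in the subunit-count convention."""

    dimer: dict[int, int]
    trimer: dict[int, int]
    pentamer: dict[int, int]
    all_dimers_complete: bool = False

    def __post_init__(self):
        for name in CLASS_SIZES:
            _check_class_counts(name, getattr(self, name))
        totals = {name: sum(getattr(self, name).values()) for name in CLASS_SIZES}
        if len(set(totals.values())) != 1:
            raise ValueError(f"per-class totals differ: {totals}")
        if self.all_dimers_complete and set(self.dimer) - {2}:
            raise ValueError("all_dimers_complete contradicts incomplete dimer rows")

    @property
    def n_present(self) -> int:
        return sum(self.dimer.values())


@dataclass(frozen=True)
class OccupancyTable:
    """Occupancy tabulation of one present-site set (see module docstring)."""

    dimer: dict[int, int]
    trimer: dict[int, int]
    pentamer: dict[int, int]
    n_present: int

    @property
    def all_dimers_complete(self) -> bool:
        return set(self.dimer) <= {2}

    def group_counts(self, name: str) -> dict[int, int]:
        return {k: v // k for k, v in getattr(self, name).items()}

    def complete_groups(self, name: str) -> int:
        size = CLASS_SIZES[name]
        return getattr(self, name).get(size, 0) // size

    def matches(self, profile: OccupancyProfile) -> bool:
        if profile.all_dimers_complete and not self.all_dimers_complete:
            return False
        return all(
            {k: v for k, v in getattr(self, n).items() if v}
            == {k: v for k, v in getattr(profile, n).items() if v}
            for n in CLASS_SIZES
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, size in CLASS_SIZES.items():
            counts = getattr(self, name)
            for k in range(1, size + 1):
                rows.append(
                    {
                        "class": name,
                        "present_members": k,
                        "subunits": counts.get(k, 0),
                        "groups": counts.get(k, 0) // k,
                    }
                )
        return pd.DataFrame(rows)


#: The published occupancy columns for the 48-, 52- and 54-subunit
#: intermediates (subunit-count convention; all dimers complete in each).
PUBLISHED_INTERMEDIATE_PROFILES: dict[int, OccupancyProfile] = {
    48: OccupancyProfile(
        dimer={2: 48},
        trimer={1: 4, 2: 2, 3: 42},
        pentamer={3: 6, 4: 12, 5: 30},
        all_dimers_complete=True,
    ),
    52: OccupancyProfile(
        dimer={2: 52},
        trimer={1: 3, 2: 4, 3: 45},
        pentamer={2: 2, 3: 3, 4: 12, 5: 35},
        all_dimers_complete=True,
    ),
    54: OccupancyProfile(
        dimer={2: 54},
        trimer={2: 6, 3: 48},
        pentamer={3: 9, 5: 45},
        all_dimers_complete=True,
    ),
}


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------


def _soft_mask_weights(dist: np.ndarray, radius: float, soft_width: float) -> np.ndarray:
    w = np.zeros_like(dist)
    w[dist <= radius] = 1.0
    edge = (dist > radius) & (dist < radius + soft_width)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - radius) / soft_width))
    return w


def chain_map_cc(
    dmap: DensityMap,
    model: ShellModel,
    chain_id: str,
    resolution: float,
    mask_radius: float = 3.0,
    soft_width: float = 3.0,
) -> float:
    """Masked real-space cross-correlation of one chain against the map.

    A reference density for the chain is simulated at the map's geometry and
    nominal resolution; a binary mask of voxels within ``mask_radius`` of
    any chain atom, with a ``soft_width`` cosine edge, weights a zero-mean
    unit-variance correlation.  The value is scale- and offset-invariant and
    lies in [-1, 1].
    """
    chain = model.chain(chain_id)
    if chain.n_atoms == 0:
        raise OutOfFrameError(f"chain {chain_id} has no atoms")
    reach = mask_radius + soft_width
    lo_idx = np.floor(dmap.position_to_index(chain.coords.min(axis=0) - reach)).astype(int)
    hi_idx = np.ceil(dmap.position_to_index(chain.coords.max(axis=0) + reach)).astype(int)
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx + 1, dmap.shape)
    if np.any(lo_idx >= hi_idx):
        raise OutOfFrameError(f"chain {chain_id} lies outside the map frame")
    sub = dmap.grid[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]]
    sub_origin = dmap.origin + lo_idx * dmap.voxel_size
    crop = DensityMap(sub, dmap.voxel_size, sub_origin)

    ref = simulate_density(
        ShellModel({chain_id: chain}), resolution, dmap.voxel_size, like=crop
    ).grid

    ax = [
        sub_origin[d] + dmap.voxel_size * np.arange(sub.shape[d]) for d in range(3)
    ]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dist, _ = cKDTree(chain.coords).query(pts, k=1)
    w = _soft_mask_weights(dist.reshape(sub.shape), mask_radius, soft_width)
    wsum = w.sum()
    if wsum <= 0:
        raise OutOfFrameError(f"soft mask for chain {chain_id} is empty")

    a = np.asarray(sub, dtype=float)
    b = ref
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    da, db = a - am, b - bm
    denom = np.sqrt((w * da * da).sum() * (w * db * db).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((w * da * db).sum() / denom, -1.0, 1.0))


def classify_chain_states(
    records,
    t_high: float = T_HIGH_DEFAULT,
    t_low: float = T_LOW_DEFAULT,
) -> list[ChainCCRecord]:
    """Attach the three-way stability state to cc records.

    ``records`` may be ``ChainCCRecord`` items or ``(chain_id, site_id, cc)``
    tuples.
    """
    if not t_low < t_high:
        raise ValueError("t_low must be below t_high")
    out = []
    for rec in records:
        if isinstance(rec, ChainCCRecord):
            cid, sid, cc = rec.chain_id, rec.site_id, rec.cc
        else:
            cid, sid, cc = rec
        if cc > t_high:
            state = "fully_resolved"
        elif cc >= t_low:
            state = "less_resolved"
        else:
            state = "absent"
        out.append(ChainCCRecord(cid, int(sid), float(cc), state))
    return out


def classify_model(
    dmap: DensityMap,
    model: ShellModel,
    resolution: float,
    mask_radius: float = 3.0,
    soft_width: float = 3.0,
    t_high: float = T_HIGH_DEFAULT,
    t_low: float = T_LOW_DEFAULT,
) -> list[ChainCCRecord]:
    """Per-chain cc + classification for every chain of the model."""
    assignment = model.assignment or {}
    raw = []
    for cid in model.chain_ids:
        cc = chain_map_cc(dmap, model, cid, resolution, mask_radius, soft_width)
        raw.append((cid, assignment.get(cid, -1), cc))
    return classify_chain_states(raw, t_high=t_high, t_low=t_low)


# ---------------------------------------------------------------------------
# occupancy tabulation
# ---------------------------------------------------------------------------


def tabulate_occupancy(lattice: SubunitLattice, present_sites) -> OccupancyTable:
    """Tabulate, per interface class, how many subunits sit in groups with
    each present-member count."""
    present = sorted({int(s) for s in present_sites})
    if any(s < 0 or s >= lattice.n_sites for s in present):
        raise ValueError("present_sites must be within 0..59")
    mask = np.zeros(lattice.n_sites, dtype=bool)
    mask[present] = True
    out: dict[str, dict[int, int]] = {}
    for name, group_of in (
        ("dimer", lattice.dimer_of),
        ("trimer", lattice.trimer_of),
        ("pentamer", lattice.pentamer_of),
    ):
        n_groups = group_of.max() + 1
        per_group = np.bincount(group_of[mask], minlength=n_groups)
        counts: dict[int, int] = {}
        for k in range(1, CLASS_SIZES[name] + 1):
            groups_k = int((per_group == k).sum())
            if groups_k:
                counts[k] = groups_k * k
        out[name] = counts
    return OccupancyTable(
        dimer=out["dimer"],
        trimer=out["trimer"],
        pentamer=out["pentamer"],
        n_present=len(present),
    )


# ---------------------------------------------------------------------------
# profile-consistency search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSearchResult:
    status: str  # found | none | inconclusive
    sites: frozenset | None
    examined: int

    def __bool__(self):
        return self.status == "found"


def _target_group_histogram(counts: dict[int, int], size: int, n_groups: int) -> np.ndarray:
    hist = np.zeros(size + 1, dtype=int)
    for k, subunits in counts.items():
        hist[k] = subunits // k
    hist[0] = n_groups - hist.sum()
    if hist[0] < 0:
        raise ValueError("profile requires more groups than the lattice has")
    return hist


def find_subset_matching_profile(
    lattice: SubunitLattice,
    profile: OccupancyProfile,
    node_budget: int = 2_000_000,
    chunk: int = 20_000,
) -> ProfileSearchResult:
    """Search for a present-site set whose tabulation equals the profile.

    The search space is restricted to dimer-complete subsets (2^30 dimer
    inclusion choices), enumerated deterministically as combinations of
    *excluded* dimers and evaluated in vectorised chunks.  Exceeding
    ``node_budget`` examined combinations yields status ``"inconclusive"``,
    distinct from an exhaustive ``"none"``.
    """
    total = profile.n_present
    if total % 2 or set(profile.dimer) - {2}:
        # dimers contribute two subunits each; odd totals or broken dimers
        # are unreachable in the dimer-complete space
        return ProfileSearchResult("none", None, 0)
    n_dimers = total // 2
    n_excl = 30 - n_dimers
    if n_excl < 0:
        return ProfileSearchResult("none", None, 0)

    dimer_sites = [lattice.group_members("dimer", d) for d in range(30)]
    tri = np.array([[lattice.trimer_of[s] for s in sites] for sites in dimer_sites])
    pen = np.array([[lattice.pentamer_of[s] for s in sites] for sites in dimer_sites])
    tri_target = _target_group_histogram(profile.trimer, 3, 20)
    pen_target = _target_group_histogram(profile.pentamer, 5, 12)

    examined = 0
    combos_iter = itertools.combinations(range(30), n_excl)
    if n_excl == 0:
        combos_iter = iter([()])
    while True:
        block = list(itertools.islice(combos_iter, chunk))
        if not block:
            return ProfileSearchResult("none", None, examined)
        if examined + len(block) > node_budget:
            block = block[: node_budget - examined]
            if not block:
                return ProfileSearchResult("inconclusive", None, examined)
        arr = np.array(block, dtype=int)  # (m, n_excl)
        m = len(arr)
        tri_removed = np.zeros((m, 20), dtype=int)
        pen_removed = np.zeros((m, 12), dtype=int)
        if n_excl:
            rows = np.repeat(np.arange(m), n_excl * 2)
            np.add.at(tri_removed, (rows, tri[arr].reshape(m, -1).ravel()), 1)
            np.add.at(pen_removed, (rows, pen[arr].reshape(m, -1).ravel()), 1)
        tri_present = 3 - tri_removed
        pen_present = 5 - pen_removed
        ok = np.ones(m, dtype=bool)
        for k in range(4):
            ok &= (tri_present == k).sum(axis=1) == tri_target[k]
        for k in range(6):
            ok &= (pen_present == k).sum(axis=1) == pen_target[k]
        hit = np.flatnonzero(ok)
        if hit.size:
            excl = set(int(d) for d in arr[hit[0]])
            sites = frozenset(
                s for d in range(30) if d not in excl for s in dimer_sites[d]
            )
            table = tabulate_occupancy(lattice, sites)
            assert table.matches(profile), "search result failed verification"
            return ProfileSearchResult("found", sites, examined + int(hit[0]) + 1)
        examined += m
        if examined >= node_budget:
            return ProfileSearchResult("inconclusive", None, examined)


# ---------------------------------------------------------------------------
# structure-based dimer-operator selection
# ---------------------------------------------------------------------------


def select_dimer_operator_by_contact(
    model: ShellModel,
    lattice: SubunitLattice,
    contact_cutoff: float = 5.0,
    max_pairs: int = 6,
) -> np.ndarray:
    """Pick the twofold group member whose related chain pairs share the
    largest atomic contact (the E-loop pairing in a real shell).

    Requires ``model.assignment``; returns the selected involution, suitable
    for :func:`shellkit.icosa_lattice.with_dimer_operator`.
    """
    if model.assignment is None:
        raise ValueError("model has no site assignment")
    site_to_chain = {s: c for c, s in model.assignment.items()}
    key_to_site = {
        icosa_lattice._matrix_key(R): i for i, R in enumerate(lattice.site_rotations)
    }
    invs = [
        R for R in lattice.operators.rotations if abs(np.trace(R) + 1.0) < 1e-6
    ]
    best_T, best_score = None, -1.0
    for T in invs:
        pairs = []
        for i in range(lattice.n_sites):
            j = key_to_site[icosa_lattice._matrix_key(lattice.site_rotations[i] @ T)]
            if i < j and i in site_to_chain and j in site_to_chain:
                pairs.append((site_to_chain[i], site_to_chain[j]))
            if len(pairs) >= max_pairs:
                break
        if not pairs:
            continue
        contacts = []
        for ca, cb in pairs:
            ta = cKDTree(model.chain(ca).coords)
            tb = cKDTree(model.chain(cb).coords)
            contacts.append(ta.count_neighbors(tb, contact_cutoff))
        score = float(np.mean(contacts))
        if score > best_score:
            best_score, best_T = score, T
    if best_T is None:
        raise ValueError("no twofold-related chain pair present in the model")
    return best_T
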