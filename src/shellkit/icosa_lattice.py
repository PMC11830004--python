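"""Icosahedral point-group operators and the 60-site T=1 subunit lattice.

Axis convention (canonical frame)
---------------------------------
The three mutually perpendicular twofold axes lie along ``x``, ``y`` and
``z``.  The icosahedron vertices are the cyclic permutations of
``(0, ±1, ±phi)`` with ``phi`` the golden ratio, so one fivefold axis,
``(phi, 0, 1)/|.|``, lies in the ``xz``-plane at ``atan(1/phi) ≈ 31.7175°``
from ``+x`` (``58.2825°`` from ``+z``).

Operator-count conventions
--------------------------
Two counting conventions coexist and both are honoured where each is used:
the full rotation group returned by :func:`generate_point_group_operators`
contains 60 matrices (identity included), whereas the *minimal local
symmetry* set of :func:`minimal_local_symmetry_set` excludes the reference
site, so ``n_occupied`` fully occupied sites yield ``n_occupied - 1``
operators (27 occupied -> 26 operators; a complete shell -> 59).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHI",
    "OperatorSet",
    "SubunitLattice",
    "UnsupportedSymmetryError",
    "InvalidGroupError",
    "generate_point_group_operators",
    "build_subunit_lattice",
    "minimal_local_symmetry_set",
    "rotation_about",
]

PHI = (1.0 + np.sqrt(5.0)) / 2.0

#: Frobenius-norm tolerance for matching two rotation operators.
OPERATOR_MATCH_TOL = 1e-6


class UnsupportedSymmetryError(ValueError):
    """Raised for point-group labels this release does not implement."""


class InvalidGroupError(ValueError):
    """Raised when a supplied operator set is not a closed rotation group."""


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by `angle` about `axis`."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _matrix_key(R: np.ndarray, decimals: int = 6) -> tuple:
    """Stable hashable key for a rotation matrix (rounding << inter-operator
    distances, >> accumulated double-precision noise)."""
    return tuple(np.round(np.asarray(R), decimals).ravel() + 0.0)


@dataclass(frozen=True)
class OperatorSet:
    """A finite rotation point group.

    Invariants (checked on construction): every matrix is special orthogonal
    to 1e-9, the set contains the identity and is closed under composition
    and inversion.
    """

    label: str
    rotations: np.ndarray  # (n, 3, 3)

    def __post_init__(self):
        R = np.asarray(self.rotations, dtype=float)
        object.__setattr__(self, "rotations", R)
        if R.ndim != 3 or R.shape[1:] != (3, 3):
            raise InvalidGroupError("rotations must have shape (n, 3, 3)")
        eye = np.eye(3)
        for M in R:
            if np.abs(M @ M.T - eye).max() > 1e-9:
                raise InvalidGroupError("operator is not orthonormal")
            if abs(np.linalg.det(M) - 1.0) > 1e-9:
                raise InvalidGroupError("operator determinant != +1")

    @property
    def count(self) -> int:
        return len(self.rotations)

    def index_of(self, R: np.ndarray) -> int:
        """Index of the member matching ``R`` within OPERATOR_MATCH_TOL."""
        d = np.linalg.norm(self.rotations - np.asarray(R)[None], axis=(1, 2))
        i = int(np.argmin(d))
        if d[i] > OPERATOR_MATCH_TOL:
            raise InvalidGroupError("matrix is not a member of the operator set")
        return i

    def validate_closure(self) -> None:
        keys = {_matrix_key(R) for R in self.rotations}
        if _matrix_key(np.eye(3)) not in keys:
            raise InvalidGroupError("operator set lacks the identity")
        for R in self.rotations:
            if _matrix_key(R.T) not in keys:
                raise InvalidGroupError("operator set is not closed under inversion")
            # spot-check closure against the first operator of the set
        for A in self.rotations:
            if _matrix_key(A @ self.rotations[1 % len(self.rotations)]) not in keys:
                raise InvalidGroupError("operator set is not closed under composition")


def generate_point_group_operators(label: str = "I") -> OperatorSet:
    """Generate the rotational icosahedral group ("I", 60 operators).

    Deterministic; matrices are sorted by a canonical lexicographic key of
    their rounded entries.
    """
    if label != "I":
        raise UnsupportedSymmetryError(
            f"unsupported symmetry label {label!r}; only 'I' is implemented"
        )
    five = rotation_about(np.array([PHI, 0.0, 1.0]), 2.0 * np.pi / 5.0)
    two = rotation_about(np.array([0.0, 0.0, 1.0]), np.pi)
    members: dict[tuple, np.ndarray] = {_matrix_key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    gens = [five, two]
    while frontier:
        nxt = []
        for R in frontier:
            for G in gens:
                P = G @ R
                k = _matrix_key(P)
                if k not in members:
                    members[k] = P
                    nxt.append(P)
        frontier = nxt
    mats = sorted(members.values(), key=_matrix_key)
    ops = OperatorSet(label=label, rotations=np.array(mats))
    assert ops.count == 60
    return ops


def _involutions(operators: OperatorSet) -> list[np.ndarray]:
    """The 15 order-2 members (trace -1) of an icosahedral set."""
    return [R for R in operators.rotations if abs(np.trace(R) + 1.0) < 1e-6]


def _rotation_axis(R: np.ndarray) -> np.ndarray:
    """Unit rotation axis of a non-identity rotation (sign arbitrary)."""
    w, v = np.linalg.eig(R)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    return axis / np.linalg.norm(axis)


def _base_direction() -> np.ndarray:
    """Generic direction strictly inside one fundamental domain: a fixed
    convex combination of an adjacent fivefold axis, threefold axis and
    twofold axis."""
    v5 = np.array([PHI, 0.0, 1.0])
    v3 = np.array([2.0 * PHI + 1.0, PHI, 0.0])  # centre of an adjacent face
    v2 = np.array([1.0, 0.0, 0.0])  # midpoint axis of the shared edge
    c = 0.5 * v5 / np.linalg.norm(v5) + 0.3 * v3 / np.linalg.norm(v3) + 0.2 * v2
    return c / np.linalg.norm(c)


@dataclass
class SubunitLattice:
    """The 60-site T=1 lattice with its dimer/trimer/pentamer partition.

    ``site_rotations[i]`` places the reference subunit at site ``i``
    (coordinates transform as ``x_i = R_i @ x_ref``).  ``centroids[i]`` is
    the unit direction of site ``i``'s subunit centroid.
    """

    t_number: int
    operators: OperatorSet
    site_rotations: np.ndarray  # (60, 3, 3)
    centroids: np.ndarray  # (60, 3) unit vectors
    dimer_of: np.ndarray  # (60,) int, 0..29
    trimer_of: np.ndarray  # (60,) int, 0..19
    pentamer_of: np.ndarray  # (60,) int, 0..11
    adjacency: list[tuple[int, int, str]]  # edges labelled dimer/trimer/pentamer
    pentamer_axes: np.ndarray  # (12, 3)
    trimer_axes: np.ndarray  # (20, 3)
    dimer_axes: np.ndarray  # (30, 3)
    dimer_operator: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def n_sites(self) -> int:
        return len(self.site_rotations)

    def group_members(self, kind: str, group_id: int) -> list[int]:
        table = {
            "dimer": self.dimer_of,
            "trimer": self.trimer_of,
            "pentamer": self.pentamer_of,
        }[kind]
        return [int(i) for i in np.flatnonzero(table == group_id)]

    def dimer_partner(self, site: int) -> int:
        members = self.group_members("dimer", int(self.dimer_of[site]))
        return members[0] if members[1] == site else members[1]

    def edges(self, kinds: tuple[str, ...] = ("dimer", "trimer", "pentamer")):
        return [(i, j) for i, j, k in self.adjacency if k in kinds]

    def to_dict(self) -> dict:
        return {
            "t_number": self.t_number,
            "symmetry": self.operators.label,
            "n_sites": self.n_sites,
            "centroids": self.centroids.tolist(),
            "site_rotations": self.site_rotations.tolist(),
            "dimer_of": self.dimer_of.tolist(),
            "trimer_of": self.trimer_of.tolist(),
            "pentamer_of": self.pentamer_of.tolist(),
            "adjacency": [[int(i), int(j), k] for i, j, k in self.adjacency],
            "pentamer_axes": self.pentamer_axes.tolist(),
            "trimer_axes": self.trimer_axes.tolist(),
            "dimer_axes": self.dimer_axes.tolist(),
        }


def lattice_from_dict(d: dict) -> "SubunitLattice":
    """Inverse of :meth:`SubunitLattice.to_dict` (JSON round-trip)."""
    ops = generate_point_group_operators(d.get("symmetry", "I"))
    lat = SubunitLattice(
        t_number=int(d["t_number"]),
        operators=ops,
        site_rotations=np.asarray(d["site_rotations"], dtype=float),
        centroids=np.asarray(d["centroids"], dtype=float),
        dimer_of=np.asarray(d["dimer_of"], dtype=int),
        trimer_of=np.asarray(d["trimer_of"], dtype=int),
        pentamer_of=np.asarray(d["pentamer_of"], dtype=int),
        adjacency=[(int(i), int(j), str(k)) for i, j, k in d["adjacency"]],
        pentamer_axes=np.asarray(d["pentamer_axes"], dtype=float),
        trimer_axes=np.asarray(d["trimer_axes"], dtype=float),
        dimer_axes=np.asarray(d["dimer_axes"], dtype=float),
    )
    return lat


def matrix_to_euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """(rot, tilt, psi) in degrees for the ZYZ convention used by common
    cryo-EM local-symmetry operator lists."""
    R = np.asarray(R, dtype=float)
    tilt = float(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if abs(np.sin(tilt)) > 1e-6:
        # R = Rz(psi) @ Ry(tilt) @ Rz(rot)
        rot = float(np.arctan2(R[2, 1], -R[2, 0]))
        psi = float(np.arctan2(R[1, 2], R[0, 2]))
    elif R[2, 2] > 0:  # tilt = 0: only psi + rot is determined
        rot = 0.0
        psi = float(np.arctan2(R[1, 0], R[0, 0]))
    else:  # tilt = pi: only psi - rot is determined
        rot = 0.0
        psi = float(np.arctan2(-R[1, 0], -R[0, 0]))
    return tuple(np.degrees([rot, tilt, psi]))


def _partition_by_axes(centroids: np.ndarray, axes: np.ndarray, size: int):
    """Assign each site to its nearest signed axis; relabel groups by first
    site occurrence and validate orbit sizes."""
    dots = centroids @ axes.T
    nearest = np.argmax(dots, axis=1)
    # relabel in order of first appearance over site ids -> stable ids
    label_map: dict[int, int] = {}
    group_of = np.empty(len(centroids), dtype=int)
    for i, a in enumerate(nearest):
        if a not in label_map:
            label_map[int(a)] = len(label_map)
        group_of[i] = label_map[int(a)]
    counts = np.bincount(group_of)
    if not np.all(counts == size):
        raise InvalidGroupError(
            f"axis partition produced orbit sizes {counts.tolist()}, expected {size}"
        )
    ordered_axes = np.empty((len(label_map), 3))
    for old, new in label_map.items():
        ordered_axes[new] = axes[old]
    return group_of, ordered_axes


def build_subunit_lattice(
    operators: OperatorSet,
    reference_placement: np.ndarray | None = None,
    dimer_operator: np.ndarray | None = None,
) -> SubunitLattice:
    """Place 60 sites and partition them into 30 dimers / 20 trimers / 12
    pentamers with labelled adjacency.

    Parameters
    ----------
    operators
        A valid icosahedral operator set (see
        :func:`generate_point_group_operators`).
    reference_placement
        Optional rotation applied to the canonical reference direction
        before replication; the construction is invariant under it up to a
        relabelling of sites.
    dimer_operator
        Optional order-2 group member defining the dimer pairing.  By
        default the twofold whose axis is angularly nearest the reference
        centroid direction is used (for the deposited shell this is the
        E-loop contact pair; see
        ``occupancy_pipeline.select_dimer_operator_by_contact`` for the
        structure-based selection).
    """
    operators.validate_closure()
    if operators.count != 60:
        raise InvalidGroupError("expected the 60-operator icosahedral set")
    P = np.eye(3) if reference_placement is None else np.asarray(reference_placement, float)
    if np.abs(P @ P.T - np.eye(3)).max() > 1e-8:
        raise ValueError("reference_placement must be a rotation matrix")
    cref = P @ _base_direction()

    cents = operators.rotations @ cref  # (60, 3)
    order = np.lexsort(np.round(cents, 6).T[::-1])  # lexicographic on (x, y, z)
    site_rotations = operators.rotations[order]
    cents = cents[order]

    # --- pentamer / trimer partitions from nearest signed symmetry axes ---
    verts = []
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            for v in ([0.0, sx, sy * PHI], [sx, sy * PHI, 0.0], [sx * PHI, 0.0, sy]):
                verts.append(v)
    vaxes = np.array(verts)
    vaxes /= np.linalg.norm(vaxes, axis=1, keepdims=True)
    pentamer_of, pentamer_axes = _partition_by_axes(cents, vaxes, 5)

    # face centres: orbit of one face-centre direction under the group
    f0 = np.array([2.0 * PHI + 1.0, PHI, 0.0])
    f0 /= np.linalg.norm(f0)
    fdirs = operators.rotations @ f0
    faxes = np.unique(np.round(fdirs, 6), axis=0)
    if len(faxes) != 20:
        raise InvalidGroupError("expected 20 threefold axis directions")
    faxes = faxes / np.linalg.norm(faxes, axis=1, keepdims=True)
    trimer_of, trimer_axes = _partition_by_axes(cents, faxes, 3)

    # --- dimer pairing through a chosen twofold ---
    if dimer_operator is None:
        invs = _involutions(operators)
        axes2 = np.array([_rotation_axis(R) for R in invs])
        score = np.abs(axes2 @ cref)
        T = invs[int(np.argmax(score))]
    else:
        T = np.asarray(dimer_operator, float)
        operators.index_of(T)  # membership check
        if abs(np.trace(T) + 1.0) > 1e-6:
            raise ValueError("dimer_operator must be an order-2 group member")

    key_to_site = {_matrix_key(R): i for i, R in enumerate(site_rotations)}
    partner = np.empty(60, dtype=int)
    for i, R in enumerate(site_rotations):
        k = _matrix_key(R @ T)
        if k not in key_to_site:
            raise InvalidGroupError("operator set is not closed (dimer pairing failed)")
        partner[i] = key_to_site[k]
    if np.any(partner == np.arange(60)) or np.any(partner[partner] != np.arange(60)):
        raise InvalidGroupError("dimer pairing is not a perfect matching")

    dimer_of = np.full(60, -1, dtype=int)
    dimer_axes = []
    next_id = 0
    for i in range(60):
        if dimer_of[i] < 0:
            j = int(partner[i])
            dimer_of[i] = dimer_of[j] = next_id
            Ti = site_rotations[i] @ T @ site_rotations[i].T
            ax = _rotation_axis(Ti)
            mid = cents[i] + cents[j]
            if ax @ mid < 0:
                ax = -ax
            dimer_axes.append(ax)
            next_id += 1
    dimer_axes = np.array(dimer_axes)

    # sanity: dimer partners never share a trimer or pentamer
    for i in range(60):
        j = int(partner[i])
        if trimer_of[i] == trimer_of[j] or pentamer_of[i] == pentamer_of[j]:
            raise InvalidGroupError("dimer partner shares a trimer/pentamer orbit")

    # --- adjacency ---
    adjacency: list[tuple[int, int, str]] = []
    for i in range(60):
        j = int(partner[i])
        if i < j:
            adjacency.append((i, j, "dimer"))
    for g in range(20):
        m = [int(i) for i in np.flatnonzero(trimer_of == g)]
        for a in range(3):
            i, j = m[a], m[(a + 1) % 3]
            adjacency.append((min(i, j), max(i, j), "trimer"))
    for g in range(12):
        m = np.flatnonzero(pentamer_of == g)
        ax = pentamer_axes[g]
        # order members azimuthally around the fivefold axis
        e1 = np.cross(ax, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(ax, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ax, e1)
        ang = np.arctan2(cents[m] @ e2, cents[m] @ e1)
        ring = m[np.argsort(ang)]
        for a in range(5):
            i, j = int(ring[a]), int(ring[(a + 1) % 5])
            adjacency.append((min(i, j), max(i, j), "pentamer"))

    return SubunitLattice(
        t_number=1,
        operators=operators,
        site_rotations=site_rotations,
        centroids=cents,
        dimer_of=dimer_of,
        trimer_of=trimer_of,
        pentamer_of=pentamer_of,
        adjacency=adjacency,
        pentamer_axes=pentamer_axes,
        trimer_axes=trimer_axes,
        dimer_axes=dimer_axes,
        dimer_operator=T,
    )


def with_dimer_operator(lattice: SubunitLattice, dimer_operator: np.ndarray) -> SubunitLattice:
    """Rebuild the lattice partition with an explicitly chosen dimer twofold.

    Site numbering, trimer and pentamer partitions are unchanged; only the
    dimer pairing (and its adjacency edges/axes) are re-derived.
    """
    new = build_subunit_lattice(
        lattice.operators,
        reference_placement=None,
        dimer_operator=dimer_operator,
    )
    # the default build uses the canonical reference; verify compatibility
    if not np.allclose(new.centroids, lattice.centroids, atol=1e-6):
        raise InvalidGroupError(
            "with_dimer_operator requires a lattice built from the canonical reference"
        )
    return new


def minimal_local_symmetry_set(
    lattice: SubunitLattice,
    occupied_sites,
    reference_site: int,
) -> list[np.ndarray]:
    """Operators mapping the reference site onto every *other* occupied site.

    Follows the deposited local-symmetry convention in which the reference
    is excluded, so 27 fully occupied sites yield 26 operators and a
    complete shell yields 59 (the point group itself counts 60, identity
    included).  Order follows site numbering.
    """
    occupied = sorted(int(s) for s in occupied_sites)
    if any(s < 0 or s >= lattice.n_sites for s in occupied):
        raise ValueError("occupied_sites must be within 0..59")
    if int(reference_site) not in occupied:
        raise ValueError("reference_site must be one of the occupied sites")
    Rref = lattice.site_rotations[int(reference_site)]
    return [
        lattice.site_rotations[j] @ Rref.T for j in occupied if j != int(reference_site)
    ]
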