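"""Atomic-model and density-map I/O, plus chain -> lattice-site assignment.

Coordinates are Å throughout; diameters are converted to nm only at the
metrics/report layer.  Model parsing and writing are delegated to biotite
(PDB and mmCIF); volumes go through :mod:`shellkit.mrc`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure, set_structure

from shellkit import mrc
from shellkit.icosa_lattice import SubunitLattice

__all__ = [
    "VDW_RADII",
    "Chain",
    "ShellModel",
    "DensityMap",
    "SiteAssignment",
    "EmptyModelError",
    "ModelParseError",
    "NoAssignmentError",
    "load_shell_model",
    "save_shell_model",
    "load_density_map",
    "save_density_map",
    "fit_sphere_center",
    "assign_chains_to_sites",
    "kabsch_rotation",
]

#: Van-der-Waals radii (Å); single documented table (Bondi-style values),
#: unknown elements fall back to carbon.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "SE": 1.90,
    "FE": 1.94,
    "ZN": 1.39,
    "MG": 1.73,
}
DEFAULT_RADIUS = 1.70


class ModelParseError(ValueError):
    """Malformed model file."""


class EmptyModelError(ValueError):
    """Model contains no usable chains."""


class NoAssignmentError(ValueError):
    """Chain-to-site assignment residual exceeded the cutoff."""


@dataclass
class Chain:
    chain_id: str
    coords: np.ndarray  # (n, 3) float64, Å
    elements: np.ndarray  # (n,) str
    radii: np.ndarray  # (n,) float64, Å
    res_ids: np.ndarray | None = None
    atom_names: np.ndarray | None = None
    b_factors: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ModelParseError(f"chain {self.chain_id}: non-finite coordinates")
        if np.any(np.asarray(self.radii) <= 0):
            raise ModelParseError(f"chain {self.chain_id}: non-positive radii")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rotation=None, translation=None) -> "Chain":
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return Chain(
            self.chain_id,
            coords,
            self.elements,
            self.radii,
            self.res_ids,
            self.atom_names,
            self.b_factors,
        )


@dataclass
class ShellModel:
    """A multi-chain atomic model with an optional chain -> site assignment."""

    chains: dict[str, Chain]
    assignment: dict[str, int] | None = None

    def __post_init__(self):
        if not self.chains:
            raise EmptyModelError("model contains zero chains")

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains.values())

    def chain(self, chain_id: str) -> Chain:
        return self.chains[chain_id]

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.chains.values()])

    def all_coords(self) -> np.ndarray:
        return np.concatenate([c.coords for c in self.chains.values()])

    def all_radii(self) -> np.ndarray:
        return np.concatenate([c.radii for c in self.chains.values()])

    def subset(self, chain_ids) -> "ShellModel":
        chain_ids = list(chain_ids)
        missing = [c for c in chain_ids if c not in self.chains]
        if missing:
            raise KeyError(f"chains not in model: {missing}")
        assign = None
        if self.assignment is not None:
            assign = {c: s for c, s in self.assignment.items() if c in chain_ids}
        return ShellModel({c: self.chains[c] for c in chain_ids}, assignment=assign)

    def transformed(self, rotation=None, translation=None) -> "ShellModel":
        return ShellModel(
            {
                cid: ch.transformed(rotation, translation)
                for cid, ch in self.chains.items()
            },
            assignment=None if self.assignment is None else dict(self.assignment),
        )

    def present_sites(self) -> set[int]:
        if self.assignment is None:
            raise ValueError("model has no site assignment")
        return set(self.assignment.values())


@dataclass
class DensityMap:
    """3D voxel grid with isotropic physical voxel size and origin (Å).

    ``grid[i, j, k]`` is the value at position
    ``origin + voxel_size * (i, j, k)``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3D with dimensions >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.grid.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size, self.origin.copy())

    def position_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size


@dataclass
class SiteAssignment:
    """Bijection between a subset of chain ids and lattice site ids.

    ``rotation`` maps model-frame directions (about ``center``) into the
    lattice frame; ``residual`` is the mean centroid chord distance in Å
    after superposition.
    """

    pairs: dict[str, int]
    residual: float
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self):
        sites = list(self.pairs.values())
        if len(set(sites)) != len(sites):
            raise ValueError("assignment is not one-to-one")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    def to_json(self, path=None) -> str:
        payload = {
            "pairs": self.pairs,
            "residual_angstrom": self.residual,
            "rotation": np.asarray(self.rotation).tolist(),
            "center": np.asarray(self.center).tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _radii_for(elements) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements])


def _model_from_atom_array(atoms, drop_hydrogens: bool) -> ShellModel:
    if drop_hydrogens:
        atoms = atoms[~np.isin(atoms.element, ("H", "D"))]
    if atoms.array_length() == 0:
        raise EmptyModelError("no (heavy) atoms in file")
    # reject files where one chain id occurs in two non-contiguous runs
    cids = atoms.chain_id
    change = np.flatnonzero(cids[1:] != cids[:-1]) + 1
    starts = np.concatenate(([0], change))
    run_ids = cids[starts]
    if len(set(run_ids)) != len(run_ids):
        dupes = sorted({c for c in run_ids if list(run_ids).count(c) > 1})
        raise ModelParseError(f"duplicate chain ids: {dupes}")
    chains: dict[str, Chain] = {}
    bounds = np.concatenate((starts, [atoms.array_length()]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        sub = atoms[a:b]
        cid = str(sub.chain_id[0])
        chains[cid] = Chain(
            chain_id=cid,
            coords=np.asarray(sub.coord, dtype=float),
            elements=np.asarray(sub.element, dtype=object),
            radii=_radii_for(sub.element),
            res_ids=np.asarray(sub.res_id),
            atom_names=np.asarray(sub.atom_name, dtype=object),
            b_factors=np.asarray(sub.b_factor, dtype=float)
            if "b_factor" in sub.get_annotation_categories()
            else None,
        )
    return ShellModel(chains)


def load_shell_model(path, format: str | None = None, drop_hydrogens: bool = True) -> ShellModel:
    """Load a PDB or mmCIF model; format inferred from the extension."""
    path = str(path)
    fmt = format
    if fmt is None:
        low = path.lower()
        fmt = "pdb" if low.endswith(".pdb") or low.endswith(".ent") else "mmcif"
    import warnings as _warnings

    if fmt not in ("pdb", "mmcif", "cif", "pdbx"):
        raise ValueError(f"unknown model format {fmt!r}")
    try:
        if fmt == "pdb":
            atoms = PDBFile.read(path).get_structure(model=1, extra_fields=["b_factor"])
        else:
            with _warnings.catch_warnings():
                # files written without B-factors are fine; they default to nan
                _warnings.simplefilter("ignore", UserWarning)
                atoms = get_structure(CIFFile.read(path), model=1, extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises several parse-error types
        raise ModelParseError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    return _model_from_atom_array(atoms, drop_hydrogens)


def save_shell_model(model: ShellModel, path, format: str | None = None) -> None:
    """Write the model as PDB or mmCIF (format inferred from extension)."""
    path = str(path)
    fmt = format
    if fmt is None:
        fmt = "pdb" if path.lower().endswith(".pdb") else "mmcif"
    n = model.n_atoms
    atoms = struc.AtomArray(n)
    i = 0
    for cid, ch in model.chains.items():
        sl = slice(i, i + ch.n_atoms)
        atoms.coord[sl] = ch.coords
        atoms.chain_id[sl] = cid
        atoms.element[sl] = [str(e) for e in ch.elements]
        atoms.res_id[sl] = ch.res_ids if ch.res_ids is not None else np.arange(1, ch.n_atoms + 1)
        atoms.atom_name[sl] = (
            ch.atom_names if ch.atom_names is not None else ["CA"] * ch.n_atoms
        )
        atoms.res_name[sl] = "ALA"
        atoms.hetero[sl] = False
        i += ch.n_atoms
    if fmt == "pdb":
        f = PDBFile()
        f.set_structure(atoms)
        f.write(path)
    else:
        f = CIFFile()
        set_structure(f, atoms)
        f.write(path)


def load_density_map(path) -> DensityMap:
    grid, voxel_size, origin = mrc.read_mrc(path)
    return DensityMap(grid=grid, voxel_size=voxel_size, origin=origin)


def save_density_map(dmap: DensityMap, path) -> None:
    mrc.write_mrc(path, dmap.grid, dmap.voxel_size, dmap.origin)


def fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares centre of a sphere through ``points`` (linear fit);
    falls back to the centroid for < 4 points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        return pts.mean(axis=0)
    A = np.c_[2.0 * pts, np.ones(len(pts))]
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def kabsch_rotation(P: np.ndarray, Q: np.ndarray, weights=None) -> np.ndarray:
    """Optimal rotation R (det +1) minimising ||R P - Q|| row-wise."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    w = np.ones(len(P)) if weights is None else np.asarray(weights, float)
    H = (P * w[:, None]).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _assignment_cost(dirs_rot: np.ndarray, site_dirs: np.ndarray) -> np.ndarray:
    # chordal distance matrix between rotated chain dirs and site dirs
    return np.linalg.norm(dirs_rot[:, None, :] - site_dirs[None, :, :], axis=2)


def assign_chains_to_sites(
    model: ShellModel,
    lattice: SubunitLattice,
    reference_subunit: ShellModel | None = None,
    cutoff: float = 5.0,
) -> SiteAssignment:
    """Assign model chains to lattice sites by centroid-constellation matching.

    The shell centre is estimated by a least-squares sphere fit of chain
    centroids, a global rotation into the lattice frame is found by matching
    an anchor pair of centroid directions against all compatible site-pair
    directions (Kabsch), and the chain <-> site matching is solved as an
    optimal bipartite assignment (Hungarian) on centroid distances, followed
    by one Kabsch/assignment refinement round.  Deterministic; invariant
    under chain relabelling and global rotation by construction.

    For a shell of identical subunits the constellation is ambiguous up to a
    group element; ties are broken deterministically towards the rotation
    nearest the identity (exact recovery for models already expressed in the
    lattice frame), or — when ``reference_subunit`` is given in the
    reference placement — by subunit-orientation agreement.  Every derived
    quantity (occupancy tables, measurements) is invariant under the choice
    of representative.
    """
    if model.n_chains > lattice.n_sites:
        raise ValueError(
            f"model has {model.n_chains} chains but the lattice only {lattice.n_sites} sites"
        )
    cents = model.centroids()
    # a sphere fit needs 4 non-coplanar centroids; fewer chains are assumed
    # to be already centred on the shell origin
    center = fit_sphere_center(cents) if model.n_chains >= 4 else np.zeros(3)
    rel = cents - center
    rho = np.linalg.norm(rel, axis=1)
    if np.any(rho < 1e-9):
        raise ValueError("a chain centroid coincides with the shell centre")
    dirs = rel / rho[:, None]
    site_dirs = lattice.centroids
    cids = model.chain_ids

    if model.n_chains == 1:
        site = int(np.argmax(site_dirs @ dirs[0]))
        return SiteAssignment(
            pairs={cids[0]: site}, residual=0.0, rotation=np.eye(3), center=center
        )

    # anchor pair: chain 0 and its angularly nearest neighbour
    a = 0
    cosines = dirs @ dirs[a]
    cosines[a] = -2.0
    b = int(np.argmax(cosines))
    cos_ab = float(dirs[a] @ dirs[b])

    candidates: list[tuple[float, np.ndarray]] = []
    seen = set()
    pair_cos = site_dirs @ site_dirs.T
    cand = np.argwhere(np.abs(pair_cos - cos_ab) < 0.05)
    for i, j in cand:
        if i == j:
            continue
        P = np.stack([dirs[a], dirs[b], np.cross(dirs[a], dirs[b])])
        Q = np.stack([site_dirs[i], site_dirs[j], np.cross(site_dirs[i], site_dirs[j])])
        R = kabsch_rotation(P, Q)
        key = tuple(np.round(R, 4).ravel())
        if key in seen:
            continue
        seen.add(key)
        v = dirs @ R.T
        d = _assignment_cost(v, site_dirs)
        candidates.append((float(d.min(axis=1).sum()), R))
    if not candidates:
        raise NoAssignmentError(
            "no site pair matches the anchor chain-pair geometry; "
            f"anchor cosine {cos_ab:.3f}"
        )
    best_score = min(s for s, _ in candidates)
    # keep all near-ties: a partial shell constellation is ambiguous up to a
    # group element; ties are resolved below
    tied = [R for s, R in candidates if s <= best_score + 1e-6 * max(1.0, best_score)]

    def _refine(R):
        rows = cols = None
        for _ in range(2):  # assignment + one Kabsch refinement round
            v = dirs @ R.T
            cost = _assignment_cost(v, site_dirs)
            rows, cols = linear_sum_assignment(cost)
            R = kabsch_rotation(dirs[rows], site_dirs[cols])
        v = dirs @ R.T
        resid = float(
            np.mean(rho[rows] * np.linalg.norm(v[rows] - site_dirs[cols], axis=1))
        )
        return R, rows, cols, resid

    refined = [_refine(R) for R in tied]
    best_resid = min(r[3] for r in refined)
    refined = [r for r in refined if r[3] <= best_resid + 1e-6]
    if reference_subunit is not None and len(refined) > 1:
        # disambiguate the group element by subunit orientation: predicted
        # coordinates at each site are R_site @ ref; compare with the
        # rotated model chains (the reference chain is in the lattice frame)
        ref_chain = next(iter(reference_subunit.chains.values()))
        scored = []
        for R, rows, cols, resid in refined:
            err = 0.0
            for r, c in list(zip(rows, cols))[: min(5, len(rows))]:
                ch = model.chains[cids[r]]
                n = min(ch.n_atoms, ref_chain.n_atoms)
                pred = ref_chain.coords[:n] @ lattice.site_rotations[c].T
                got = (ch.coords[:n] - center) @ R.T
                err += float(np.linalg.norm(pred - got, axis=1).mean())
            scored.append((err, R, rows, cols, resid))
        scored.sort(key=lambda t: t[0])
        _, R, rows, cols, residual = scored[0]
    else:
        # deterministic fallback: the rotation nearest the identity (exact
        # recovery for models already expressed in the lattice frame)
        refined.sort(key=lambda t: float(np.linalg.norm(t[0] - np.eye(3))))
        R, rows, cols, residual = refined[0]
    if residual > cutoff:
        raise NoAssignmentError(
            f"assignment residual {residual:.2f} Å exceeds cutoff {cutoff:.2f} Å "
            f"({model.n_chains} chains)"
        )
    pairs = {cids[r]: int(c) for r, c in zip(rows, cols)}
    model.assignment = dict(pairs)
    return SiteAssignment(pairs=pairs, residual=residual, rotation=R, center=center)
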