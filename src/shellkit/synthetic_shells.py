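"""Synthetic shells, removal-plan partial models and simulated noisy maps.

The reference shell is one asymmetric pseudo-atomic blob replicated by all
60 site rotations; with the default geometry (centroid radius 105 Å, blob
radius 9 Å) the outer diameter is ~230 Å, i.e. the ~23 nm regime of a real
T=1 shell.  Density simulation uses an isotropic Gaussian kernel whose
Fourier amplitude halves at spatial frequency 1/resolution:
``sigma = resolution * sqrt(ln 2) / (pi * sqrt(2))`` (equivalently the
spec'd ``resolution/(2*pi*sqrt(2)) * k`` with ``k = 2*sqrt(ln 2)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from shellkit.icosa_lattice import SubunitLattice
from shellkit.structure_io import Chain, DensityMap, ShellModel

__all__ = [
    "CHAIN_ALPHABET",
    "SyntheticSpec",
    "GeometryError",
    "site_chain_id",
    "make_reference_shell",
    "make_partial_model",
    "simulate_density",
    "add_map_noise",
    "kernel_sigma",
]

#: Chain id used for lattice site ``i`` (single characters keep PDB output
#: format-legal for all 60 chains).
CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class GeometryError(ValueError):
    """Raised when generated subunits overlap beyond the clash budget."""


def site_chain_id(site: int) -> str:
    return CHAIN_ALPHABET[site]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic shell + map fixture."""

    n_atoms: int = 32
    blob_radius: float = 9.0  # Å
    atom_radius: float = 1.7  # Å
    shell_radius: float = 105.0  # Å, subunit-centroid radius
    resolution: float = 4.6  # Å
    voxel_size: float = 1.5  # Å
    snr: float = 3.0
    removal_plan: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 2.0 * self.voxel_size:
            raise ValueError(
                f"resolution {self.resolution} below Nyquist (2 * voxel {self.voxel_size})"
            )
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if any(s < 0 or s > 59 for s in self.removal_plan):
            raise ValueError("removal_plan must be a subset of sites 0..59")


def kernel_sigma(resolution: float) -> float:
    """Gaussian sigma (Å) for the documented amplitude-halving convention."""
    return resolution * np.sqrt(np.log(2.0)) / (np.pi * np.sqrt(2.0))


def _blob_template(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic, orientation-detectable point blob, centred at 0."""
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=(spec.n_atoms, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = spec.blob_radius * rng.random(spec.n_atoms) ** (1.0 / 3.0)
    pts = u * r[:, None]
    return pts - pts.mean(axis=0)


def make_reference_subunit(lattice: SubunitLattice, spec: SyntheticSpec) -> ShellModel:
    """The single reference subunit in its reference placement, i.e. the
    chain of site ``s`` equals ``site_rotations[s] @ reference``.  Suitable
    as the ``reference_subunit`` of ``assign_chains_to_sites``."""
    cref = lattice.site_rotations[0].T @ lattice.centroids[0]
    template = _blob_template(spec) + cref * spec.shell_radius
    chain = Chain(
        chain_id="REF",
        coords=template,
        elements=np.array(["C"] * spec.n_atoms, dtype=object),
        radii=np.full(spec.n_atoms, spec.atom_radius),
    )
    return ShellModel({"REF": chain})


def make_reference_shell(lattice: SubunitLattice, spec: SyntheticSpec) -> ShellModel:
    """Replicate one pseudo-atomic subunit over all 60 sites.

    Chains are named by site id (``site_chain_id``); the model carries its
    ground-truth assignment.  Deterministic for a given seed.
    """
    cref = lattice.site_rotations[0].T @ lattice.centroids[0]
    template = _blob_template(spec) + cref * spec.shell_radius
    chains: dict[str, Chain] = {}
    assignment: dict[str, int] = {}
    for site in range(lattice.n_sites):
        cid = site_chain_id(site)
        coords = template @ lattice.site_rotations[site].T
        chains[cid] = Chain(
            chain_id=cid,
            coords=coords,
            elements=np.array(["C"] * spec.n_atoms, dtype=object),
            radii=np.full(spec.n_atoms, spec.atom_radius),
        )
        assignment[cid] = site
    model = ShellModel(chains, assignment=assignment)

    # clash control: fraction of atoms within 2 * atom_radius of another chain
    coords = model.all_coords()
    owner = np.repeat(np.arange(lattice.n_sites), spec.n_atoms)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.0 * spec.atom_radius, output_type="ndarray")
    clashing = pairs[owner[pairs[:, 0]] != owner[pairs[:, 1]]]
    frac = len(np.unique(clashing)) / len(coords) if len(clashing) else 0.0
    if frac > 0.10:
        raise GeometryError(
            f"{frac:.1%} of atoms clash between subunits; reduce blob_radius "
            "or increase shell_radius"
        )
    return model


def make_partial_model(model: ShellModel, removal_plan) -> ShellModel:
    """Copy of the model with the chains of the listed sites deleted."""
    plan = {int(s) for s in removal_plan}
    if model.assignment is None:
        raise ValueError("model has no site assignment")
    site_to_chain = {s: c for c, s in model.assignment.items()}
    missing = plan - set(site_to_chain)
    if missing:
        raise ValueError(f"removal plan references unoccupied sites: {sorted(missing)}")
    keep = [c for c, s in model.assignment.items() if s not in plan]
    return model.subset(keep)


def _grid_for(coords: np.ndarray, voxel_size: float, pad: float) -> tuple[np.ndarray, tuple]:
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    origin = np.floor(lo / voxel_size) * voxel_size
    shape = tuple(int(np.ceil((hi[d] - origin[d]) / voxel_size)) + 1 for d in range(3))
    return origin, shape


def simulate_density(
    model: ShellModel,
    resolution: float,
    voxel_size: float,
    like: DensityMap | None = None,
    atom_weight: float = 1.0,
) -> DensityMap:
    """Sum of per-atom normalised Gaussians on a regular grid.

    Each atom contributes ``atom_weight`` of integrated density (analytic
    Gaussian integral), so the map total is proportional to the atom count;
    the grid extends >= 5 sigma beyond the atoms unless ``like`` pins the
    geometry to an existing map.
    """
    if resolution < 2.0 * voxel_size:
        raise ValueError(
            f"resolution {resolution} below Nyquist limit 2 * voxel {voxel_size}"
        )
    sigma = kernel_sigma(resolution)
    coords_list = [c.coords for c in model.chains.values() if c.n_atoms > 0]
    if like is not None:
        origin = like.origin.copy()
        shape = like.shape
        voxel_size = like.voxel_size
    else:
        if not coords_list:
            return DensityMap(np.zeros((1, 1, 1), dtype=np.float64), voxel_size)
        allc = np.concatenate(coords_list)
        origin, shape = _grid_for(allc, voxel_size, pad=max(5.0 * sigma, 2.0 * voxel_size))
    grid = np.zeros(shape, dtype=np.float64)
    if not coords_list:
        return DensityMap(grid, voxel_size, origin)
    allc = np.concatenate(coords_list)

    amp = atom_weight / ((2.0 * np.pi) ** 1.5 * sigma**3)
    halfwidth = max(5.0 * sigma, 2.0 * voxel_size)
    nhw = int(np.ceil(halfwidth / voxel_size))
    axes = [np.arange(n) * voxel_size + origin[d] for d, n in enumerate(shape)]
    for x, y, z in allc:
        idx = []
        offs = []
        for d, pos in enumerate((x, y, z)):
            c = int(round((pos - origin[d]) / voxel_size))
            a = max(0, c - nhw)
            b = min(shape[d], c + nhw + 1)
            if a >= b:
                break
            idx.append((a, b))
            offs.append(axes[d][a:b] - pos)
        else:
            gx = np.exp(-0.5 * (offs[0] / sigma) ** 2)
            gy = np.exp(-0.5 * (offs[1] / sigma) ** 2)
            gz = np.exp(-0.5 * (offs[2] / sigma) ** 2)
            grid[idx[0][0] : idx[0][1], idx[1][0] : idx[1][1], idx[2][0] : idx[2][1]] += (
                amp * np.einsum("i,j,k->ijk", gx, gy, gz)
            )
    return DensityMap(grid, voxel_size, origin)


def add_map_noise(
    dmap: DensityMap,
    snr: float,
    seed: int,
    mask: np.ndarray | None = None,
) -> DensityMap:
    """Add i.i.d. zero-mean Gaussian noise at the requested signal-to-noise.

    ``snr`` is the ratio of the signal standard deviation *inside the shell
    mask* to the noise standard deviation (whole-box SNR would be dominated
    by solvent).  The default mask is ``grid > 5% of max``.  ``snr=inf``
    returns an unchanged copy; deterministic per seed.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return dmap.copy()
    if mask is None:
        mask = dmap.grid > 0.05 * dmap.grid.max()
    if not np.any(mask):
        raise ValueError("shell mask is empty; cannot calibrate noise")
    sigma_signal = float(dmap.grid[mask].std())
    sigma_noise = sigma_signal / snr
    rng = np.random.default_rng(seed)
    noisy = dmap.grid + rng.normal(0.0, sigma_noise, size=dmap.shape)
    return DensityMap(noisy, dmap.voxel_size, dmap.origin.copy())


def make_fixture(
    lattice: SubunitLattice,
    spec: SyntheticSpec,
) -> tuple[ShellModel, DensityMap, dict]:
    """Full fixture: partial model per the removal plan + simulated noisy map
    + ground-truth record."""
    full = make_reference_shell(lattice, spec)
    model = make_partial_model(full, spec.removal_plan) if spec.removal_plan else full
    clean = simulate_density(model, spec.resolution, spec.voxel_size)
    noisy = add_map_noise(clean, spec.snr, seed=spec.seed)
    truth = {
        "removal_plan": sorted(int(s) for s in spec.removal_plan),
        "present_sites": sorted(model.assignment.values()),
        "spec": {
            "n_atoms": spec.n_atoms,
            "blob_radius": spec.blob_radius,
            "atom_radius": spec.atom_radius,
            "shell_radius": spec.shell_radius,
            "resolution": spec.resolution,
            "voxel_size": spec.voxel_size,
            "snr": spec.snr,
            "seed": spec.seed,
        },
    }
    return model, noisy, truth


def with_removal_plan(spec: SyntheticSpec, removal_plan) -> SyntheticSpec:
    return replace(spec, removal_plan=frozenset(int(s) for s in removal_plan))
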