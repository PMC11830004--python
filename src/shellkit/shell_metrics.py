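"""Geometric and comparative shell measurements.

Diameters are measured in Å internally and reported in nm (one decimal)
only here; pore diameters stay in Å.  Pore radii are measured from
van-der-Waals surfaces along the exact symmetry axis (no off-axis search).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import biotite.sequence as seq
import biotite.sequence.align as align

from shellkit.icosa_lattice import SubunitLattice
from shellkit.structure_io import (
    ShellModel,
    SiteAssignment,
    assign_chains_to_sites,
    kabsch_rotation,
)

__all__ = [
    "ShellMeasurements",
    "AlignmentResult",
    "shell_diameters",
    "axis_pore_profile",
    "superpose_and_rmsd",
    "pairwise_sequence_identity",
]


@dataclass(frozen=True)
class ShellMeasurements:
    inner_diameter_nm: float
    outer_diameter_nm: float
    inner_diameter_angstrom: float
    outer_diameter_angstrom: float
    axis_class: str
    axis_index: int
    cylinder_radius: float
    n_atoms_in_cylinder: int

    def __post_init__(self):
        if not self.outer_diameter_angstrom >= self.inner_diameter_angstrom > 0:
            raise ValueError("need outer >= inner > 0")


def _model_frame(model, lattice, assignment):
    """(center, rotation lattice->model) for an assigned model."""
    if assignment is None:
        assignment = assign_chains_to_sites(model, lattice)
    if not isinstance(assignment, SiteAssignment):
        raise TypeError("assignment must be a SiteAssignment")
    return assignment.center, assignment.rotation.T, assignment


_AXIS_SETS = {"fivefold": "pentamer_axes", "threefold": "trimer_axes", "twofold": "dimer_axes"}


def shell_diameters(
    model: ShellModel,
    lattice: SubunitLattice,
    axis: str = "fivefold",
    assignment: SiteAssignment | None = None,
    axis_index: int = 0,
    cylinder_radius: float = 15.0,
) -> ShellMeasurements:
    """Inner/outer diameter along a symmetry axis.

    Within a cylinder of ``cylinder_radius`` around the full axis line, the
    outer diameter is twice the maximum and the inner diameter twice the
    minimum atom-centre distance from the shell centre.
    """
    if axis not in _AXIS_SETS:
        raise ValueError(f"unknown axis class {axis!r}")
    center, lat_to_model, assignment = _model_frame(model, lattice, assignment)
    ax = lat_to_model @ getattr(lattice, _AXIS_SETS[axis])[axis_index]
    xyz = model.all_coords() - center
    along = xyz @ ax
    perp = np.linalg.norm(xyz - np.outer(along, ax), axis=1)
    sel = perp <= cylinder_radius
    if not np.any(sel):
        raise ValueError("no atoms inside the axial cylinder")
    r = np.linalg.norm(xyz[sel], axis=1)
    inner, outer = 2.0 * float(r.min()), 2.0 * float(r.max())
    return ShellMeasurements(
        inner_diameter_nm=round(inner / 10.0, 1),
        outer_diameter_nm=round(outer / 10.0, 1),
        inner_diameter_angstrom=inner,
        outer_diameter_angstrom=outer,
        axis_class=axis,
        axis_index=axis_index,
        cylinder_radius=cylinder_radius,
        n_atoms_in_cylinder=int(sel.sum()),
    )


def axis_pore_profile(
    model: ShellModel,
    lattice: SubunitLattice,
    axis_class: str = "fivefold",
    assignment: SiteAssignment | None = None,
    axis_index: int = 0,
    step: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pore-radius profile along one symmetry axis.

    Returns ``(t, radius, min_diameter)``: at each axial position ``t`` (Å
    from the shell centre) the pore radius is the distance to the nearest
    atom van-der-Waals surface; the pore diameter is ``2 * min(radius)``
    over the wall crossing.
    """
    if axis_class not in _AXIS_SETS:
        raise ValueError(f"unknown axis class {axis_class!r}")
    center, lat_to_model, assignment = _model_frame(model, lattice, assignment)
    ax = lat_to_model @ getattr(lattice, _AXIS_SETS[axis_class])[axis_index]
    xyz = model.all_coords() - center
    radii = model.all_radii()
    r_atom = np.linalg.norm(xyz, axis=1)
    t = np.arange(0.3 * r_atom.min(), 1.1 * r_atom.max(), step)
    if len(t) == 0:
        raise ValueError("axis misses the model")
    pts = np.outer(t, ax)
    # surface distance to every atom, minimised per axial sample
    prof = np.empty(len(t))
    for k, p in enumerate(pts):
        prof[k] = float((np.linalg.norm(xyz - p, axis=1) - radii).min())
    if prof.min() < 0:
        # axis passes inside an atom: no open pore at this axis
        return t, prof, 0.0
    return t, prof, 2.0 * float(prof.min())


def superpose_and_rmsd(
    model_a: ShellModel,
    model_b: ShellModel,
    matching: str = "by-site",
) -> float:
    """Kabsch superposition RMSD (Å) over matched heavy atoms.

    ``by-site`` matches chains through both models' lattice-site
    assignments; ``by-chain-id`` matches equal chain ids.  Within matched
    chains atoms pair by (res_id, atom_name) when available, else by order.
    """
    if matching == "by-site":
        if model_a.assignment is None or model_b.assignment is None:
            raise ValueError("by-site matching requires assignments on both models")
        rev_b = {s: c for c, s in model_b.assignment.items()}
        chain_pairs = [
            (ca, rev_b[s]) for ca, s in model_a.assignment.items() if s in rev_b
        ]
    elif matching == "by-chain-id":
        chain_pairs = [(c, c) for c in model_a.chain_ids if c in model_b.chains]
    else:
        raise ValueError(f"unknown matching {matching!r}")
    if not chain_pairs:
        raise ValueError("no common chains/sites to superpose")
    P, Q = [], []
    for ca, cb in chain_pairs:
        A, B = model_a.chain(ca), model_b.chain(cb)
        if (
            A.res_ids is not None
            and A.atom_names is not None
            and B.res_ids is not None
            and B.atom_names is not None
        ):
            keys_a = {
                (int(r), str(n)): i
                for i, (r, n) in enumerate(zip(A.res_ids, A.atom_names))
            }
            keys_b = {
                (int(r), str(n)): i
                for i, (r, n) in enumerate(zip(B.res_ids, B.atom_names))
            }
            common = sorted(set(keys_a) & set(keys_b))
            ia = [keys_a[k] for k in common]
            ib = [keys_b[k] for k in common]
        else:
            n = min(A.n_atoms, B.n_atoms)
            ia = ib = list(range(n))
        P.append(A.coords[ia])
        Q.append(B.coords[ib])
    P = np.concatenate(P)
    Q = np.concatenate(Q)
    if len(P) < 3:
        raise ValueError("need at least 3 matched atom pairs")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    d = Pc @ R.T - Qc
    return float(np.sqrt((d * d).sum() / len(d)))


@dataclass(frozen=True)
class AlignmentResult:
    percent_identity: float
    percent_similarity: float
    aligned_columns: int
    matrix: str
    gap_open: int
    gap_extend: int

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= self.percent_similarity <= 100.0:
            raise ValueError("need 0 <= identity <= similarity <= 100")


_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


def pairwise_sequence_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = -10,
    gap_extend: int = -1,
) -> AlignmentResult:
    """Global pairwise identity/similarity between two protein sequences.

    Needleman-Wunsch with affine gaps (documented defaults: BLOSUM62,
    open -10, extend -1).  Identity = identical columns / aligned columns
    excluding terminal gaps; similarity = positively scoring columns over
    the same denominator.  Both as percentages.
    """
    for label, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        bad = [i for i, c in enumerate(str(s).upper()) if c not in _VALID_AA]
        if bad:
            raise ValueError(f"{label}: invalid residue characters at positions {bad[:10]}")
        if not s:
            raise ValueError(f"{label} is empty")
    pa = seq.ProteinSequence(str(seq_a).upper())
    pb = seq.ProteinSequence(str(seq_b).upper())
    mat = align.SubstitutionMatrix(
        seq.ProteinSequence.alphabet, seq.ProteinSequence.alphabet, matrix
    )
    aln = align.align_optimal(
        pa, pb, mat, gap_penalty=(gap_open, gap_extend), terminal_penalty=False
    )[0]
    trace = aln.trace
    inside = np.flatnonzero((trace[:, 0] >= 0) & (trace[:, 1] >= 0))
    start, stop = inside[0], inside[-1] + 1  # trim terminal gap columns
    ident = simil = 0
    ncols = stop - start
    for i, j in trace[start:stop]:
        if i >= 0 and j >= 0:
            ca, cb = str(pa[int(i)]), str(pb[int(j)])
            if ca == cb:
                ident += 1
            if ca == cb or mat.get_score(ca, cb) > 0:
                simil += 1
    return AlignmentResult(
        percent_identity=round(100.0 * ident / ncols, 1),
        percent_similarity=round(100.0 * simil / ncols, 1),
        aligned_columns=int(ncols),
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )
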