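"""Bond-angle-torsion (BAT) internal coordinates.

A molecule with N atoms has 3N degrees of freedom; anchoring the three
*root atoms* (a bonded chain r0-r1-r2) removes the 6 rigid-body DOFs and
leaves 3N-6 internal coordinates: N-1 bond lengths, N-2 planar angles and
N-3 proper dihedrals, read off a spanning tree of the bond graph.

For a binary complex, molecule 2 is attached to molecule 1 through a
non-physical *pseudobond* running from molecule 1's third root atom to
molecule 2's first root atom.  The six coordinates along that pseudobond
chain (one distance, two angles, three dihedrals) parameterize the
rigid-body position and orientation of molecule 2 in molecule 1's frame;
they are labelled subsystem ``Y`` and typed ``ext_*``.

Units: lengths in nm, angles in radians throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomTable",
    "DOFDescriptor",
    "BATTree",
    "BATTrajectory",
    "build_bat_tree",
    "join_complex",
    "cartesian_to_bat",
    "bat_to_cartesian",
    "enumerate_root_sets",
]

INTERNAL_KINDS = ("bond", "angle", "torsion")
EXTERNAL_KINDS = ("ext_bond", "ext_angle", "ext_torsion")
PERIODIC_KINDS = ("torsion", "ext_torsion")

#: mass (u) below which an atom is treated as hydrogen-like when ranking
#: root-atom candidates
_HEAVY_MASS_CUTOFF = 3.5


@dataclass(frozen=True)
class AtomTable:
    """Atom identities and masses (u); indices are implicit 0..N-1."""

    names: tuple[str, ...]
    masses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.masses):
            raise ValueError("names and masses must have equal length")
        if any(m <= 0 for m in self.masses):
            raise ValueError("all atomic masses must be positive")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_masses(cls, masses, names=None) -> "AtomTable":
        masses = tuple(float(m) for m in masses)
        if names is None:
            names = tuple(f"X{i}" for i in range(len(masses)))
        return cls(tuple(names), masses)


@dataclass(frozen=True)
class DOFDescriptor:
    """One internal or external degree of freedom.

    ``atom_quad`` holds 2 atoms for bonds, 3 for angles, 4 for torsions;
    the first atom is the one being placed, the remainder its reference
    frame (parent, grandparent, torsion reference).
    """

    kind: str
    atom_quad: tuple[int, ...]
    subsystem: str = "A"
    periodic: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.kind not in INTERNAL_KINDS + EXTERNAL_KINDS:
            raise ValueError(f"unknown DOF kind {self.kind!r}")
        if (self.kind in EXTERNAL_KINDS) != (self.subsystem == "Y"):
            raise ValueError("ext_* kinds must carry subsystem 'Y' and vice versa")
        object.__setattr__(self, "periodic", self.kind in PERIODIC_KINDS)

    @property
    def is_external(self) -> bool:
        return self.kind in EXTERNAL_KINDS


@dataclass(frozen=True)
class BATTree:
    """Spanning-tree BAT coordinate system over one molecule or a complex.

    ``placements`` lists, in deterministic breadth-first order, the frame
    ``(atom, parent, grandparent, torsion_ref)`` used to position every
    non-root atom; it drives both directions of the coordinate transform.
    """

    atoms: AtomTable
    bonds: frozenset[tuple[int, int]]
    root_atoms: tuple[int, int, int]
    dofs: tuple[DOFDescriptor, ...]
    molecule_of_atom: tuple[int, ...]
    placements: tuple[tuple[int, int, int, int], ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    @property
    def is_complex(self) -> bool:
        return any(d.is_external for d in self.dofs)

    def subsystem_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, d in enumerate(self.dofs) if d.subsystem == label], dtype=int)

    def offset_atoms(self, offset: int) -> "BATTree":
        """Shift every atom index by ``offset`` (for joining into a complex)."""
        shift = lambda t: tuple(a + offset for a in t)  # noqa: E731
        return BATTree(
            atoms=self.atoms,
            bonds=frozenset(tuple(sorted(shift(b))) for b in self.bonds),
            root_atoms=shift(self.root_atoms),
            dofs=tuple(replace(d, atom_quad=shift(d.atom_quad)) for d in self.dofs),
            molecule_of_atom=self.molecule_of_atom,
            placements=tuple(shift(p) for p in self.placements),
        )


@dataclass
class BATTrajectory:
    """Frames x DOFs matrix of BAT values with per-DOF metadata."""

    values: np.ndarray
    dofs: tuple[DOFDescriptor, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.dofs):
            raise ValueError(
                f"values must be (frames, {len(self.dofs)}), got {self.values.shape}"
            )

    @property
    def frame_count(self) -> int:
        return self.values.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.values.shape[1]

    def subsystem_labels(self) -> np.ndarray:
        return np.array([d.subsystem for d in self.dofs])

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i]


def _adjacency(n_atoms: int, bonds) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        if i == j or not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise ValueError(f"invalid bond ({i}, {j}) for {n_atoms} atoms")
        adj[i].append(j)
        adj[j].append(i)
    for nb in adj:
        nb.sort()
    return adj


def _connected_components(n_atoms: int, adj) -> list[list[int]]:
    seen = [False] * n_atoms
    comps = []
    for start in range(n_atoms):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in adj[a]:
                if not seen[b]:
                    seen[b] = True
                    stack.append(b)
        comps.append(sorted(comp))
    return comps


def build_bat_tree(atoms: AtomTable, bonds, root_atoms) -> BATTree:
    """Build the 3N-6 DOF BAT tree of a single connected molecule.

    The spanning tree is grown breadth-first from the root triple with
    ties broken by atom index, so the DOF ordering is a deterministic
    function of (topology, roots).  DOF layout: the three root-block
    coordinates ``bond(r0,r1), bond(r1,r2), angle(r0,r1,r2)`` first, then
    one ``(bond, angle, torsion)`` triple per placed atom.
    """
    n = len(atoms)
    if n < 3:
        raise ValueError("need at least 3 atoms for a BAT coordinate system")
    bond_set = frozenset(tuple(sorted((int(i), int(j)))) for i, j in bonds)
    adj = _adjacency(n, bond_set)
    comps = _connected_components(n, adj)
    if len(comps) > 1:
        raise ValueError(
            f"bond graph is disconnected: {len(comps)} components {comps[:4]}"
        )
    r0, r1, r2 = (int(a) for a in root_atoms)
    if len({r0, r1, r2}) != 3:
        raise ValueError("root atoms must be three distinct atoms")
    if tuple(sorted((r0, r1))) not in bond_set or tuple(sorted((r1, r2))) not in bond_set:
        raise ValueError(f"root atoms ({r0}, {r1}, {r2}) do not form a bonded chain")

    parent = {r0: -1, r1: -1, r2: -1}
    order = [r0, r1, r2]  # BFS placement order over the spanning tree
    queue = [r0, r1, r2]
    qi = 0
    while qi < len(queue):
        a = queue[qi]
        qi += 1
        for b in adj[a]:
            if b not in parent:
                parent[b] = a
                order.append(b)
                queue.append(b)

    first_child: dict[int, int] = {}
    placements: list[tuple[int, int, int, int]] = []
    roots = (r0, r1, r2)

    def _frame(a: int, p: int) -> tuple[int, int]:
        """Return (q, t): angle and torsion reference atoms for placing a."""
        if p == r0:
            q, t_anc = r1, r2
        elif p == r1:
            q, t_anc = r2, r0
        elif p == r2:
            q, t_anc = r1, r0
        else:
            q = parent[p]
            if q == r0:
                t_anc = r1
            elif q == r1:
                t_anc = r2
            elif q == r2:
                t_anc = r1
            else:
                t_anc = parent[q]
        if p in first_child:
            # later branch children measure their dihedral against the
            # first-placed sibling instead of the ancestor chain
            t = first_child[p]
        else:
            t = t_anc
        return q, t

    dofs: list[DOFDescriptor] = [
        DOFDescriptor("bond", (r0, r1)),
        DOFDescriptor("bond", (r1, r2)),
        DOFDescriptor("angle", (r0, r1, r2)),
    ]
    for a in order[3:]:
        p = parent[a]
        q, t = _frame(a, p)
        dofs.append(DOFDescriptor("bond", (a, p)))
        dofs.append(DOFDescriptor("angle", (a, p, q)))
        dofs.append(DOFDescriptor("torsion", (a, p, q, t)))
        placements.append((a, p, q, t))
        first_child.setdefault(p, a)

    assert len(dofs) == 3 * n - 6
    return BATTree(
        atoms=atoms,
        bonds=bond_set,
        root_atoms=roots,
        dofs=tuple(dofs),
        molecule_of_atom=tuple([1] * n),
        placements=tuple(placements),
    )


def join_complex(tree_A: BATTree, tree_B: BATTree, root_atoms_B) -> BATTree:
    """Join two molecules into one complex coordinate system.

    Molecule B keeps its 3N_B-6 internal DOFs (rebuilt from
    ``root_atoms_B`` if those differ from B's current roots) and gains 6
    pseudobond DOFs labelled ``Y``: its rigid-body placement in A's frame,
    anchored at A's third root atom.  Atom indices of the two trees must
    already be disjoint (see :meth:`BATTree.offset_atoms`).
    """
    a_atoms = {a for b in tree_A.bonds for a in b} | set(tree_A.root_atoms)
    b_atoms = {a for b in tree_B.bonds for a in b} | set(tree_B.root_atoms)
    overlap = a_atoms & b_atoms
    if overlap:
        raise ValueError(
            f"atom indices overlap between molecules (e.g. {sorted(overlap)[:5]}); "
            "re-index molecule B with offset_atoms() first"
        )
    root_atoms_B = tuple(int(a) for a in root_atoms_B)
    if root_atoms_B != tree_B.root_atoms:
        # roots determine B's internal DOF list; rebuild in B-local indices
        b_sorted = sorted(b_atoms)
        offset = b_sorted[0]
        if b_sorted != list(range(offset, offset + len(b_sorted))):
            raise ValueError("molecule B atom indices must be contiguous")
        local_bonds = [(i - offset, j - offset) for i, j in tree_B.bonds]
        local_roots = tuple(a - offset for a in root_atoms_B)
        tree_B = build_bat_tree(tree_B.atoms, local_bonds, local_roots).offset_atoms(offset)

    rA0, rA1, rA2 = tree_A.root_atoms
    b0, b1, b2 = tree_B.root_atoms
    anchor = rA2  # molecule-1 anchor: its third root atom

    ext = [
        DOFDescriptor("ext_bond", (b0, anchor), "Y"),
        DOFDescriptor("ext_angle", (b0, anchor, rA1), "Y"),
        DOFDescriptor("ext_torsion", (b0, anchor, rA1, rA0), "Y"),
        DOFDescriptor("ext_angle", (b1, b0, anchor), "Y"),
        DOFDescriptor("ext_torsion", (b1, b0, anchor, rA1), "Y"),
        DOFDescriptor("ext_torsion", (b2, b1, b0, anchor), "Y"),
    ]
    dofs = (
        tuple(replace(d, subsystem="A") for d in tree_A.dofs)
        + tuple(replace(d, subsystem="B") for d in tree_B.dofs)
        + tuple(ext)
    )
    # placement order: A as before, then B's roots off the pseudobond,
    # then B's interior
    placements = (
        tree_A.placements
        + ((b0, anchor, rA1, rA0), (b1, b0, anchor, rA1), (b2, b1, b0, anchor))
        + tree_B.placements
    )
    atoms = AtomTable(
        tree_A.atoms.names + tree_B.atoms.names,
        tree_A.atoms.masses + tree_B.atoms.masses,
    )
    molecule_of = tuple([1] * tree_A.n_atoms + [2] * tree_B.n_atoms)
    return BATTree(
        atoms=atoms,
        bonds=tree_A.bonds | tree_B.bonds,
        root_atoms=tree_A.root_atoms,
        dofs=dofs,
        molecule_of_atom=molecule_of,
        placements=placements,
    )


def _bond_lengths(x: np.ndarray, quads) -> np.ndarray:
    a, p = quads[:, 0], quads[:, 1]
    return np.linalg.norm(x[:, a, :] - x[:, p, :], axis=-1)


def _angles(x: np.ndarray, quads, tol: float = 1e-8) -> np.ndarray:
    a, p, q = quads[:, 0], quads[:, 1], quads[:, 2]
    u = x[:, a, :] - x[:, p, :]
    v = x[:, q, :] - x[:, p, :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident bonded atoms encountered")
    cosang = np.einsum("fij,fij->fi", u, v) / (nu * nv)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.arccos(cosang)
    bad = (ang < tol) | (np.pi - ang < tol)
    if np.any(bad):
        f, i = np.argwhere(bad)[0]
        raise ValueError(f"collinear angle atoms (frame {f}, angle DOF #{i})")
    return ang


def _dihedrals(x: np.ndarray, quads) -> np.ndarray:
    """Signed IUPAC dihedral in [-pi, pi) for atom sequences (a, p, q, t)."""
    a, p, q, t = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    b1 = x[:, p, :] - x[:, a, :]
    b2 = x[:, q, :] - x[:, p, :]
    b3 = x[:, t, :] - x[:, q, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    y = np.einsum("fij,fij->fi", m, n2)
    c = np.einsum("fij,fij->fi", n1, n2)
    phi = np.arctan2(y, c)
    # convention: half-open interval, pi maps to -pi
    phi[phi >= np.pi] = -np.pi
    return phi


def cartesian_to_bat(frames: np.ndarray, tree: BATTree) -> BATTrajectory:
    """Convert Cartesian frames (frames, atoms, 3) to BAT coordinates.

    Internal DOFs are invariant under rigid rototranslation of the input;
    external (Y) DOFs measure molecule 2 in molecule 1's frame and change
    accordingly.
    """
    x = np.asarray(frames, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != tree.n_atoms or x.shape[2] != 3:
        raise ValueError(
            f"frames must be (F, {tree.n_atoms}, 3), got {x.shape}"
        )
    values = np.empty((x.shape[0], tree.n_dofs))
    by_len: dict[int, list[int]] = {2: [], 3: [], 4: []}
    for i, d in enumerate(tree.dofs):
        by_len[len(d.atom_quad)].append(i)
    for nlen, idx in by_len.items():
        if not idx:
            continue
        quads = np.array([tree.dofs[i].atom_quad for i in idx], dtype=int)
        if nlen == 2:
            vals = _bond_lengths(x, quads)
        elif nlen == 3:
            vals = _angles(x, quads)
        else:
            vals = _dihedrals(x, quads)
        values[:, idx] = vals
    if np.any(values[:, [i for i in by_len[2]]] <= 0):
        raise ValueError("non-positive bond length encountered")
    return BATTrajectory(values, tree.dofs)


def _place_atom(pa, pb, pc, b, theta, phi):
    """NeRF placement: position atom d with bond d-c = b, angle d-c-b =
    theta and dihedral d-c-b-a = phi, given positions pa, pb, pc."""
    bc = pc - pb
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = pb - pa
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    b = np.asarray(b)[..., None]
    theta = np.asarray(theta)[..., None]
    phi = np.asarray(phi)[..., None]
    d_local = b * (
        -np.cos(theta) * bc + np.sin(theta) * (np.cos(phi) * m - np.sin(phi) * n)
    )
    return pc + d_local


def bat_to_cartesian(traj: BATTrajectory, tree: BATTree) -> np.ndarray:
    """Reconstruct Cartesian frames from BAT values (forward kinematics).

    The anchor convention places r0 at the origin, r1 on the +z axis and
    r2 in the xz half-plane; internal coordinates are therefore exactly
    reproduced by a following :func:`cartesian_to_bat` round trip.
    """
    vals = traj.values
    if vals.shape[1] != tree.n_dofs:
        raise ValueError("trajectory/tree DOF count mismatch")
    value_of = {d.atom_quad: vals[:, i] for i, d in enumerate(tree.dofs)}
    F = vals.shape[0]
    x = np.zeros((F, tree.n_atoms, 3))
    r0, r1, r2 = tree.root_atoms
    b01 = value_of[(r0, r1)]
    b12 = value_of[(r1, r2)]
    th = value_of[(r0, r1, r2)]
    x[:, r1, 2] = b01
    x[:, r2, 0] = b12 * np.sin(th)
    x[:, r2, 2] = b01 - b12 * np.cos(th)

    for (a, p, q, t) in tree.placements:
        # B-root placements reuse molecule-internal bond/angle values
        # under a reversed quad (e.g. the angle at b1 between b0 and b2)
        bond = value_of.get((a, p))
        if bond is None:
            bond = value_of.get((p, a))
        angle = value_of.get((a, p, q))
        if angle is None:
            angle = value_of.get((q, p, a))
        phi = value_of[(a, p, q, t)]
        if bond is None or angle is None:
            raise KeyError(f"missing DOF values to place atom {a}")
        x[:, a, :] = _place_atom(x[:, t, :], x[:, q, :], x[:, p, :], bond, angle, phi)
    return x


def enumerate_root_sets(tree: BATTree, n_sets: int = 5) -> list[tuple[int, int, int]]:
    """Deterministically enumerate bonded root-atom triples.

    Triples are canonicalized (first index < last index) and ranked by
    (number of light atoms in the triple, atom indices), so heavy-atom
    chains come first and the list is stable across runs.  If fewer than
    ``n_sets`` distinct triples exist, all are returned with a warning.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    adj = _adjacency(tree.n_atoms, tree.bonds)
    masses = tree.atoms.masses
    triples = []
    for j in range(tree.n_atoms):
        for i in adj[j]:
            for k in adj[j]:
                if i < k:
                    light = sum(1 for a in (i, j, k) if masses[a] < _HEAVY_MASS_CUTOFF)
                    triples.append((light, (i, j, k)))
    triples.sort()
    out = [t for _, t in triples]
    if len(out) < n_sets:
        warnings.warn(
            f"only {len(out)} distinct bonded triples available (requested {n_sets})",
            stacklevel=2,
        )
        return out
    return out[:n_sets]
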