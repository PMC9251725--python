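"""File formats, configuration and report writing.

Internal conventions: lengths in nm (PDB Angstrom converted on read),
angles in radians, entropies in units of R.  Unit conversions to
J mol^-1 K^-1 and -T*dS kJ mol^-1 happen only here, at the reporting
boundary.  Reports carry the full configuration echo and seeds and no
timestamps, so identical inputs give byte-identical output.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .decomposition import (BindingEntropyResults, ConvergenceSeries,
                            DecompositionResult, SpanTable, TERM_NAMES)
from .estimators import HistogramSpec, R_GAS
from .topology import AtomTable

__all__ = [
    "AnalysisConfig",
    "read_topology",
    "write_topology",
    "read_psf",
    "read_trajectory",
    "write_trajectory",
    "write_report",
    "save_entropy_archive",
]

DIALECTS = ("plain_matrix", "pdb_models", "xtc", "dcd")


@dataclass
class AnalysisConfig:
    """Flat analysis configuration with field-stable defaults."""

    temperature: float = 300.0            # K
    standard_concentration: float = 1.0   # mol/L
    bins_1d: int = 50
    bins_2d: int = 50
    n_root_sets: int = 5
    n_blocks: int = 10
    seed: int = 0
    dialect: str = "plain_matrix"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; "
                             f"choose from {DIALECTS}")

    @property
    def histogram(self) -> HistogramSpec:
        return HistogramSpec(bins_1d=self.bins_1d, bins_2d=self.bins_2d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Parse a flat ``key = value`` config file ('#' comments)."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def show(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in self.to_dict().items())


# ---------------------------------------------------------------- topology

def read_topology(path):
    """Read the plain-text topology: atom lines ``index name mass`` and
    bond lines ``i j`` (optionally under ``[atoms]``/``[bonds]`` headers).

    Returns ``(AtomTable, bonds)``; atom indices must be contiguous from 0.
    """
    atoms: dict[int, tuple[str, float]] = {}
    bonds: list[tuple[int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("["):
            continue
        parts = line.split()
        if len(parts) == 3:
            idx, name, mass = int(parts[0]), parts[1], float(parts[2])
            if idx in atoms:
                raise ValueError(f"{path}:{lineno}: duplicate atom index {idx}")
            atoms[idx] = (name, mass)
        elif len(parts) == 2:
            bonds.append((int(parts[0]), int(parts[1])))
        else:
            raise ValueError(f"{path}:{lineno}: expected 'index name mass' "
                             f"or 'i j', got {raw!r}")
    if sorted(atoms) != list(range(len(atoms))):
        raise ValueError(f"{path}: atom indices must be contiguous from 0")
    names = tuple(atoms[i][0] for i in range(len(atoms)))
    masses = tuple(atoms[i][1] for i in range(len(atoms)))
    return AtomTable(names, masses), bonds


def write_topology(path, atoms: AtomTable, bonds) -> None:
    with open(path, "w") as fh:
        fh.write("[atoms]\n")
        for i, (name, mass) in enumerate(zip(atoms.names, atoms.masses)):
            fh.write(f"{i} {name} {mass:.6f}\n")
        fh.write("[bonds]\n")
        for i, j in sorted(tuple(sorted(b)) for b in bonds):
            fh.write(f"{i} {j}\n")


def read_psf(path):
    """Minimal PSF reader: only the !NATOM and !NBOND sections are used.

    Atom lines follow the X-PLOR layout ``id segid resid resname name
    type charge mass ...``; indices are converted to 0-based.
    """
    lines = Path(path).read_text().splitlines()
    names, masses, bonds = [], [], []
    i = 0
    while i < len(lines):
        header = lines[i]
        if "!NATOM" in header:
            n = int(header.split()[0])
            for j in range(1, n + 1):
                parts = lines[i + j].split()
                names.append(parts[4])
                masses.append(float(parts[7]))
            i += n
        elif "!NBOND" in header:
            nb = int(header.split()[0])
            ints: list[int] = []
            while len(ints) < 2 * nb:
                i += 1
                ints.extend(int(t) for t in lines[i].split())
            bonds = [(ints[k] - 1, ints[k + 1] - 1)
                     for k in range(0, 2 * nb, 2)]
        i += 1
    if not names:
        raise ValueError(f"{path}: no !NATOM section found")
    return AtomTable(tuple(names), tuple(masses)), bonds


# -------------------------------------------------------------- trajectory

def read_trajectory(path, dialect: str = "plain_matrix", top=None,
                    n_atoms: int | None = None) -> np.ndarray:
    """Read Cartesian frames as (frames, atoms, 3) in nm.

    ``plain_matrix``: one frame per line of 3N floats (nm).
    ``pdb_models``: multi-model PDB (Angstrom, converted).
    ``xtc``/``dcd``: optional, via mdtraj; needs ``top`` (a PDB path).
    """
    if dialect == "plain_matrix":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] % 3:
            raise ValueError(
                f"{path}: row length {data.shape[1]} is not a multiple of 3")
        frames = data.reshape(data.shape[0], -1, 3)
    elif dialect == "pdb_models":
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(str(path))
        try:
            coords = pdb.get_coord(model=None)  # (models, atoms, 3), Angstrom
        except Exception as exc:
            raise ValueError(
                f"{path}: inconsistent atom counts across models ({exc})"
            ) from exc
        frames = np.asarray(coords, dtype=float) / 10.0
    elif dialect in ("xtc", "dcd"):
        try:
            import mdtraj
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ImportError(
                f"the {dialect!r} dialect requires the optional mdtraj "
                "package") from exc
        if top is None:
            raise ValueError(f"the {dialect!r} dialect needs top= (a PDB path)")
        frames = np.asarray(mdtraj.load(str(path), top=str(top)).xyz,
                            dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if n_atoms is not None and frames.shape[1] != n_atoms:
        raise ValueError(f"{path}: expected {n_atoms} atoms per frame, "
                         f"got {frames.shape[1]}")
    return frames


def write_trajectory(path, frames, dialect: str = "plain_matrix",
                     atoms: AtomTable | None = None) -> None:
    """Write Cartesian frames; plain matrix uses full float precision so
    a read-back is bit-identical."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be (F, N, 3)")
    if dialect == "plain_matrix":
        np.savetxt(path, frames.reshape(frames.shape[0], -1), fmt="%.17g")
    elif dialect == "pdb_models":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile
        n = frames.shape[1]
        arr = struc.AtomArrayStack(frames.shape[0], n)
        arr.coord = frames * 10.0
        arr.atom_name = ([a[:4] for a in atoms.names] if atoms is not None
                         else ["C"] * n)
        arr.element = ["C"] * n
        arr.res_id = np.ones(n, dtype=int)
        arr.res_name = ["MOL"] * n
        arr.chain_id = ["A"] * n
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(str(path))
    else:
        raise ValueError(f"unsupported write dialect {dialect!r}")


# ----------------------------------------------------------------- reports

def _decomposition_payload(result: DecompositionResult,
                           config: AnalysisConfig | None) -> dict:
    terms = result.term_dict()
    T = result.temperature
    return {
        "software": f"batropy {__version__}",
        "schema": "batropy.decomposition/1",
        "temperature_K": T,
        "standard_concentration_mol_per_L": result.standard_concentration,
        "n_dofs": result.n_dofs,
        "root_set_B": list(result.root_set_B) if result.root_set_B else None,
        "clamped_mi_total_R": result.clamped_mi_total,
        "config": config.to_dict() if config is not None else None,
        "terms_R": terms,
        "terms_J_per_mol_K": {k: v * R_GAS for k, v in terms.items()},
        "minus_T_dS_kJ_per_mol": {k: -T * v * R_GAS / 1000.0
                                  for k, v in terms.items()},
    }


def write_report(result, path, format: str = "json",
                 config: AnalysisConfig | None = None) -> None:
    """Serialize a result object to JSON or CSV.

    Accepts a :class:`DecompositionResult` (or fitted results), a
    :class:`SpanTable` (CSV rows = complexes) or a
    :class:`ConvergenceSeries` (CSV rows = blocks).
    """
    if format not in ("json", "csv"):
        raise ValueError("format must be 'json' or 'csv'")
    if isinstance(result, BindingEntropyResults):
        result = result.result
    path = Path(path)

    if isinstance(result, DecompositionResult):
        payload = _decomposition_payload(result, config)
        if format == "json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            buf = _io.StringIO()
            buf.write("term,value_R,value_J_per_mol_K,minus_T_dS_kJ_per_mol\n")
            for k, v in payload["terms_R"].items():
                buf.write(f"{k},{v!r},{payload['terms_J_per_mol_K'][k]!r},"
                          f"{payload['minus_T_dS_kJ_per_mol'][k]!r}\n")
            path.write_text(buf.getvalue())
    elif isinstance(result, SpanTable):
        if format == "json":
            payload = {
                "software": f"batropy {__version__}",
                "schema": "batropy.spans/1",
                "normalized_by_dofs": result.normalized_by_dofs,
                "spans_R": result.spans.to_dict(),
                "percent_of_total_span": result.percent.to_dict(),
                "per_complex": result.per_complex.to_dict(orient="records"),
                "config": config.to_dict() if config is not None else None,
            }
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            result.per_complex.to_csv(path, index=False)
    elif isinstance(result, ConvergenceSeries):
        if format == "json":
            payload = {
                "software": f"batropy {__version__}",
                "schema": "batropy.convergence/1",
                "shuffled": result.shuffled,
                "seed": result.seed,
                "block_ends": result.block_ends.tolist(),
                "terms_R": {k: v.tolist() for k, v in result.terms.items()},
                "config": config.to_dict() if config is not None else None,
            }
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        else:
            result.to_frame().to_csv(path, index=False)
    else:
        raise TypeError(f"cannot write a report for {type(result).__name__}")


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())


def save_entropy_archive(path, s1d, mi_matrix, dof_kinds, subsystems) -> None:
    """Store per-DOF entropies and the MI matrix in an HDF5 archive."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.attrs["software"] = f"batropy {__version__}"
        h5.create_dataset("s1d_R", data=np.asarray(s1d, float))
        h5.create_dataset("mi_R", data=np.asarray(
            mi_matrix.values if hasattr(mi_matrix, "values") else mi_matrix,
            float))
        str_dt = h5py.string_dtype()
        h5.create_dataset("dof_kind", data=list(dof_kinds), dtype=str_dt)
        h5.create_dataset("subsystem", data=list(subsystems), dtype=str_dt)
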