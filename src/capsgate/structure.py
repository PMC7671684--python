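"""Structural "molecular ruler" metrics.

Atomic models are held as biotite ``AtomArray`` objects wrapped in a thin
:class:`StructureModel`; superposition (Kabsch), segment-anchored per-residue
RMSD, and inter-residue minimum distances are implemented here.

Residue numbering: measurements are reported against the numbering in the
PDB records, 1-based, with an optional offset for species conventions (the
functional work numbers mouse residues, which sit one higher than the rat
cryo-EM structures: mouse T551/E571 correspond to structure T550/E570, so
``offset = -1`` maps mouse numbers onto those structures).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import MissingAtomError, PairingError, ParameterError, PDBParseError

#: Bondi van der Waals radii (Å) by element symbol.
BONDI_VDW = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Sidechain oxygen atoms per residue type, used for hydrogen-bond rulers.
SIDECHAIN_OXYGENS = {
    "THR": ("OG1",), "SER": ("OG",), "TYR": ("OH",),
    "GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",), "ASN": ("OD1",),
}


@dataclass
class StructureModel:
    """Parsed atomic coordinates plus source metadata."""

    atoms: struc.AtomArray
    meta: dict = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def mask(self, chain: str | None = None,
             res_range: tuple[int, int] | None = None,
             res_ids=None, atom_names=None) -> np.ndarray:
        a = self.atoms
        m = np.ones(self.n_atoms, bool)
        if chain is not None:
            m &= a.chain_id == chain
        if res_range is not None:
            m &= (a.res_id >= res_range[0]) & (a.res_id <= res_range[1])
        if res_ids is not None:
            m &= np.isin(a.res_id, list(res_ids))
        if atom_names is not None:
            m &= np.isin(a.atom_name, list(atom_names))
        return m

    def subset(self, **kw) -> "StructureModel":
        return StructureModel(self.atoms[self.mask(**kw)], dict(self.meta))

    def transformed(self, rotation: np.ndarray,
                    translation=(0.0, 0.0, 0.0)) -> "StructureModel":
        """Rigidly transformed copy: x -> R x + t."""
        out = self.atoms.copy()
        out.coord = self.atoms.coord @ np.asarray(rotation, float).T \
            + np.asarray(translation, float)
        return StructureModel(out, dict(self.meta))

    def chains(self) -> list:
        return sorted(set(self.atoms.chain_id))

    def to_pdb_text(self) -> str:
        f = PDBFile()
        f.set_structure(self.atoms)
        buf = io.StringIO()
        f.write(buf)
        return buf.getvalue()

    def write_pdb(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_pdb_text())


def _validate_coordinates(text: str):
    """Line-numbered check of the fixed coordinate columns before parsing."""
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(
                    f"line {ln}: truncated ATOM/HETATM record "
                    f"({len(line)} chars, need 54)", line_number=ln)
            for lo, hi, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"line {ln}: malformed {name} coordinate "
                        f"{fieldtxt!r}", line_number=ln) from None


def read_structure(source, keep_hydrogens: bool = False) -> StructureModel:
    """Parse fixed-column PDB text (or a path) into a StructureModel.

    Only the first MODEL block is used (a warning is emitted for the rest);
    for alternate locations the highest-occupancy conformer is kept (ties
    resolve to the first, i.e. altloc 'A'); hydrogens are dropped by default
    since cryo-EM models lack them.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and source.endswith(".pdb"):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in text.splitlines()):
        raise PDBParseError("no ATOM/HETATM records in input")
    _validate_coordinates(text)
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models > 1:
        warnings.warn(
            f"PDB contains {n_models} MODEL blocks; using the first only",
            UserWarning, stacklevel=2)
    try:
        atoms = pdb.get_structure(model=1, altloc="occupancy",
                                  extra_fields=["occupancy"])
    except Exception as e:  # biotite's own parse failures
        raise PDBParseError(f"PDB parsing failed: {e}") from e
    if not keep_hydrogens:
        atoms = atoms[atoms.element != "H"]
    title = " ".join(pdb.lines[i][10:].strip()
                     for i in range(len(pdb.lines))
                     if pdb.lines[i].startswith("TITLE")) or None
    return StructureModel(atoms, {"title": title, "n_models": n_models})


def write_structure(model: StructureModel, path=None):
    """Serialize to fixed-column PDB text (returned, or written to ``path``)."""
    if path is None:
        return model.to_pdb_text()
    model.write_pdb(path)
    return None


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mobile -> reference with its selection RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _atom_key_frame(model: StructureModel, m: np.ndarray) -> pd.DataFrame:
    a = model.atoms[m]
    return pd.DataFrame({
        "chain": a.chain_id, "res": a.res_id, "atom": a.atom_name,
        "x": a.coord[:, 0], "y": a.coord[:, 1], "z": a.coord[:, 2],
    })


def paired_coords(mobile: StructureModel, reference: StructureModel,
                  **selection) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms common to both structures, in matched order.

    Atoms are identified by (chain, residue number, atom name).
    """
    fm = _atom_key_frame(mobile, mobile.mask(**selection))
    fr = _atom_key_frame(reference, reference.mask(**selection))
    merged = fm.merge(fr, on=["chain", "res", "atom"], suffixes=("_m", "_r"))
    if len(merged) == 0:
        raise PairingError(
            "selection resolves to no atom pairs common to both structures")
    xm = merged[["x_m", "y_m", "z_m"]].to_numpy()
    xr = merged[["x_r", "y_r", "z_r"]].to_numpy()
    return xm, xr


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (Kabsch, via SVD)."""
    P = np.asarray(mobile_xyz, float)
    Q = np.asarray(reference_xyz, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("coordinate arrays must be matching (n, 3)")
    if P.shape[0] < 3:
        raise PairingError("need at least 3 paired atoms for superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    if np.linalg.matrix_rank(H) < 2:
        raise PairingError("degenerate (collinear) selection: rank-deficient")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(R, t, rmsd, P.shape[0])


def superpose_kabsch(mobile: StructureModel, reference: StructureModel,
                     **selection) -> tuple[Superposition, StructureModel]:
    """Superpose ``mobile`` onto ``reference`` over a selection.

    Selection keywords are those of :meth:`StructureModel.mask` (chain,
    res_range, res_ids, atom_names); the transform is fitted on the selected
    paired atoms and applied to the whole mobile structure.
    """
    xm, xr = paired_coords(mobile, reference, **selection)
    sp = kabsch(xm, xr)
    return sp, mobile.transformed(sp.rotation, sp.translation)


# ---------------------------------------------------------------------------
# Per-residue RMSD
# ---------------------------------------------------------------------------


@dataclass
class RmsdProfile:
    """Per-residue RMSD (Å) against a reference after segment-anchored alignment.

    Missing residues are reported as NaN gaps, never as zeros.
    """

    res_ids: np.ndarray
    rmsd_A: np.ndarray
    align_descriptor: str = ""
    atom_set: tuple = BACKBONE_ATOMS
    alignment_rmsd: float = np.nan

    def to_tsv(self, path_or_buf=None):
        df = pd.DataFrame({"residue": self.res_ids, "rmsd_A": self.rmsd_A})
        return df.to_csv(path_or_buf, sep="\t", index=False,
                         float_format="%.4f")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.res_ids, self.rmsd_A, "o-")
        ax.set_xlabel("residue")
        ax.set_ylabel("backbone RMSD (Å)")
        return ax


def per_residue_rmsd(mobile: StructureModel, reference: StructureModel,
                     analyze: tuple[int, int], align: tuple[int, int],
                     atom_set=BACKBONE_ATOMS,
                     chain: str | None = None) -> RmsdProfile:
    """Segment-anchored per-residue RMSD.

    The mobile structure is superposed on the reference over the ``align``
    residue range (e.g. the S4 segment) with the given atom set, then the
    RMSD of each residue in ``analyze`` is computed over the same atom set
    with no per-residue re-fitting.
    """
    sp, moved = superpose_kabsch(mobile, reference, chain=chain,
                                 res_range=align, atom_names=atom_set)
    res_ids = np.arange(analyze[0], analyze[1] + 1)
    out = np.full(res_ids.size, np.nan)
    for k, rid in enumerate(res_ids):
        try:
            xm, xr = paired_coords(moved, reference, chain=chain,
                                   res_ids=[rid], atom_names=atom_set)
        except PairingError:
            continue  # gap
        out[k] = float(np.sqrt(np.mean(np.sum((xm - xr) ** 2, axis=1))))
    return RmsdProfile(res_ids, out,
                       align_descriptor=f"res {align[0]}-{align[1]}"
                                        + (f" chain {chain}" if chain else ""),
                       atom_set=tuple(atom_set), alignment_rmsd=sp.rmsd)


# ---------------------------------------------------------------------------
# Inter-residue distances (hydrogen-bond rulers)
# ---------------------------------------------------------------------------


def residue_min_distance(model: StructureModel,
                         resA: tuple, resB: tuple) -> dict:
    """Minimum pairwise distance between two residues' atom subsets, in Å.

    ``resA``/``resB`` are ``(chain or None, residue number, atom names or
    None)``; ``None`` atom names default to the residue's sidechain oxygens
    (the hydrogen-bond donors/acceptors of interest). With chain ``None``
    the distance is computed per subunit and reported per chain plus mean.
    """
    chainA, numA, atomsA = resA
    chainB, numB, atomsB = resB
    chains = [chainA] if chainA is not None else model.chains()
    per_chain = {}
    for ch in chains:
        chB = chainB if chainB is not None else ch
        a = _residue_atoms(model, ch, numA, atomsA)
        b = _residue_atoms(model, chB, numB, atomsB)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        per_chain[ch] = float(d.min())
    return {
        "per_chain": per_chain,
        "mean": float(np.mean(list(per_chain.values()))),
        "min": float(np.min(list(per_chain.values()))),
    }


def _residue_atoms(model: StructureModel, chain, res_id, atom_names):
    a = model.atoms
    m = (a.chain_id == chain) & (a.res_id == res_id)
    if not m.any():
        raise MissingAtomError(f"residue {res_id} chain {chain} not found")
    if atom_names is None:
        res_name = a.res_name[m][0]
        atom_names = SIDECHAIN_OXYGENS.get(res_name)
        if atom_names is None:
            raise MissingAtomError(
                f"no sidechain-oxygen table entry for residue type {res_name}")
    m &= np.isin(a.atom_name, list(atom_names))
    if not m.any():
        raise MissingAtomError(
            f"atoms {tuple(atom_names)} of residue {res_id} chain {chain} "
            "are missing")
    return a.coord[m]


def ruler_distance(apo: StructureModel, bound: StructureModel,
                   res_a: int = 551, res_b: int = 571,
                   numbering_offset: int = -1,
                   atoms_a=None, atoms_b=None) -> dict:
    """Apo-vs-bound change of the T551-E571 hydrogen-bond ruler distance.

    Residue numbers are given in the functional (mouse) convention and
    shifted by ``numbering_offset`` onto the structures' numbering (rat
    structures sit one lower, the default). Returns the per-state mean
    minimum sidechain-oxygen distances and their difference (apo - bound),
    positive when ligand binding pulls the pair together.
    """
    ra, rb = res_a + numbering_offset, res_b + numbering_offset
    d_apo = residue_min_distance(apo, (None, ra, atoms_a), (None, rb, atoms_b))
    d_bound = residue_min_distance(bound, (None, ra, atoms_a), (None, rb, atoms_b))
    return {
        "apo": d_apo,
        "bound": d_bound,
        "delta_mean_A": d_apo["mean"] - d_bound["mean"],
        "residues_structure_numbering": (ra, rb),
        "numbering_offset": numbering_offset,
    }


# ---------------------------------------------------------------------------
# Deterministic toy structures
# ---------------------------------------------------------------------------

# local-frame backbone satellite offsets (radial, tangential, axial) from CA
_BACKBONE_OFFSETS = {
    "N": (0.3, -0.8, -0.9),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.2, 0.9, 0.6),
    "O": (1.0, 1.2, 0.8),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def make_helix(n_res: int = 20, rise_A: float = 1.5, twist_deg: float = 100.0,
               radius_A: float = 2.3, chain: str = "A",
               res_start: int = 1, ca_only: bool = False) -> StructureModel:
    """Idealised helical backbone with deterministic coordinates."""
    if n_res < 1 or radius_A <= 0:
        raise ParameterError("need n_res >= 1 and positive radius")
    names = ("CA",) if ca_only else ("N", "CA", "C", "O")
    atoms = []
    for i in range(n_res):
        theta = np.deg2rad(twist_deg) * i
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        e_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        ca = radius_A * e_r + np.array([0.0, 0.0, rise_A * i])
        for nm in names:
            dr, dt, dz = _BACKBONE_OFFSETS[nm]
            pos = ca + dr * e_r + dt * e_t + dz * e_z
            atoms.append(struc.Atom(pos, chain_id=chain,
                                    res_id=res_start + i, res_name="ALA",
                                    atom_name=nm,
                                    element=_BACKBONE_ELEMENTS[nm]))
    arr = struc.array(atoms)
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr, {"kind": "helix"})


def make_ring_stack(rings, element: str = "C", chain: str = "A",
                    stagger_deg: float = 0.0) -> StructureModel:
    """Stacked atom rings around the z axis with known per-ring pore radius.

    ``rings`` is a list of ``(z_A, radius_A, n_atoms)``; at a ring's plane
    the pore radius is analytically ``radius_A - vdW(element)``.
    """
    vdw = BONDI_VDW[element.upper()]
    atoms = []
    for ri, (z, radius, n) in enumerate(rings):
        if radius <= vdw:
            raise ParameterError(
                f"ring radius {radius} Å must exceed the vdW radius {vdw} Å")
        for k in range(n):
            theta = 2 * np.pi * k / n + np.deg2rad(stagger_deg) * ri
            pos = np.array([radius * np.cos(theta), radius * np.sin(theta), z])
            atoms.append(struc.Atom(pos, chain_id=chain, res_id=ri + 1,
                                    res_name="RNG",
                                    atom_name=f"{element}{k + 1}",
                                    element=element, hetero=True))
    arr = struc.array(atoms)
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    return StructureModel(arr, {"kind": "pore_ring_stack"})
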