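"""Readers/writers for all on-disk formats; every dialect decision lives here.

Formats: SHELX fixed-column HKL (3I4,2F8.2), MTZ (via gemmi), multi-record
SDF V2000 (via RDKit, no sanitization so idealized toy molecules round-trip),
multi-model PDB (via gemmi), small-molecule CIF for solutions, YAML run
configs, JSONL logs.  Atom indices are 0-based in memory and 1-based on
disk, following SDF/PDB convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import yaml

from hamr.chem_model import Atom, Bond, Conformer, Lineage, Molecule
from hamr.crystal_model import (
    ReflectionSet,
    SpaceGroup,
    UnitCell,
    merge_friedel,
)

# ---------------------------------------------------------------------------
# SHELX HKL


def read_hkl(
    path,
    cell: UnitCell,
    spacegroup: Optional[SpaceGroup] = None,
    mode: str = "F",
) -> ReflectionSet:
    """Read a SHELX fixed-column HKL file (3I4,2F8.2; 0 0 0 terminator).

    ``mode="F"`` reads amplitude/sigma columns directly; ``mode="I"``
    converts intensities via |F| = sqrt(max(I, 0)), sigF = sigI/(2|F|)
    (clamped; the number of clamped negatives is reported via logging).
    Friedel mates (and symmetry equivalents, when a space group is given)
    are merged and systematic absences removed.
    """
    if mode not in ("F", "I"):
        raise ValueError("mode must be 'F' or 'I'")
    hkl, val, sig = [], [], []
    n_clamped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                v = float(line[12:20])
                s = float(line[20:28])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed HKL record at line {ln}: {line!r}"
                ) from exc
            if h == 0 and k == 0 and l == 0:
                break
            hkl.append((h, k, l))
            val.append(v)
            sig.append(s)
    if not hkl:
        raise ValueError(f"{path}: no reflections before terminator")
    hkl = np.array(hkl, dtype=int)
    val = np.array(val)
    sig = np.array(sig)
    if mode == "I":
        n_clamped = int((val < 0).sum())
        f = np.sqrt(np.maximum(val, 0.0))
        sigf = np.where(f > 1e-9, sig / (2.0 * np.maximum(f, 1e-9)), sig)
        val, sig = f, np.maximum(sigf, 1e-9)
        if n_clamped:
            import logging

            logging.getLogger(__name__).info(
                "%s: clamped %d negative intensities to |F|=0", path, n_clamped
            )
    sig = np.maximum(sig, 1e-9)
    return merge_friedel(hkl, val, sig, cell, spacegroup)


def write_hkl(path, refls: ReflectionSet) -> None:
    """Write SHELX fixed-column HKL (amplitudes) with 0 0 0 terminator."""
    with open(path, "w") as fh:
        for (h, k, l), f, s in zip(refls.hkl, refls.f, refls.sigma):
            fh.write(f"{h:4d}{k:4d}{l:4d}{f:8.2f}{s:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


# ---------------------------------------------------------------------------
# MTZ


def read_mtz(
    path,
    columns: Optional[dict] = None,
    expected_cell: Optional[UnitCell] = None,
) -> ReflectionSet:
    """Read reflections from MTZ.  Column defaults: F/SIGF (falling back to
    I/SIGI with intensity conversion) and FreeR_flag if present."""
    mtz = gemmi.read_mtz_file(str(path))
    labels = mtz.column_labels()
    cols = dict(columns or {})
    cell = UnitCell(
        mtz.cell.a, mtz.cell.b, mtz.cell.c,
        mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma,
    )
    if expected_cell is not None:
        rel = np.abs(
            np.array(cell.as_tuple()) - np.array(expected_cell.as_tuple())
        ) / np.array(expected_cell.as_tuple())
        if rel.max() > 1e-3:
            raise ValueError(
                f"{path}: cell {cell.as_tuple()} deviates >0.1% from "
                f"expected {expected_cell.as_tuple()}"
            )
    sg = SpaceGroup(mtz.spacegroup.xhm()) if mtz.spacegroup else None
    mode = "F"
    fcol = cols.get("F", "F" if "F" in labels else None)
    scol = cols.get("SIGF", "SIGF" if "SIGF" in labels else None)
    if fcol is None or fcol not in labels:
        if "I" in labels:
            fcol, scol, mode = "I", "SIGI" if "SIGI" in labels else None, "I"
        else:
            raise ValueError(
                f"{path}: no amplitude/intensity column; available: {labels}"
            )
    if scol is None or scol not in labels:
        raise ValueError(
            f"{path}: no sigma column for {fcol!r}; available: {labels}"
        )
    arr = np.array(mtz.array)
    idx = {lab: i for i, lab in enumerate(labels)}
    hkl = arr[:, [idx["H"], idx["K"], idx["L"]]].astype(int)
    v = arr[:, idx[fcol]].astype(float)
    s = arr[:, idx[scol]].astype(float)
    free = None
    freecol = cols.get("FREE", "FreeR_flag")
    if freecol in labels:
        free = arr[:, idx[freecol]] > 0.5
    if mode == "I":
        f = np.sqrt(np.maximum(v, 0.0))
        s = np.where(f > 1e-9, s / (2.0 * np.maximum(f, 1e-9)), s)
        v = f
    s = np.maximum(s, 1e-9)
    return merge_friedel(hkl, v, s, cell, sg, free=free)


def write_mtz(path, refls: ReflectionSet) -> None:
    """Write an MTZ with F/SIGF/FreeR_flag columns."""
    mtz = gemmi.Mtz(with_base=True)
    if refls.spacegroup is not None:
        mtz.spacegroup = refls.spacegroup.gemmi
    else:
        mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.set_cell_for_all(refls.cell.gemmi)
    mtz.add_dataset("hamr")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    mtz.add_column("FreeR_flag", "I")
    data = np.column_stack(
        [refls.hkl.astype(float), refls.f, refls.sigma,
         refls.is_free.astype(float)]
    ).astype(np.float32)
    mtz.set_data(data)
    mtz.write_to_file(str(path))


# ---------------------------------------------------------------------------
# conformer ensembles (SDF / PDB)


def _molecule_to_rdkit(mol: Molecule, conf: Conformer):
    from rdkit import Chem

    rw = Chem.RWMol()
    for a in mol.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.charge)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    orders = {
        1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
    }
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, orders.get(b.order, Chem.BondType.SINGLE))
    m = rw.GetMol()
    c = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(conf.coords):
        c.SetAtomPosition(i, tuple(float(v) for v in xyz))
    m.AddConformer(c)
    m.SetProp("_Name", mol.name or "hamr")
    return m


def write_ensemble(path, mol: Molecule, conformers: Sequence[Conformer]) -> None:
    """Write a multi-record SDF V2000 plus a JSON lineage sidecar."""
    from rdkit import Chem

    path = Path(path)
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        for conf in conformers:
            w.write(_molecule_to_rdkit(mol, conf))
    sidecar = []
    for conf in conformers:
        entry = {"cid": conf.cid}
        if conf.lineage is not None:
            entry["lineage"] = {
                "generation": conf.lineage.generation,
                "parent_id": conf.lineage.parent_id,
                "torsion_id": list(conf.lineage.torsion_id)
                if conf.lineage.torsion_id else None,
                "angles_deg": list(conf.lineage.angles_deg)
                if conf.lineage.angles_deg else None,
            }
        sidecar.append(entry)
    with open(path.with_suffix(path.suffix + ".lineage.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_ensemble(path) -> tuple[Molecule, list[Conformer]]:
    """Read a conformer ensemble from multi-record SDF or multi-model PDB.

    All records must share one chemical graph; a record whose atom count or
    element at some index diverges raises an error naming the offender.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return _read_pdb_ensemble(path)
    return _read_sdf_ensemble(path)


def _read_sdf_ensemble(path: Path) -> tuple[Molecule, list[Conformer]]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"{path}: no SDF records")
    ref = mols[0]
    elements = [a.GetSymbol() for a in ref.GetAtoms()]
    charges = [a.GetFormalCharge() for a in ref.GetAtoms()]
    bonds = []
    order_map = {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3, "AROMATIC": 1}
    for b in ref.GetBonds():
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                 order_map.get(str(b.GetBondType()), 1))
        )
    mol = Molecule(
        atoms=[
            Atom(el, ch, is_heavy=(el != "H"))
            for el, ch in zip(elements, charges)
        ],
        bonds=bonds,
        name=ref.GetProp("_Name") if ref.HasProp("_Name") else path.stem,
    )
    conformers = []
    for rec_i, m in enumerate(mols):
        if m.GetNumAtoms() != mol.n_atoms:
            raise ValueError(
                f"{path}: record {rec_i} has {m.GetNumAtoms()} atoms, "
                f"expected {mol.n_atoms}"
            )
        for k, a in enumerate(m.GetAtoms()):
            if a.GetSymbol() != elements[k]:
                raise ValueError(
                    f"{path}: record {rec_i} element mismatch at atom index "
                    f"{k}: {a.GetSymbol()} != {elements[k]}"
                )
        pos = m.GetConformer().GetPositions()
        conformers.append(Conformer(mol, np.array(pos), cid=f"rec-{rec_i:04d}"))
    side = path.with_suffix(path.suffix + ".lineage.json")
    if side.exists():
        with open(side) as fh:
            sidecar = json.load(fh)
        for conf, entry in zip(conformers, sidecar):
            conf.cid = entry.get("cid") or conf.cid
            lin = entry.get("lineage")
            if lin:
                conf.lineage = Lineage(
                    generation=lin["generation"],
                    parent_id=lin["parent_id"],
                    torsion_id=tuple(lin["torsion_id"])
                    if lin["torsion_id"] else None,
                    angles_deg=tuple(lin["angles_deg"])
                    if lin["angles_deg"] else None,
                )
    return mol, conformers


def _read_pdb_ensemble(path: Path) -> tuple[Molecule, list[Conformer]]:
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    models = []
    for model in st:
        elements, coords = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        models.append((elements, np.array(coords)))
    ref_el = models[0][0]
    n = len(ref_el)
    # bonds by distance (PDB carries no CONECT guarantee for toys)
    coords0 = models[0][1]
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords0[i] - coords0[j]) <= 1.8:
                bonds.append(Bond(i, j, 1))
    mol = Molecule(
        atoms=[Atom(el, 0, el != "H") for el in ref_el],
        bonds=bonds, name=path.stem,
    )
    out = []
    for mi, (els, xyz) in enumerate(models):
        if len(els) != n:
            raise ValueError(f"{path}: model {mi} atom count {len(els)} != {n}")
        for k, el in enumerate(els):
            if el != ref_el[k]:
                raise ValueError(
                    f"{path}: model {mi} element mismatch at index {k}"
                )
        out.append(Conformer(mol, xyz, cid=f"model-{mi}"))
    return mol, out


# ---------------------------------------------------------------------------
# solution CIF


def write_solution_cif(path, solution, refls: ReflectionSet) -> None:
    """Small-molecule CIF for a phased solution: cell, full symmetry
    operator list, fractional atom sites (wrapped to [0, 1))."""
    cell = refls.cell
    sg = refls.spacegroup
    conf = solution.conformer
    xyz = solution.pose.apply(conf.coords, cell)
    frac = cell.fractionalize(xyz) % 1.0
    doc = gemmi.cif.Document()
    block = doc.add_new_block("hamr_solution")
    pair = block.set_pair
    pair("_cell_length_a", f"{cell.a:.4f}")
    pair("_cell_length_b", f"{cell.b:.4f}")
    pair("_cell_length_c", f"{cell.c:.4f}")
    pair("_cell_angle_alpha", f"{cell.alpha:.4f}")
    pair("_cell_angle_beta", f"{cell.beta:.4f}")
    pair("_cell_angle_gamma", f"{cell.gamma:.4f}")
    if sg is not None:
        pair("_space_group_name_H-M_alt", gemmi.cif.quote(sg.symbol))
        loop = block.init_loop("_space_group_symop_", ["operation_xyz"])
        for trip in sg.triplets():
            loop.add_row([gemmi.cif.quote(trip)])
    loop = block.init_loop(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    counts: dict[str, int] = {}
    for atom, (x, y, z) in zip(conf.parent.atoms, frac):
        counts[atom.element] = counts.get(atom.element, 0) + 1
        loop.add_row(
            [f"{atom.element}{counts[atom.element]}", atom.element,
             f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]
        )
    pair("_hamr_llg_like", f"{solution.llg_like:.4f}")
    pair("_hamr_tfz_like", f"{solution.tfz_like:.4f}")
    pair("_hamr_r_work", f"{solution.r_work:.6f}")
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# run manifest / config


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one run: inputs, checksums, parameters, seed."""

    inputs: dict = field(default_factory=dict)    # path -> sha256
    cell: Optional[tuple] = None
    spacegroup: Optional[str] = None
    d_min: Optional[float] = None
    config_hash: Optional[str] = None
    version: str = ""
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "inputs": self.inputs,
                    "cell": list(self.cell) if self.cell else None,
                    "spacegroup": self.spacegroup,
                    "d_min": self.d_min,
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            inputs=d.get("inputs", {}),
            cell=tuple(d["cell"]) if d.get("cell") else None,
            spacegroup=d.get("spacegroup"),
            d_min=d.get("d_min"),
            config_hash=d.get("config_hash"),
            version=d.get("version", ""),
            seed=d.get("seed", 0),
        )


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
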