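"""PDB-format input/output and ligand identification.

Parsing is backed by gemmi (coordinates, experiment method, resolution,
MODRES bookkeeping, polymer/heterogen classification, altloc resolution);
HET and SEQRES header records are scanned from the raw file because gemmi
does not expose them. A heteroatom group is a ligand candidate when it is
listed in a HET record, is not a MODRES-modified polymer residue, and is not
water; the atom-count gate is applied separately by :func:`extract_ligands`.

Residue numbering is author numbering as deposited; insertion codes are kept
as part of the residue id. Hydrogens are parsed and retained on residues but
never counted as ligand heavy atoms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import geometric_center, min_distance

__all__ = [
    "Atom",
    "Residue",
    "ChainRecord",
    "LigandRecord",
    "StructureRecord",
    "ParseError",
    "EmptyStructureError",
    "WATER_IDS",
    "parse_structure",
    "extract_ligands",
    "split_chains",
    "write_prediction",
    "write_structure",
]

WATER_IDS = frozenset({"HOH", "DOD", "WAT"})


class ParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ParseError):
    """Raised when a file contains no polymer coordinates."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        object.__setattr__(self, "coords", c)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def with_coords(self, coords) -> "Atom":
        return Atom(self.name, self.element, np.asarray(coords, dtype=float),
                    self.is_hetero)


@dataclass(frozen=True)
class Residue:
    """One polymer residue; ``seq_id`` is the author number plus insertion code."""

    name: str
    seq_id: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.seq_id}: no atoms")

    @property
    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class ChainRecord:
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        seen = set()
        for r in self.residues:
            if r.seq_id in seen:
                raise ValueError(
                    f"chain {self.chain_id}: duplicate residue id {r.seq_id}")
            seen.add(r.seq_id)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates in residue order; raises if a residue lacks a CA."""
        coords = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is None:
                raise ValueError(
                    f"chain {self.chain_id}: residue {r.name} {r.seq_id} has no CA atom")
            coords.append(ca.coords)
        return np.asarray(coords)

    def heavy_coords(self) -> np.ndarray:
        return np.asarray([a.coords for r in self.residues for a in r.heavy_atoms])


@dataclass(frozen=True)
class LigandRecord:
    """A heteroatom group kept as a ligand candidate (heavy atoms only)."""

    comp_id: str
    chain_id: str
    het_seq_id: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if self.comp_id in WATER_IDS:
            raise ValueError(f"{self.comp_id} is water, not a ligand")

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms])


@dataclass
class StructureRecord:
    entry_id: str
    method: str
    resolution: float | None
    polymer_types: set[str]
    chains: list[ChainRecord]
    ligands: list[LigandRecord]
    raw_het: list[tuple[str, str, str]] = field(default_factory=list)
    raw_modres: list[tuple[str, str, str]] = field(default_factory=list)
    seqres: dict[str, list[str]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"{self.entry_id}: no chain {chain_id}")

    def ligands_of_chain(self, chain_id: str) -> list[LigandRecord]:
        return [l for l in self.ligands if l.chain_id == chain_id]


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _seq_id(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def _scan_header(path: Path) -> tuple[list, dict]:
    """Collect HET records and SEQRES composition from the raw file."""
    het: list[tuple[str, str, str]] = []
    seqres: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "HET   ":
                comp = line[7:10].strip()
                chain = line[12:13].strip()
                num = line[13:17].strip() + line[17:18].strip()
                het.append((comp, chain, num))
            elif rec == "SEQRES":
                chain = line[11:12].strip()
                seqres.setdefault(chain, []).extend(line[19:].split())
            elif line.startswith(("ATOM", "HETATM")):
                break
    return het, seqres


def parse_structure(path) -> StructureRecord:
    """Parse one PDB entry (model 1) into a :class:`StructureRecord`.

    Alternate locations are collapsed to a single conformer; ligand candidates
    are heteroatom groups present in HET records, absent from MODRES records,
    and not water. A candidate on a chain without polymer residues is
    reassigned to the polymer chain nearest to its geometric center.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.setup_entities()

    raw_het, seqres = _scan_header(path)
    raw_modres = [
        (m.res_id.name, m.chain_name, f"{m.res_id.seqid.num}{m.res_id.seqid.icode.strip()}")
        for m in st.mod_residues
    ]
    het_comp_ids = {h[0] for h in raw_het}
    modres_keys = {(m[0], m[1], m[2]) for m in raw_modres}

    method = st.info["_exptl.method"] if "_exptl.method" in st.info else ""
    if not method:
        method = "UNKNOWN"
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models")
    model = st[0]

    chains: list[ChainRecord] = []
    het_groups: list[tuple[str, str, str, list[Atom]]] = []
    polymer_types: set[str] = set()

    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [
                Atom(a.name, a.element.name or "X", np.array(a.pos.tolist()),
                     is_hetero=(gres.het_flag == "H"))
                for a in gres
            ]
            if not atoms:
                continue
            if gres.entity_type == gemmi.EntityType.Polymer:
                residues.append(Residue(gres.name, _seq_id(gres), tuple(atoms)))
            elif gres.entity_type == gemmi.EntityType.Water or gres.name in WATER_IDS:
                continue
            else:
                het_groups.append((gres.name, gchain.name, _seq_id(gres), atoms))
        if residues:
            chains.append(ChainRecord(gchain.name, tuple(residues)))
            ptype = gchain.get_polymer().check_polymer_type()
            polymer_types.add(_polymer_kind(ptype))

    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chains with coordinates")

    ligands: list[LigandRecord] = []
    for comp_id, chain_id, num, atoms in het_groups:
        if het_comp_ids and comp_id not in het_comp_ids:
            continue  # HETATM group never declared in a HET record
        if (comp_id, chain_id, num) in modres_keys:
            continue
        heavy = tuple(a for a in atoms if not a.is_hydrogen)
        if not heavy:
            continue
        ligands.append(LigandRecord(comp_id, _assign_chain(chain_id, heavy, chains),
                                    num, heavy))

    raw_id = st.info["_entry.id"] if "_entry.id" in st.info else ""
    entry_id = (raw_id or path.stem)[:4].upper()
    return StructureRecord(
        entry_id=entry_id,
        method=method.upper(),
        resolution=resolution,
        polymer_types=polymer_types,
        chains=chains,
        ligands=ligands,
        raw_het=raw_het,
        raw_modres=raw_modres,
        seqres=seqres,
    )


def _polymer_kind(ptype: gemmi.PolymerType) -> str:
    name = str(ptype).split(".")[-1]
    if name.startswith("Peptide"):
        return "protein"
    if name == "Dna":
        return "dna"
    if name == "Rna":
        return "rna"
    if name == "DnaRnaHybrid":
        return "dna/rna"
    return "other"


def _assign_chain(chain_id: str, heavy: tuple[Atom, ...],
                  chains: list[ChainRecord]) -> str:
    """Keep the deposited chain id when it names a polymer chain; otherwise
    reassign to the polymer chain nearest the ligand center."""
    polymer_ids = {c.chain_id for c in chains}
    if chain_id in polymer_ids:
        return chain_id
    center = geometric_center(heavy).coords
    return min(chains, key=lambda c: min_distance(center, c.heavy_coords())).chain_id


def extract_ligands(s: StructureRecord, min_atoms: int = 6) -> list[LigandRecord]:
    """Ligands with at least ``min_atoms`` heavy atoms.

    HET-record membership, MODRES exclusion and the water rule were already
    applied at parse time; this gate adds the heavy-atom-count rule.
    """
    return [l for l in s.ligands if l.atom_count >= min_atoms]


def split_chains(s: StructureRecord) -> list[ChainRecord]:
    """Polymer chains of the entry; heteroatom groups are never chains."""
    return list(s.chains)


# ---------------------------------------------------------------------------
# writing

_PDB_ATOM = ("{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
             "{num:>4s}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {elem:>2s}\n")


def _split_num(seq_id: str) -> tuple[str, str]:
    if seq_id and seq_id[-1].isalpha():
        return seq_id[:-1], seq_id[-1]
    return seq_id, " "


def _format_atom(rec: str, serial: int, name: str, res: str, chain: str,
                 seq_id: str, coords, elem: str) -> str:
    num, icode = _split_num(seq_id)
    # PDB atom-name column convention: 1-letter elements start in column 14
    padded = f" {name:<3s}" if len(name) < 4 and len(elem) == 1 else f"{name:<4s}"
    return _PDB_ATOM.format(rec=rec, serial=serial, name=padded, alt=" ", res=res,
                            chain=chain, num=num, icode=icode,
                            x=coords[0], y=coords[1], z=coords[2],
                            occ=1.0, b=0.0, elem=elem)


def write_structure(s: StructureRecord, path, header_extra: list[str] | None = None) -> None:
    """Write a StructureRecord as PDB text (HEADER, EXPDTA, REMARK 2, MODRES,
    HET, SEQRES, coordinates). The emitted file re-parses to the same atoms,
    chain ids and coordinates at PDB field precision."""
    lines: list[str] = []
    lines.append(f"HEADER    {'SYNTHETIC PROTEIN':<40s}{'01-JAN-20':<9s}   {s.entry_id:<4s}\n")
    lines.append(f"EXPDTA    {s.method}\n")
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {s.resolution:4.2f} ANGSTROMS.\n")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.\n")
    if header_extra:
        lines.extend(header_extra)
    for comp, chain, num in s.raw_modres:
        n, icode = _split_num(num)
        lines.append(f"MODRES {s.entry_id:<4s} {comp:<3s} {chain:1s} {n:>4s}{icode:1s}\n")
    for comp, chain, num in s.raw_het:
        n, icode = _split_num(num)
        count = next((l.atom_count for l in s.ligands
                      if (l.comp_id, l.het_seq_id) == (comp, num)), 0)
        lines.append(f"HET    {comp:<3s}  {chain:1s}{n:>4s}{icode:1s}  {count:>5d}\n")
    for chain in s.chains:
        names = [r.name for r in chain.residues]
        for i in range(0, len(names), 13):
            row = " ".join(f"{n:<3s}" for n in names[i:i + 13])
            lines.append(f"SEQRES {i // 13 + 1:>3d} {chain.chain_id:1s} "
                         f"{len(names):>4d}  {row}\n")
    serial = 1
    for chain in s.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_format_atom("ATOM", serial, atom.name, res.name,
                                          chain.chain_id, res.seq_id, atom.coords,
                                          atom.element))
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain.residues[-1].name:<3s} "
                     f"{chain.chain_id:1s}\n")
        serial += 1
    for lig in s.ligands:
        for atom in lig.atoms:
            lines.append(_format_atom("HETATM", serial, atom.name, lig.comp_id,
                                      lig.chain_id, lig.het_seq_id, atom.coords,
                                      atom.element))
            serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def write_prediction(predictions, chain: ChainRecord, out_prefix) -> dict[str, Path]:
    """Write predicted sites as TSV + JSON summaries and a pseudo-ligand PDB.

    The PDB contains the query chain plus one HETATM pseudo-atom (comp SIT)
    per predicted center, for visualization. Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in predictions:
        residues = ";".join(f"{chain.chain_id}:{r.seq_id}" for r in p.residues)
        rows.append({
            "rank": p.rank,
            "center_x": round(float(p.center.coords[0]), 3),
            "center_y": round(float(p.center.coords[1]), 3),
            "center_z": round(float(p.center.coords[2]), 3),
            "n_support": p.support,
            "residues": residues,
        })
    tsv_path = out_prefix.with_suffix(".tsv")
    cols = ["rank", "center_x", "center_y", "center_z", "n_support", "residues"]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps({"chain": chain.chain_id, "sites": rows},
                                    indent=2) + "\n")
    pdb_path = out_prefix.with_suffix(".pdb")
    lines = []
    serial = 1
    for res in chain.residues:
        for atom in res.atoms:
            lines.append(_format_atom("ATOM", serial, atom.name, res.name,
                                      chain.chain_id, res.seq_id, atom.coords,
                                      atom.element))
            serial += 1
    for p in predictions:
        lines.append(_format_atom("HETATM", serial, "C1", "SIT", chain.chain_id,
                                  str(900 + p.rank), p.center.coords, "C"))
        serial += 1
    lines.append("END\n")
    pdb_path.write_text("".join(lines))
    return {"tsv": tsv_path, "json": json_path, "pdb": pdb_path}
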