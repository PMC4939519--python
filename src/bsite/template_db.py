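"""Bound-template database: quality filters, stability gate, and indexes.

A template is a protein chain from an X-ray structure of adequate resolution
that binds at least one stable ligand. Candidate entries pass a four-stage
cascade:

1. entry-level quality rules (protein-only, X-ray, resolution in (0, 3.0] A,
   at least one free ligand, at least one chain longer than 20 residues);
2. chain split, dropping chains of 20 residues or fewer;
3. chains owning at least one ligand with >= 6 heavy atoms;
4. chains whose ligand forms a stable complex: some ligand atom lies within
   4 A of the geometric center of the ligand's 8 A residue shell.

Surviving chains are reachable through two indexes: a homology index keyed on
a fold-classification string (from an external mapping file), and a length
index queried with a <30 % relative length difference.

The database persists as a plain directory: a JSON manifest with per-stage
counts and the config snapshot, one PDB file per template chain, and TSV
index files — inspectable and diffable.
"""
from __future__ import annotations

import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import geometric_center, min_distance
from .structure_io import (ChainRecord, LigandRecord, StructureRecord,
                           ParseError, extract_ligands, parse_structure,
                           split_chains, write_structure)

logger = logging.getLogger(__name__)

__all__ = [
    "DbConfig",
    "TemplateEntry",
    "Manifest",
    "TemplateDatabase",
    "rules_of_five",
    "site_residues",
    "stability_of_complex",
    "build_database",
    "save_database",
    "load_database",
    "load_mapping",
    "lookup_homology_class",
    "query_homology_index",
    "query_length_index",
]


@dataclass(frozen=True)
class DbConfig:
    """Thresholds of the database filter cascade (distances in Angstroms)."""

    max_resolution: float = 3.0
    min_chain_len: int = 20        # exclusive: chains must be longer than this
    min_ligand_atoms: int = 6
    stability_dist: float = 4.0
    bound_site_radius: float = 8.0
    length_tolerance: float = 0.30

    def __post_init__(self) -> None:
        for name in ("max_resolution", "min_chain_len", "min_ligand_atoms",
                     "stability_dist", "bound_site_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.length_tolerance < 1:
            raise ValueError("length_tolerance must be in (0, 1)")


@dataclass
class TemplateEntry:
    """One database chain with its stable ligands."""

    entry_id: str
    chain_id: str
    chain: ChainRecord
    ligands: list[LigandRecord]
    homology_class: str | None = None
    coord_ref: str | None = None

    @property
    def key(self) -> str:
        return f"{self.entry_id}_{self.chain_id}"

    @property
    def length(self) -> int:
        return self.chain.length


@dataclass
class Manifest:
    stage_counts: dict[str, int]
    config: dict
    n_files: int = 0
    n_skipped: int = 0
    entries: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"stage_counts": self.stage_counts, "config": self.config,
             "n_files": self.n_files, "n_skipped": self.n_skipped,
             "entries": self.entries},
            indent=2, sort_keys=True) + "\n"


class TemplateDatabase:
    """In-memory template set plus its two query indexes."""

    def __init__(self, entries: list[TemplateEntry], manifest: Manifest):
        self.entries = sorted(entries, key=lambda e: e.key)
        self.manifest = manifest
        self.homology_index: dict[str, list[TemplateEntry]] = {}
        for e in self.entries:
            if e.homology_class is not None:
                self.homology_index.setdefault(e.homology_class, []).append(e)
        self._by_length = sorted(self.entries, key=lambda e: (e.length, e.key))
        self._lengths = [e.length for e in self._by_length]

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: str) -> TemplateEntry:
        for e in self.entries:
            if e.key == key:
                return e
        raise KeyError(key)


# ---------------------------------------------------------------------------
# filters

def rules_of_five(s: StructureRecord, cfg: DbConfig = DbConfig()) -> tuple[bool, list[str]]:
    """Entry-level quality predicates; returns (pass, failed-predicate names).

    Pass requires: protein-only polymers, X-ray diffraction, resolution in
    (0, max_resolution], at least one free-ligand candidate, and at least one
    chain longer than ``min_chain_len`` residues.
    """
    reasons = []
    if not s.polymer_types or s.polymer_types != {"protein"}:
        reasons.append("polymer type")
    if "X-RAY" not in s.method.upper():
        reasons.append("method")
    if s.resolution is None or not (0 < s.resolution <= cfg.max_resolution):
        reasons.append("resolution")
    if not s.ligands:
        reasons.append("free ligand")
    if not any(c.length > cfg.min_chain_len for c in s.chains):
        reasons.append("chain length")
    return (not reasons, reasons)


def site_residues(chain: ChainRecord, ligand_coords: np.ndarray,
                  radius: float) -> list:
    """Chain residues with any heavy atom within ``radius`` (closed bound)
    of any of the given coordinates."""
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if ligand_coords.size == 0:
        return []
    out = []
    for res in chain.residues:
        coords = np.asarray([a.coords for a in res.heavy_atoms])
        if coords.size and cdist(coords, ligand_coords).min() <= radius:
            out.append(res)
    return out


def stability_of_complex(chain: ChainRecord, ligand: LigandRecord,
                         cfg: DbConfig = DbConfig()) -> bool:
    """Whether the chain-ligand complex is stable.

    The binding site is every chain residue with a heavy atom within
    ``bound_site_radius`` of the ligand; the complex is stable when some
    ligand atom lies within ``stability_dist`` of the geometric center of the
    site's heavy atoms. An empty site is unstable.
    """
    site = site_residues(chain, ligand.coords(), cfg.bound_site_radius)
    if not site:
        return False
    site_atoms = np.asarray([a.coords for r in site for a in r.heavy_atoms])
    center = geometric_center(site_atoms, source="site heavy atoms")
    return min_distance(center.coords, ligand.coords()) <= cfg.stability_dist


# ---------------------------------------------------------------------------
# homology mapping

def load_mapping(path) -> dict[tuple[str, str], str]:
    """Read a ``pdb_id  chain_id  class_string`` mapping file.

    ``#`` comments and blank lines are ignored; on a duplicate chain the first
    occurrence wins with a logged warning; malformed lines raise with their
    line number.
    """
    mapping: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'pdb_id chain_id class', got {line!r}")
            key = (fields[0].upper(), fields[1])
            if key in mapping:
                logger.warning("%s:%d: duplicate mapping for %s/%s ignored",
                               path, lineno, *key)
                continue
            mapping[key] = fields[2]
    return mapping


def lookup_homology_class(entry_id: str, chain_id: str,
                          mapping: dict[tuple[str, str], str] | None) -> str | None:
    """Fold-classification string for a chain, or None when unmapped."""
    if not mapping:
        return None
    return mapping.get((entry_id.upper(), chain_id))


# ---------------------------------------------------------------------------
# build / persist

def build_database(paths, mapping=None, cfg: DbConfig = DbConfig()) -> TemplateDatabase:
    """Run the four-stage cascade over PDB files and build both indexes.

    ``mapping`` may be a path to a mapping file or a pre-loaded dict.
    Unreadable files are logged and skipped (counted in the manifest);
    stage counts are entries for stage 1 and chains for stages 2-4.
    """
    if mapping is not None and not isinstance(mapping, dict):
        mapping = load_mapping(mapping)

    n_files = 0
    n_skipped = 0
    stage1_entries: list[StructureRecord] = []
    for path in paths:
        n_files += 1
        try:
            s = parse_structure(path)
        except ParseError as exc:
            logger.warning("skipping %s: %s", path, exc)
            n_skipped += 1
            continue
        ok, _ = rules_of_five(s, cfg)
        if ok:
            stage1_entries.append(s)

    stage2: list[tuple[StructureRecord, ChainRecord]] = []
    for s in stage1_entries:
        for chain in split_chains(s):
            if chain.length > cfg.min_chain_len:
                stage2.append((s, chain))

    stage3: list[tuple[StructureRecord, ChainRecord, list[LigandRecord]]] = []
    for s, chain in stage2:
        ligs = [l for l in extract_ligands(s, cfg.min_ligand_atoms)
                if l.chain_id == chain.chain_id]
        if ligs:
            stage3.append((s, chain, ligs))

    entries: list[TemplateEntry] = []
    for s, chain, ligs in stage3:
        stable = [l for l in ligs if stability_of_complex(chain, l, cfg)]
        if stable:
            entries.append(TemplateEntry(
                entry_id=s.entry_id,
                chain_id=chain.chain_id,
                chain=chain,
                ligands=stable,
                homology_class=lookup_homology_class(s.entry_id, chain.chain_id,
                                                     mapping),
            ))

    manifest = Manifest(
        stage_counts={
            "entries_rules_of_five": len(stage1_entries),
            "chains_length": len(stage2),
            "chains_with_ligand": len(stage3),
            "chains_stable": len(entries),
        },
        config=asdict(cfg),
        n_files=n_files,
        n_skipped=n_skipped,
        entries=[{"key": e.key, "length": e.length,
                  "homology_class": e.homology_class,
                  "n_ligands": len(e.ligands)} for e in
                 sorted(entries, key=lambda e: e.key)],
    )
    counts = list(manifest.stage_counts.values())
    assert counts[2] >= counts[3], "cascade counts must be non-increasing"
    return TemplateDatabase(entries, manifest)


def save_database(db: TemplateDatabase, out_dir) -> Path:
    """Persist as manifest.json + per-entry PDB files + TSV indexes."""
    out_dir = Path(out_dir)
    (out_dir / "entries").mkdir(parents=True, exist_ok=True)
    for e in db.entries:
        rel = f"entries/{e.key}.pdb"
        rec = StructureRecord(
            entry_id=e.entry_id, method="X-RAY DIFFRACTION",
            resolution=2.0,
            polymer_types={"protein"}, chains=[e.chain], ligands=list(e.ligands),
            raw_het=[(l.comp_id, l.chain_id, l.het_seq_id) for l in e.ligands],
        )
        write_structure(rec, out_dir / rel)
        e.coord_ref = rel
    for d in db.manifest.entries:
        d["coord_ref"] = f"entries/{d['key']}.pdb"
    (out_dir / "manifest.json").write_text(db.manifest.to_json())
    with open(out_dir / "homology_index.tsv", "w") as fh:
        for cls in sorted(db.homology_index):
            for e in db.homology_index[cls]:
                fh.write(f"{cls}\t{e.key}\n")
    with open(out_dir / "length_index.tsv", "w") as fh:
        for e in db._by_length:
            fh.write(f"{e.length}\t{e.key}\n")
    return out_dir


def load_database(db_dir) -> TemplateDatabase:
    """Load a persisted database directory back into memory."""
    db_dir = Path(db_dir)
    raw = json.loads((db_dir / "manifest.json").read_text())
    manifest = Manifest(stage_counts=raw["stage_counts"], config=raw["config"],
                        n_files=raw.get("n_files", 0),
                        n_skipped=raw.get("n_skipped", 0),
                        entries=raw["entries"])
    entries = []
    for meta in manifest.entries:
        s = parse_structure(db_dir / meta["coord_ref"])
        chain_id = meta["key"].rsplit("_", 1)[1]
        entries.append(TemplateEntry(
            entry_id=meta["key"].rsplit("_", 1)[0],
            chain_id=chain_id,
            chain=s.chain(chain_id),
            ligands=s.ligands_of_chain(chain_id),
            homology_class=meta.get("homology_class"),
            coord_ref=meta["coord_ref"],
        ))
    return TemplateDatabase(entries, manifest)


# ---------------------------------------------------------------------------
# queries

def query_homology_index(class_id: str, db: TemplateDatabase) -> list[TemplateEntry]:
    """Templates whose classification string equals ``class_id`` exactly."""
    return list(db.homology_index.get(class_id, []))


def query_length_index(query_len: int, db: TemplateDatabase,
                       cfg: DbConfig = DbConfig()) -> list[TemplateEntry]:
    """Templates with relative length difference below ``length_tolerance``.

    The difference is |query_len - template_len| / query_len, compared
    strictly; candidates are located by binary search on the sorted index.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    tol = cfg.length_tolerance
    lo = bisect_left(db._lengths, query_len * (1 - tol))
    hi = bisect_right(db._lengths, query_len * (1 + tol))
    return [e for e in db._by_length[lo:hi]
            if abs(query_len - e.length) / query_len < tol]
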