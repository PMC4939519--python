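"""Deterministic synthetic structures for exercising the whole pipeline.

Every generated "protein" is a CA + sidechain-centroid backbone laid out as a
parametric curve: a spherical-spiral cage of residues wrapped around a pocket
(so that a ligand placed at the cage's shell center satisfies the
complex-stability gate by construction) followed by a meandering tail. A fold
family is a backbone shape drawn once from the family's random stream; family
members are that shape plus small coordinate noise and a random rigid motion,
so members align well with each other while chains from different families do
not. Backbone spacing is the canonical CA-CA step of 3.8 A; there is no
physics here — the prediction method consumes geometry only.

Defects produce structures that fail exactly one database filter stage:

- ``nmr``: EXPDTA says solution NMR, no resolution (entry-rule failure);
- ``high_resolution``: resolution 3.5 A (entry-rule failure);
- ``short_chain``: an extra 15-residue chain that the length filter drops;
- ``small_ligand``: the pocket ligand has 5 heavy atoms (atom-count failure);
- ``modres_mask``: the pocket ligand is masked by a MODRES record and a small
  decoy heteroatom group keeps the entry's free-ligand predicate true
  (atom-count stage failure);
- ``unstable_ligand``: the ligand sits off the tail surface where the site
  shell is one-sided (stability failure).

All outputs are byte-reproducible from (spec, seed).
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import Center, Transform, geometric_center
from .structure_io import (Atom, ChainRecord, LigandRecord, Residue,
                           StructureRecord, parse_structure, write_structure)
from .template_db import DbConfig, site_residues, stability_of_complex

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_bound",
    "derive_unbound",
    "generate_corpus",
    "build_structure",
]

KNOWN_DEFECTS = {"nmr", "high_resolution", "small_ligand", "unstable_ligand",
                 "modres_mask", "short_chain"}

CA_STEP = 3.8          # A, canonical CA-CA spacing
LIGAND_SHELL = 1.4     # A, ligand atom radius about its center
MEMBER_NOISE = 0.30    # A, per-member backbone jitter within a family

_AA = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic bound structure."""

    seed: int
    n_residues: int = 60
    fold_family: str = "fam0"
    pocket_radius: float = 6.5   # A, cage shell radius
    pocket_depth: float = 0.8    # A, radial wiggle amplitude of the cage
    ligand_atoms: int = 8
    entry_id: str = "SYN1"
    defects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.ligand_atoms < 1:
            raise ValueError("ligand_atoms must be >= 1")
        unknown = set(self.defects) - KNOWN_DEFECTS
        if unknown:
            raise ValueError(f"unknown defects: {sorted(unknown)}")
        if {"nmr", "high_resolution"} <= set(self.defects):
            raise ValueError("contradictory defects: nmr has no resolution to raise")


@dataclass
class GroundTruth:
    """What the generator knows about a fixture, for use as a test oracle."""

    true_ligand: LigandRecord
    true_center: Center
    true_site_residues: list[str]          # seq_ids of the 8 A shell
    expected_stage_pass: dict[str, bool]   # per-filter predicate truth
    fold_family: str = ""

    def transformed(self, t: Transform) -> "GroundTruth":
        atoms = tuple(a.with_coords(t.apply(a.coords))
                      for a in self.true_ligand.atoms)
        lig = LigandRecord(self.true_ligand.comp_id, self.true_ligand.chain_id,
                           self.true_ligand.het_seq_id, atoms)
        return GroundTruth(lig, Center(t.apply(self.true_center.coords)),
                           list(self.true_site_residues),
                           dict(self.expected_stage_pass), self.fold_family)


def _family_rng(fold_family: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(fold_family.encode()) % 2**31)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _cage_points(rng: np.random.Generator, radius: float,
                 depth: float) -> np.ndarray:
    """Spherical spiral around the origin, sampled at ~CA_STEP arc spacing."""
    turns = rng.uniform(3.0, 4.5)
    phase = rng.uniform(0, 2 * np.pi)
    wfreq = rng.integers(2, 6)
    wphase = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0.12 * np.pi, 0.88 * np.pi, 4000)
    r = radius + depth * np.sin(wfreq * theta + wphase)
    phi = phase + turns * theta
    pts = np.stack([r * np.sin(theta) * np.cos(phi),
                    r * np.sin(theta) * np.sin(phi),
                    r * np.cos(theta)], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                          axis=1))])
    picks = np.arange(0, arc[-1], CA_STEP)
    idx = np.searchsorted(arc, picks)
    return pts[np.minimum(idx, len(pts) - 1)]


def _tail_points(rng: np.random.Generator, start: np.ndarray, n: int) -> np.ndarray:
    """Random walk leaving the pocket, step CA_STEP.

    The turning amplitude is redrawn every step, so local window geometry
    varies along the tail: straight stretches and tight curls alternate in a
    family-specific pattern that structural alignment can lock onto.
    """
    pts = [start]
    v = _unit(start) if np.linalg.norm(start) > 1e-6 else np.array([1.0, 0, 0])
    for _ in range(n):
        w = rng.uniform(0.15, 0.95)  # per-step turn amplitude
        kick = _unit(rng.normal(size=3))
        away = _unit(pts[-1]) if np.linalg.norm(pts[-1]) > 1e-6 else kick
        v = _unit((1.0 - w) * v + w * kick + 0.10 * away)
        pts.append(pts[-1] + CA_STEP * v)
    return np.asarray(pts[1:])


def _canonical_backbone(fold_family: str, n_residues: int, pocket_radius: float,
                        pocket_depth: float) -> tuple[np.ndarray, slice]:
    """Family-deterministic CA trace with the pocket cage somewhere along it.

    Where the cage sits in the sequence, its radius and its spiral coverage
    are all family properties, so different families differ in global
    architecture, not just in local wiggle; wrong-family alignments then map
    their ligands to uncorrelated positions instead of piling up on the
    query's pocket. Returns the coordinates and the cage's index slice.
    """
    rng = _family_rng(fold_family)
    radius = pocket_radius + rng.uniform(-0.7, 0.9)
    cage = _cage_points(rng, radius, pocket_depth)
    cage = cage[: max(8, min(len(cage), n_residues - 8))]
    n_loose = n_residues - len(cage)
    n_pre = int(round(n_loose * rng.uniform(0.0, 0.8)))
    n_post = n_loose - n_pre
    pre = _tail_points(rng, cage[0], n_pre)[::-1] if n_pre else np.empty((0, 3))
    post = _tail_points(rng, cage[-1], n_post) if n_post else np.empty((0, 3))
    coords = np.vstack([pre, cage, post])
    return coords, slice(n_pre, n_pre + len(cage))


def _sidechain_dirs(ca: np.ndarray) -> np.ndarray:
    """Outward pseudo-CB direction: away from the local backbone midpoint."""
    dirs = np.zeros_like(ca)
    for i in range(len(ca)):
        lo, hi = max(0, i - 1), min(len(ca), i + 2)
        local = ca[lo:hi].mean(axis=0)
        d = ca[i] - local
        if np.linalg.norm(d) < 1e-6:
            d = ca[i] if np.linalg.norm(ca[i]) > 1e-6 else np.array([0.0, 0, 1.0])
        dirs[i] = _unit(d)
    return dirs


def _ligand_atoms(center: np.ndarray, n_atoms: int, comp_id: str,
                  chain_id: str, seq_id: str) -> LigandRecord:
    """Heavy atoms on a small deterministic (Fibonacci) shell about center."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    atoms = []
    for k in range(n_atoms):
        z = 1 - 2 * (k + 0.5) / n_atoms
        rho = np.sqrt(max(0.0, 1 - z * z))
        ang = golden * k
        offset = LIGAND_SHELL * np.array([rho * np.cos(ang), rho * np.sin(ang), z])
        elem = "C" if k % 2 == 0 else "O"
        atoms.append(Atom(f"{elem}{k + 1}", elem, center + offset, is_hetero=True))
    return LigandRecord(comp_id, chain_id, seq_id, tuple(atoms))


def _make_chain(chain_id: str, ca: np.ndarray, names: list[str]) -> ChainRecord:
    dirs = _sidechain_dirs(ca)
    residues = []
    for i in range(len(ca)):
        atoms = [Atom("CA", "C", ca[i])]
        if names[i] != "GLY":
            atoms.append(Atom("CB", "C", ca[i] + 1.5 * dirs[i]))
        residues.append(Residue(names[i], str(i + 1), tuple(atoms)))
    return ChainRecord(chain_id, tuple(residues))


def _settle_ligand(chain: ChainRecord, n_atoms: int, cfg: DbConfig,
                   cage: slice) -> LigandRecord:
    """Place the ligand at the fixed point of the site-center map.

    Starting at the cage centroid, the ligand is moved to the heavy-atom
    center of its own 8 A residue shell until the two agree; this makes the
    stability gate hold by construction.
    """
    ca = np.asarray([r.atom("CA").coords for r in chain.residues])
    center = ca[cage].mean(axis=0)
    lig = _ligand_atoms(center, n_atoms, "LIG", chain.chain_id, "501")
    for _ in range(6):
        site = site_residues(chain, lig.coords(), cfg.bound_site_radius)
        if not site:
            break
        new_center = np.asarray([a.coords for r in site
                                 for a in r.heavy_atoms]).mean(axis=0)
        if np.linalg.norm(new_center - center) < 0.05:
            break
        center = new_center
        lig = _ligand_atoms(center, n_atoms, "LIG", chain.chain_id, "501")
    return lig


def _unstable_ligand(chain: ChainRecord, n_atoms: int,
                     cfg: DbConfig) -> LigandRecord:
    """Ligand placed off the tail end so its site shell is one-sided."""
    last = chain.residues[-1].atom("CA").coords
    prev = chain.residues[-2].atom("CA").coords
    out_dir = _unit(last - prev)
    for dist in np.arange(6.5, 14.0, 0.5):
        lig = _ligand_atoms(last + dist * out_dir, n_atoms, "LIG",
                            chain.chain_id, "501")
        if not stability_of_complex(chain, lig, cfg):
            return lig
    raise RuntimeError("could not construct an unstable ligand placement")


def _random_transform(rng: np.random.Generator, max_shift: float = 25.0) -> Transform:
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    return Transform(rot, rng.uniform(-max_shift, max_shift, size=3))


def build_structure(spec: FixtureSpec,
                    cfg: DbConfig = DbConfig()) -> tuple[StructureRecord, GroundTruth]:
    """Assemble the in-memory structure and its ground truth (pocket frame
    canonical shape; member noise and a rigid motion applied per seed)."""
    rng = np.random.default_rng(spec.seed)
    fam_rng = _family_rng(spec.fold_family)
    n_res = spec.n_residues
    ca, cage_slice = _canonical_backbone(spec.fold_family, n_res,
                                         spec.pocket_radius, spec.pocket_depth)
    names = [_AA[i] for i in fam_rng.integers(0, len(_AA), size=len(ca))]
    # members of a family differ like real homologs: coordinate jitter plus
    # ragged termini (a few residues trimmed per member, never touching the
    # cage); identical copies would make even wrong alignments coincide
    ca = ca + rng.normal(scale=MEMBER_NOISE, size=ca.shape)
    front = int(rng.integers(0, min(4, cage_slice.start) + 1))
    back_room = len(ca) - cage_slice.stop
    back = int(rng.integers(0, min(4, back_room) + 1))
    stop = len(ca) - back
    ca = ca[front:stop]
    names = names[front:stop]
    cage_slice = slice(cage_slice.start - front, cage_slice.stop - front)
    chain = _make_chain("A", ca, names)

    defects = set(spec.defects)
    n_lig = 5 if "small_ligand" in defects else spec.ligand_atoms
    if "unstable_ligand" in defects:
        ligand = _unstable_ligand(chain, n_lig, cfg)
    else:
        ligand = _settle_ligand(chain, n_lig, cfg, cage_slice)

    chains = [chain]
    ligands = [ligand]
    raw_het = [(ligand.comp_id, ligand.chain_id, ligand.het_seq_id)]
    raw_modres = []

    if "modres_mask" in defects:
        raw_modres.append((ligand.comp_id, ligand.chain_id, ligand.het_seq_id))
        # a free non-water heteroatom group keeps the entry-level ligand
        # predicate true; with 3 atoms it fails the atom-count stage
        far = chain.residues[-1].atom("CA").coords + np.array([12.0, 0, 0])
        decoy = _ligand_atoms(far, 3, "DCY", chain.chain_id, "502")
        ligands.append(decoy)
        raw_het.append((decoy.comp_id, decoy.chain_id, decoy.het_seq_id))

    if "short_chain" in defects:
        stub_start = chain.residues[0].atom("CA").coords + np.array([30.0, 0, 0])
        stub_ca = _tail_points(np.random.default_rng(spec.seed + 77),
                               stub_start, 15)
        stub_names = [_AA[i] for i in
                      np.random.default_rng(spec.seed + 78).integers(0, 20, 15)]
        chains.append(_make_chain("B", stub_ca, stub_names))

    method = "SOLUTION NMR" if "nmr" in defects else "X-RAY DIFFRACTION"
    resolution = None if "nmr" in defects else (
        3.5 if "high_resolution" in defects else 2.0)

    record = StructureRecord(
        entry_id=spec.entry_id, method=method, resolution=resolution,
        polymer_types={"protein"}, chains=chains, ligands=ligands,
        raw_het=raw_het, raw_modres=raw_modres,
    )

    t = _random_transform(rng)
    record = _transform_record(record, t)
    ligand_moved = record.ligands[0]

    site = site_residues(record.chains[0], ligand_moved.coords(),
                         cfg.bound_site_radius)
    truth = GroundTruth(
        true_ligand=ligand_moved,
        true_center=geometric_center(ligand_moved.atoms, source="true ligand"),
        true_site_residues=[r.seq_id for r in site],
        expected_stage_pass={
            "rules_of_five": not ({"nmr", "high_resolution"} & defects),
            "chain_length": True,  # the main chain always passes
            "ligand_atoms": not ({"small_ligand", "modres_mask"} & defects),
            "stability": "unstable_ligand" not in defects,
        },
        fold_family=spec.fold_family,
    )
    if not defects:
        assert stability_of_complex(record.chains[0], ligand_moved, cfg), \
            "generator postcondition: defect-free fixture must be stable"
    return record, truth


def _transform_record(s: StructureRecord, t: Transform) -> StructureRecord:
    def move_res(res: Residue) -> Residue:
        return Residue(res.name, res.seq_id,
                       tuple(a.with_coords(t.apply(a.coords)) for a in res.atoms))

    chains = [ChainRecord(c.chain_id, tuple(move_res(r) for r in c.residues))
              for c in s.chains]
    ligands = [LigandRecord(l.comp_id, l.chain_id, l.het_seq_id,
                            tuple(a.with_coords(t.apply(a.coords))
                                  for a in l.atoms))
               for l in s.ligands]
    return StructureRecord(s.entry_id, s.method, s.resolution,
                           set(s.polymer_types), chains, ligands,
                           list(s.raw_het), list(s.raw_modres), dict(s.seqres))


def generate_bound(spec: FixtureSpec, out_path,
                   cfg: DbConfig = DbConfig()) -> tuple[Path, GroundTruth]:
    """Write one bound fixture as PDB text; returns (path, ground truth)."""
    record, truth = build_structure(spec, cfg)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_structure(record, out_path)
    return out_path, truth


def derive_unbound(bound_path, truth: GroundTruth, seed: int,
                   noise_sigma: float = 0.0,
                   out_path=None) -> tuple[StructureRecord, GroundTruth]:
    """Strip the ligands, apply a seeded rigid motion and optional Gaussian
    coordinate noise; the ground truth is transported through the same rigid
    motion (noise does not move the true center)."""
    s = parse_structure(bound_path)
    rng = np.random.default_rng(seed)
    t = _random_transform(rng)
    s = _transform_record(s, t)
    if noise_sigma > 0:
        def jitter(res: Residue) -> Residue:
            return Residue(res.name, res.seq_id,
                           tuple(a.with_coords(a.coords +
                                               rng.normal(scale=noise_sigma, size=3))
                                 for a in res.atoms))
        s = StructureRecord(s.entry_id, s.method, s.resolution,
                            set(s.polymer_types),
                            [ChainRecord(c.chain_id,
                                         tuple(jitter(r) for r in c.residues))
                             for c in s.chains],
                            [], [], list(s.raw_modres), dict(s.seqres))
    else:
        s = StructureRecord(s.entry_id, s.method, s.resolution,
                            set(s.polymer_types), s.chains, [], [],
                            list(s.raw_modres), dict(s.seqres))
    new_truth = truth.transformed(t)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        write_structure(s, out_path)
    return s, new_truth


def _entry_id(family: int, member: int) -> str:
    return f"S{family}{member:02d}"[:4].upper()


def generate_corpus(n_families: int, per_family: int, seed: int, out_dir,
                    defect_table: dict[str, list[str]] | None = None,
                    n_residues: int = 60,
                    cfg: DbConfig = DbConfig(),
                    verify_separation: bool = False) -> dict:
    """Write a corpus of bound fixtures, a homology mapping and a truth table.

    Families share a backbone shape (members align well within a family);
    each family gets one classification string in ``mapping.tsv``. The truth
    table records per-entry defects, stage predicates and the true pocket.
    ``defect_table`` maps entry ids (e.g. ``"S102"``) to defect lists. With
    ``verify_separation`` the canonical shapes of all family pairs are
    aligned and any family scoring >= 0.3 against an earlier one is re-rolled
    under a perturbed name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    defect_table = defect_table or {}
    families = []
    for f in range(n_families):
        name = f"{seed}-fam{f}"
        if verify_separation:
            name = _separated_family_name(name, families, n_residues)
        families.append(name)

    truth_table: dict[str, dict] = {}
    mapping_lines = []
    for f, fam in enumerate(families):
        cls = f"a.{f + 1}.1.1"
        for m in range(per_family):
            entry_id = _entry_id(f, m)
            spec = FixtureSpec(seed=seed * 10007 + f * 101 + m,
                               n_residues=n_residues, fold_family=fam,
                               entry_id=entry_id,
                               defects=tuple(defect_table.get(entry_id, ())))
            path, truth = generate_bound(spec, out_dir / f"{entry_id}.pdb", cfg)
            mapping_lines.append(f"{entry_id}\tA\t{cls}")
            truth_table[entry_id] = {
                "family": fam, "class": cls, "chain": "A",
                "defects": list(spec.defects),
                "true_center": [round(float(x), 4)
                                for x in truth.true_center.coords],
                "site_residues": truth.true_site_residues,
                "stage_pass": truth.expected_stage_pass,
            }
    (out_dir / "mapping.tsv").write_text(
        "# pdb_id\tchain_id\tclass\n" + "\n".join(mapping_lines) + "\n")
    (out_dir / "truth.json").write_text(
        json.dumps(truth_table, indent=2, sort_keys=True) + "\n")
    return truth_table


def _separated_family_name(name: str, existing: list[str],
                           n_residues: int) -> str:
    """Re-roll a family name until its canonical shape aligns poorly
    (score < 0.3) with every already-accepted family."""
    from .ce_align import align  # local import avoids a cycle at module load

    def canon_chain(fam: str) -> ChainRecord:
        ca, _ = _canonical_backbone(fam, n_residues, 6.5, 0.8)
        return _make_chain("A", ca, ["ALA"] * len(ca))

    for attempt in range(10):
        candidate = name if attempt == 0 else f"{name}-r{attempt}"
        chain = canon_chain(candidate)
        if all(align(chain, canon_chain(old)).score < 0.3 for old in existing):
            return candidate
    raise RuntimeError(f"could not separate family {name} from earlier families")
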