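"""Binding-site prediction workflow.

Each query chain takes one of three routes:

- Part 1 (bound): the chain carries a ligand that passes the atom-count and
  complex-stability gates; its binding site is read off directly as every
  residue within 8 A of the ligand.
- Part 2 (homology search): the chain's fold-classification string selects
  database templates of the same class.
- Part 3 (length search): with no usable homologous template, candidates are
  templates whose length differs from the query's by less than 30 %.

On routes 2 and 3 the query is aligned against every candidate; candidates
whose mapped ligand does not form a stable complex with the query are
discarded, the rest are ranked by alignment similarity and at most the top 20
kept. Their ligands are carried into the query frame by the alignment
transforms and clustered by iterative consensus election: the ligand center
with the most other centers within the cluster radius (default 3 A) becomes
the next site, its cluster is removed, and the count is redone from scratch,
up to three sites. Site residues are every query residue within 10 A of the
elected ligand.

A bound chain whose ligand fails the stability gate is treated as unbound
with its original ligands removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .ce_align import AlignConfig, AlignmentResult, align, rank_templates
from .geometry import Center, apply_transform, geometric_center
from .structure_io import (Atom, ChainRecord, LigandRecord, StructureRecord,
                           extract_ligands)
from .template_db import (DbConfig, TemplateDatabase, TemplateEntry,
                          lookup_homology_class, query_homology_index,
                          query_length_index, site_residues,
                          stability_of_complex)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorConfig",
    "Route",
    "MappedLigand",
    "Cluster",
    "BindingSitePrediction",
    "ChainPrediction",
    "route",
    "predict_bound",
    "select_templates",
    "map_ligands",
    "cluster_ligand_centers",
    "detect_site_residues",
    "predict",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Prediction thresholds; distances in Angstroms."""

    cluster_radius: float = 3.0      # consensus radius, valid range 1-8
    top_templates: int = 20
    unbound_site_radius: float = 10.0
    max_sites: int = 3
    site_from_cluster_union: bool = False  # 10 A shell from all cluster members
    db: DbConfig = field(default_factory=DbConfig)
    align: AlignConfig = field(default_factory=AlignConfig)

    def __post_init__(self) -> None:
        if not 1.0 <= self.cluster_radius <= 8.0:
            raise ValueError("cluster_radius must be within [1.0, 8.0]")
        if self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")
        if self.top_templates < 1:
            raise ValueError("top_templates must be >= 1")


class Route(Enum):
    PART1 = "part1"
    PART2 = "part2"
    PART3 = "part3"


@dataclass(frozen=True)
class MappedLigand:
    """A template ligand carried into the query frame."""

    atoms: tuple[Atom, ...]
    source: str            # template key
    template_rank: int     # 0-based position in the selected-template list
    index: int             # 0-based position in the full mapped-ligand list

    @property
    def center(self) -> Center:
        return geometric_center(self.atoms, source=f"mapped ligand {self.source}")

    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms])


@dataclass(frozen=True)
class Cluster:
    """One elected consensus site: the winning ligand and its neighborhood."""

    elected: MappedLigand
    support: int                       # members removed with this cluster
    members: tuple[MappedLigand, ...]  # elected first

    @property
    def center(self) -> Center:
        return self.elected.center


@dataclass(frozen=True)
class BindingSitePrediction:
    rank: int
    center: Center
    support: int
    residues: tuple
    mode: str  # "bound" | "unbound"


@dataclass
class ChainPrediction:
    chain_id: str
    route: Route
    status: str  # "ok" | "no_template"
    predictions: list[BindingSitePrediction]


# ---------------------------------------------------------------------------

def _stable_ligands(chain: ChainRecord, ligands: list[LigandRecord],
                    cfg: PredictorConfig) -> list[LigandRecord]:
    keep = [l for l in ligands if l.atom_count >= cfg.db.min_ligand_atoms]
    return [l for l in keep if stability_of_complex(chain, l, cfg.db)]


def route(chain: ChainRecord, ligands: list[LigandRecord],
          db: TemplateDatabase, cfg: PredictorConfig,
          homology_class: str | None = None) -> Route:
    """Choose the workflow part for one chain.

    Part 1 requires a ligand passing both the atom-count and stability gates;
    otherwise the chain is treated as unbound (original ligands dropped) and
    goes to Part 2 when its classification has templates in the database,
    else to Part 3.
    """
    if _stable_ligands(chain, ligands, cfg):
        return Route.PART1
    if homology_class is not None and query_homology_index(homology_class, db):
        return Route.PART2
    return Route.PART3


def predict_bound(chain: ChainRecord, ligands: list[LigandRecord],
                  cfg: PredictorConfig = PredictorConfig()) -> list[BindingSitePrediction]:
    """Direct site detection for a stably bound chain.

    One site per stable ligand: residues within the bound-site radius (8 A) of
    the ligand, centered at the geometric center of the site's heavy atoms.
    Sites are ranked by ligand heavy-atom count, largest first.
    """
    stable = _stable_ligands(chain, ligands, cfg)
    stable.sort(key=lambda l: (-l.atom_count, l.chain_id, l.het_seq_id))
    out = []
    for i, lig in enumerate(stable[:cfg.max_sites]):
        residues = site_residues(chain, lig.coords(), cfg.db.bound_site_radius)
        site_atoms = np.asarray([a.coords for r in residues for a in r.heavy_atoms])
        center = geometric_center(site_atoms, source="bound site heavy atoms")
        out.append(BindingSitePrediction(rank=i + 1, center=center, support=1,
                                         residues=tuple(residues), mode="bound"))
    return out


def select_templates(chain: ChainRecord, candidates: list[TemplateEntry],
                     cfg: PredictorConfig = PredictorConfig()
                     ) -> list[tuple[TemplateEntry, AlignmentResult]]:
    """Align the query to every candidate, keep those whose mapped ligand
    forms a stable complex with the query, and rank to the top-k."""
    passing = []
    for entry in candidates:
        result = align(chain, entry.chain, cfg.align)
        if result.aligned_length == 0:
            continue
        stable_any = False
        for lig in entry.ligands:
            mapped = LigandRecord(lig.comp_id, chain.chain_id, lig.het_seq_id,
                                  tuple(apply_transform(result.transform,
                                                        list(lig.atoms))))
            if stability_of_complex(chain, mapped, cfg.db):
                stable_any = True
                break
        if stable_any:
            passing.append((entry, result))
    return rank_templates(passing, cfg.top_templates)


def map_ligands(selected: list[tuple[TemplateEntry, AlignmentResult]],
                cfg: PredictorConfig = PredictorConfig()) -> list[MappedLigand]:
    """Carry every selected template's ligands into the query frame."""
    mapped: list[MappedLigand] = []
    for rank, (entry, result) in enumerate(selected):
        for lig in entry.ligands:
            atoms = tuple(apply_transform(result.transform, list(lig.atoms)))
            mapped.append(MappedLigand(atoms=atoms, source=entry.key,
                                       template_rank=rank, index=len(mapped)))
    return mapped


def cluster_ligand_centers(ligands: list[MappedLigand],
                           cfg: PredictorConfig = PredictorConfig()) -> list[Cluster]:
    """Iterative consensus election of mapped-ligand centers.

    Each round counts, for every remaining ligand, the other remaining centers
    strictly within ``cluster_radius``; the ligand with the largest count is
    elected (ties: lowest template rank, then input order), then it and every
    center within the radius are removed, and counting restarts from scratch.
    At most ``max_sites`` clusters are returned, in election order.
    """
    remaining = list(ligands)
    clusters: list[Cluster] = []
    while remaining and len(clusters) < cfg.max_sites:
        centers = np.asarray([l.center.coords for l in remaining])
        dists = cdist(centers, centers)
        counts = (dists < cfg.cluster_radius).sum(axis=1) - 1  # exclude self
        best = min(range(len(remaining)),
                   key=lambda i: (-counts[i], remaining[i].template_rank,
                                  remaining[i].index))
        in_cluster = dists[best] < cfg.cluster_radius
        members = tuple([remaining[best]] +
                        [l for i, l in enumerate(remaining)
                         if in_cluster[i] and i != best])
        clusters.append(Cluster(elected=remaining[best], support=len(members),
                                members=members))
        remaining = [l for i, l in enumerate(remaining) if not in_cluster[i]]
    return clusters


def detect_site_residues(chain: ChainRecord, cluster: Cluster,
                         cfg: PredictorConfig = PredictorConfig()) -> list:
    """Query residues within the unbound-site radius (10 A) of the cluster's
    elected ligand (or of all member ligands when configured)."""
    if cfg.site_from_cluster_union:
        coords = np.vstack([m.coords() for m in cluster.members])
    else:
        coords = cluster.elected.coords()
    return site_residues(chain, coords, cfg.unbound_site_radius)


def _predict_unbound(chain: ChainRecord,
                     candidates: list[TemplateEntry],
                     cfg: PredictorConfig) -> list[BindingSitePrediction]:
    selected = select_templates(chain, candidates, cfg)
    if not selected:
        return []
    mapped = map_ligands(selected, cfg)
    clusters = cluster_ligand_centers(mapped, cfg)
    out = []
    for i, cluster in enumerate(clusters):
        residues = detect_site_residues(chain, cluster, cfg)
        out.append(BindingSitePrediction(rank=i + 1, center=cluster.center,
                                         support=cluster.support,
                                         residues=tuple(residues),
                                         mode="unbound"))
    return out


def predict(query: StructureRecord, db: TemplateDatabase,
            cfg: PredictorConfig = PredictorConfig(),
            mapping: dict | None = None,
            exclude_templates: frozenset[str] = frozenset()
            ) -> list[ChainPrediction]:
    """Predict ranked binding sites for every chain of a query structure.

    ``mapping`` supplies the query's fold classification; ``exclude_templates``
    removes database keys (e.g. the query itself) from consideration. When
    Part 2's homologous candidates all fail, the chain falls through to
    Part 3; when Part 3 also yields nothing, the chain gets an empty result
    with status "no_template". The pipeline is deterministic for a fixed
    database and configuration.
    """
    results = []
    for chain in query.chains:
        ligands = query.ligands_of_chain(chain.chain_id)
        cls = lookup_homology_class(query.entry_id, chain.chain_id, mapping)
        chosen = route(chain, ligands, db, cfg, homology_class=cls)
        if chosen is Route.PART1:
            preds = predict_bound(chain, ligands, cfg)
            results.append(ChainPrediction(chain.chain_id, chosen, "ok", preds))
            continue
        preds = []
        if chosen is Route.PART2:
            candidates = [e for e in query_homology_index(cls, db)
                          if e.key not in exclude_templates]
            preds = _predict_unbound(chain, candidates, cfg)
            if not preds:
                chosen = Route.PART3  # fall through to the length index
        if chosen is Route.PART3:
            candidates = [e for e in query_length_index(chain.length, db, cfg.db)
                          if e.key not in exclude_templates]
            preds = _predict_unbound(chain, candidates, cfg)
        status = "ok" if preds else "no_template"
        results.append(ChainPrediction(chain.chain_id, chosen, status, preds))
    return results
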