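"""Benchmark metrics: 4 A center-hit accuracy and residue-level MCC.

A predicted site is a hit when its geometric center lies within 4 A of any
heavy atom of the true (experimentally observed) ligand; Top1/Top3 success is
whether the first / any of the first three ranked sites hits. The Matthews
correlation coefficient is computed over the residue partition into
predicted/experimental binding-site sets, with the experimental site taken as
every residue within 8 A of the original ligand. A bound chain that passes
the complex-stability gate scores accuracy 100 % and MCC 1 by convention,
without running a prediction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .geometry import Center, min_distance
from .predictor import BindingSitePrediction, PredictorConfig, predict
from .structure_io import ChainRecord, LigandRecord, StructureRecord
from .template_db import site_residues, stability_of_complex

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "site_hit",
    "topk_success",
    "residue_partition",
    "compute_mcc",
    "evaluate_query",
    "evaluate_dataset",
]

HIT_THRESHOLD = 4.0  # A; center-to-ligand-atom criterion


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    query: str
    chain: str
    mode: str  # "bound" | "unbound"
    top1_hit: bool
    top3_hit: bool
    mcc: float


def site_hit(predicted_center: Center, true_ligand: LigandRecord,
             threshold: float = HIT_THRESHOLD) -> bool:
    """Whether the predicted center lies within ``threshold`` of any heavy
    atom of the true ligand."""
    if true_ligand.atom_count == 0:
        raise ValueError("true ligand has no atoms")
    return min_distance(predicted_center.coords, true_ligand.coords()) <= threshold


def topk_success(predictions: list[BindingSitePrediction],
                 true_ligands: list[LigandRecord], k: int,
                 threshold: float = HIT_THRESHOLD) -> bool:
    """Whether any of the first ``k`` ranked sites hits any true ligand."""
    return any(
        site_hit(p.center, lig, threshold)
        for p in predictions[:k]
        for lig in true_ligands
    )


def residue_partition(chain: ChainRecord,
                      predicted_sites: list[BindingSitePrediction],
                      experimental_ligands: list[LigandRecord],
                      exp_site_radius: float = 8.0) -> ConfusionCounts:
    """Residue-level confusion counts.

    The experimental binding site is every chain residue within
    ``exp_site_radius`` of any experimental-ligand heavy atom; the predicted
    site is the union of the predicted sites' residue lists. TP/FP/FN/TN
    follow from the two partitions; every chain residue lands in exactly one
    cell.
    """
    exp = set()
    for lig in experimental_ligands:
        exp.update(r.seq_id for r in site_residues(chain, lig.coords(),
                                                   exp_site_radius))
    pre = {r.seq_id for p in predicted_sites for r in p.residues}
    all_ids = {r.seq_id for r in chain.residues}
    tp = len(pre & exp)
    fp = len(pre - exp)
    fn = len(exp - pre)
    tn = len(all_ids - pre - exp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) *
                      (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


def evaluate_query(query: StructureRecord, chain_id: str,
                   truth_ligands: list[LigandRecord],
                   db, cfg: PredictorConfig = PredictorConfig(),
                   mapping: dict | None = None,
                   exclude_templates: frozenset[str] = frozenset()
                   ) -> EvaluationResult:
    """Score one chain against its ground-truth ligands.

    A bound chain whose ligand passes the stability gate scores Top1 hit and
    MCC 1 by convention. Otherwise the prediction pipeline runs and both the
    center-hit flags and the residue-level MCC are measured against the truth
    ligands.
    """
    chain = query.chain(chain_id)
    own = [l for l in query.ligands_of_chain(chain_id)
           if l.atom_count >= cfg.db.min_ligand_atoms]
    if any(stability_of_complex(chain, l, cfg.db) for l in own):
        return EvaluationResult(query.entry_id, chain_id, "bound",
                                top1_hit=True, top3_hit=True, mcc=1.0)
    chain_results = predict(query, db, cfg, mapping=mapping,
                            exclude_templates=exclude_templates)
    preds = next((r.predictions for r in chain_results
                  if r.chain_id == chain_id), [])
    counts = residue_partition(chain, preds[:1], truth_ligands,
                               exp_site_radius=cfg.db.bound_site_radius)
    return EvaluationResult(
        query.entry_id, chain_id, "unbound",
        top1_hit=topk_success(preds, truth_ligands, 1),
        top3_hit=topk_success(preds, truth_ligands, 3),
        mcc=compute_mcc(counts),
    )


def evaluate_dataset(queries, db, cfg: PredictorConfig = PredictorConfig(),
                     mapping: dict | None = None,
                     exclude_self: bool = False) -> dict:
    """Evaluate a set of (structure, chain_id, truth-ligand-list) triples.

    Returns per-query results plus aggregate Top1/Top3 rates and mean MCC.
    Queries without a ground-truth ligand are excluded with a logged reason.
    """
    results: list[EvaluationResult] = []
    for query, chain_id, truth in queries:
        if not truth:
            logger.warning("excluding %s/%s: no ground-truth ligand",
                           query.entry_id, chain_id)
            continue
        exclude = (frozenset({f"{query.entry_id}_{chain_id}"})
                   if exclude_self else frozenset())
        results.append(evaluate_query(query, chain_id, truth, db, cfg,
                                      mapping=mapping,
                                      exclude_templates=exclude))
    n = len(results)
    return {
        "results": results,
        "n": n,
        "top1_rate": sum(r.top1_hit for r in results) / n if n else float("nan"),
        "top3_rate": sum(r.top3_hit for r in results) / n if n else float("nan"),
        "mean_mcc": sum(r.mcc for r in results) / n if n else float("nan"),
    }
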