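"""End-to-end plumbing: raw records -> encodings -> trained stack -> report.

``encode_dataset`` turns the four record collections into aligned arrays (one
row per protein); ``run_pipeline`` holds out a test split, pretrains the
branches, trains the fusion classifier on their frozen outputs and evaluates
on the held-out proteins. ``run_kfold_cv`` repeats that protocol over k
disjoint folds and ``run_domain_ablation`` contrasts the full stack with a
variant whose classifier is wired to the sequence and PPI branches only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import encode as enc
from .errors import ConfigurationError, EvaluationError
from .io import AnnotationRecord, DomainHit, ScoredLink, SequenceRecord, TrigramTable
from .metrics import EvalReport, evaluate
from .models import BRANCHES, Model, PredictionScores, build_classifier_masks
from .simulate import SyntheticDataset
from .train import (
    TrainConfig,
    TrainHistory,
    derive_seeds,
    pretrain_submodel,
    split_train_val,
    train_classifier,
)

logger = logging.getLogger("gofuse")


@dataclass
class PipelineConfig:
    """Encoding-side knobs of a run.

    ``pad_len`` is the fixed sequence length (the classical choice is 1,500;
    smaller values are appropriate when the data's longest protein is known).
    ``ppi_normalize`` divides retained link scores by 1000 so the PPI features
    enter the dense net in [0, 1] — numerically friendlier than raw scores.
    """

    pad_len: int = 1500
    ppi_threshold: int = enc.PPI_SCORE_THRESHOLD
    ppi_normalize: bool = True
    ontology: str = "MF"
    min_count: int = 20
    test_fraction: float = 0.2


@dataclass
class EncodedDataset:
    """Aligned fixed-shape arrays for every included protein."""

    protein_ids: List[str]
    x_seq: np.ndarray          # (n, pad_len - 2, 100) float32
    x_dom: np.ndarray          # (n, m_max) int64
    x_ppi: np.ndarray          # (n, n) float32 rows of the PPI matrix
    y: np.ndarray              # (n, T) float32 binary labels
    term_set: enc.GoTermSet
    vocab: enc.DomainVocabulary
    m_max: int
    pad_len: int

    @property
    def n_terms(self) -> int:
        return len(self.term_set)

    def branch_input(self, branch: str) -> np.ndarray:
        return {"sequence": self.x_seq, "domain": self.x_dom, "ppi": self.x_ppi}[branch]

    def sidecar(self) -> dict:
        """JSON-serializable summary for run manifests."""
        return {
            "n_proteins": len(self.protein_ids),
            "n_terms": self.n_terms,
            "m_max": self.m_max,
            "vocab_size": self.vocab.size,
            "pad_len": self.pad_len,
            "ontology": self.term_set.ontology,
            "min_count": self.term_set.min_count,
            "terms": list(self.term_set.terms),
        }


def encode_dataset(
    sequences: Sequence[SequenceRecord],
    domain_hits: Sequence[DomainHit],
    links: Sequence[ScoredLink],
    annotations: Sequence[AnnotationRecord],
    table: TrigramTable,
    config: PipelineConfig | None = None,
) -> EncodedDataset:
    """Encode all four modalities into aligned arrays.

    Proteins longer than ``pad_len`` are excluded with a logged warning
    rather than truncated.
    """
    cfg = config or PipelineConfig()
    kept: List[SequenceRecord] = []
    for rec in sequences:
        if len(rec.sequence) > cfg.pad_len:
            logger.warning(
                "excluding protein %s: length %d exceeds pad_len %d",
                rec.protein_id, len(rec.sequence), cfg.pad_len,
            )
        else:
            kept.append(rec)
    if not kept:
        raise ConfigurationError("no protein fits within pad_len")
    ids = [r.protein_id for r in kept]
    id_set = set(ids)

    x_seq = np.stack(
        [enc.encode_sequence(r.sequence, table, cfg.pad_len, r.protein_id) for r in kept]
    )

    hits_by_protein: Dict[str, List[DomainHit]] = {pid: [] for pid in ids}
    for h in domain_hits:
        if h.protein_id in id_set:
            hits_by_protein[h.protein_id].append(h)
    sorted_hits = {
        pid: enc.sort_domains(enc.dedup_domain_hits(hs))
        for pid, hs in hits_by_protein.items()
    }
    vocab = enc.build_domain_vocab(
        [h for hs in sorted_hits.values() for h in hs]
    )
    m_max = max((len(hs) for hs in sorted_hits.values()), default=0) or 1
    x_dom = np.stack(
        [enc.encode_domain_sentence(sorted_hits[pid], vocab, m_max, pid) for pid in ids]
    )

    x_ppi = enc.build_ppi_matrix(
        links, ids, threshold=cfg.ppi_threshold, normalize=cfg.ppi_normalize
    )

    term_set = enc.select_go_terms(
        [a for a in annotations if a.protein_id in id_set],
        cfg.ontology,
        cfg.min_count,
    )
    y = enc.build_label_matrix(ids, annotations, term_set)
    return EncodedDataset(ids, x_seq, x_dom, x_ppi, y, term_set, vocab, m_max, cfg.pad_len)


def encode_synthetic(dataset: SyntheticDataset, table: TrigramTable,
                     config: PipelineConfig | None = None) -> EncodedDataset:
    return encode_dataset(
        dataset.sequences, dataset.domain_hits, dataset.links,
        dataset.annotations, table, config,
    )


@dataclass
class TrainedStack:
    """The pretrained branches plus the fusion classifier for one training set."""

    branches: Dict[str, Model]
    classifier: Model
    histories: Dict[str, TrainHistory]
    #: absolute dataset rows whose out-of-sample branch scores trained the fusion
    fusion_rows: np.ndarray | None = None

    def predict(self, data: EncodedDataset, idx: np.ndarray) -> np.ndarray:
        outs = [
            self.branches[b].predict_proba(data.branch_input(b)[idx])
            for b in self.branches
        ]
        return self.classifier.forward_branches(*outs)

    def prediction_scores(self, data: EncodedDataset,
                          idx: np.ndarray | None = None) -> PredictionScores:
        idx = np.arange(len(data.protein_ids)) if idx is None else idx
        return PredictionScores(
            protein_ids=[data.protein_ids[i] for i in idx],
            terms=list(data.term_set.terms),
            matrix=self.predict(data, idx),
        )


def train_stack(
    data: EncodedDataset,
    train_idx: np.ndarray,
    cfg: TrainConfig,
    branches: Sequence[str] = BRANCHES,
    overrides: Dict[str, dict] | None = None,
) -> TrainedStack:
    """Pretrain the requested branches, then fit the fusion classifier on
    their frozen training-set outputs.

    ``overrides`` maps a branch name (or "classifier") to TrainConfig fields
    that replace the shared defaults for that component only — the knobs of
    the protocol's per-module manual hyperparameter adjustment.

    All branches share one 80/20 split, and the fusion classifier is trained
    on the branch scores of the shared validation portion — out-of-sample for
    every branch, so the classifier's per-term preferences reflect how well
    each branch generalises rather than how well it memorised its training
    proteins (stacked-generalisation practice).
    """
    y_tr = data.y[train_idx]
    seeds = derive_seeds(cfg.seed, *(f"branch.{b}" for b in branches),
                         "fusion", "stack.split")
    rel_train, rel_val = split_train_val(
        len(train_idx), cfg.val_fraction, seeds["stack.split"]
    )
    models: Dict[str, Model] = {}
    histories: Dict[str, TrainHistory] = {}
    overrides = overrides or {}
    for b in branches:
        bcfg = TrainConfig(**{**cfg.__dict__, **overrides.get(b, {}),
                              "seed": seeds[f"branch.{b}"]})
        models[b], histories[b] = pretrain_submodel(
            b, data.branch_input(b)[train_idx], y_tr, bcfg,
            vocab_size=data.vocab.size if b == "domain" else None,
            split=(rel_train, rel_val),
        )
    branch_outputs = [
        models[b].predict_proba(data.branch_input(b)[train_idx][rel_val])
        for b in branches
    ]
    fcfg = TrainConfig(**{**cfg.__dict__, **overrides.get("classifier", {}),
                          "seed": seeds["fusion"]})
    masks = build_classifier_masks(data.n_terms, n_branches=len(branches))
    classifier, histories["classifier"] = train_classifier(
        branch_outputs, y_tr[rel_val], fcfg, masks
    )
    return TrainedStack(models, classifier, histories,
                        fusion_rows=np.asarray(train_idx)[rel_val])


@dataclass
class PipelineResult:
    report: EvalReport
    stack: TrainedStack
    test_idx: np.ndarray
    scores: np.ndarray
    data: EncodedDataset = field(repr=False)


def run_pipeline(
    data: EncodedDataset,
    cfg: TrainConfig,
    branches: Sequence[str] = BRANCHES,
    test_fraction: float = 0.2,
    overrides: Dict[str, dict] | None = None,
) -> PipelineResult:
    """Held-out evaluation of the full protocol on one encoded dataset."""
    seeds = derive_seeds(cfg.seed, "holdout")
    train_idx, test_idx = split_train_val(
        len(data.protein_ids), test_fraction, seeds["holdout"]
    )
    stack = train_stack(data, train_idx, cfg, branches, overrides)
    scores = stack.predict(data, test_idx)
    y_test = data.y[test_idx]
    if not y_test.any():
        raise EvaluationError(
            "held-out proteins carry no positive label; use more data or fewer terms"
        )
    return PipelineResult(
        report=evaluate(scores, y_test),
        stack=stack,
        test_idx=test_idx,
        scores=scores,
        data=data,
    )


def run_kfold_cv(
    data: EncodedDataset,
    k: int = 5,
    cfg: TrainConfig | None = None,
    branches: Sequence[str] = BRANCHES,
    overrides: Dict[str, dict] | None = None,
) -> Tuple[List[EvalReport], Dict[str, float]]:
    """k-fold cross-validation with per-fold branch pretraining (no reuse of
    globally pretrained branches, so no information crosses fold boundaries).

    Returns the per-fold reports and the mean F-max/AUPR/AUC.
    """
    cfg = cfg or TrainConfig()
    n = len(data.protein_ids)
    if k < 2:
        raise ConfigurationError(f"k-fold CV needs k >= 2, got {k}")
    if n < k:
        raise ConfigurationError(f"cannot split {n} proteins into {k} folds")
    seeds = derive_seeds(cfg.seed, "folds")
    perm = np.random.default_rng(seeds["folds"]).permutation(n)
    folds = np.array_split(perm, k)
    reports: List[EvalReport] = []
    for i, fold in enumerate(folds):
        train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        test_idx = np.sort(fold)
        y_test = data.y[test_idx]
        if not y_test.any():
            raise EvaluationError(
                f"fold {i} has zero positive labels for every term; "
                "use more data or fewer terms"
            )
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": derive_seeds(cfg.seed, f"fold{i}")[f"fold{i}"]})
        stack = train_stack(data, train_idx, fold_cfg, branches, overrides)
        reports.append(evaluate(stack.predict(data, test_idx), y_test))
    mean = {
        "fmax": float(np.mean([r.fmax for r in reports])),
        "aupr": float(np.mean([r.aupr for r in reports])),
        "auc": float(np.mean([r.auc for r in reports])),
    }
    return reports, mean


def run_domain_ablation(
    data: EncodedDataset,
    cfg: TrainConfig,
    test_fraction: float = 0.2,
    overrides: Dict[str, dict] | None = None,
) -> Tuple[EvalReport, EvalReport]:
    """(full report, no-domain report) under identical seeds and splits.

    The sequence and PPI branches are pretrained once and shared; the ablated
    variant re-trains only the fusion classifier with an input mask whose rows
    sum to 2 (sequence + PPI), mirroring how the full classifier's rows sum
    to 3.
    """
    seeds = derive_seeds(cfg.seed, "holdout")
    train_idx, test_idx = split_train_val(
        len(data.protein_ids), test_fraction, seeds["holdout"]
    )
    stack = train_stack(data, train_idx, cfg, BRANCHES, overrides)
    y_test = data.y[test_idx]
    report_full = evaluate(stack.predict(data, test_idx), y_test)

    ablated_branches = ("sequence", "ppi")
    fusion_rows = stack.fusion_rows  # same out-of-sample rows as the full fusion
    outputs_tr = [
        stack.branches[b].predict_proba(data.branch_input(b)[fusion_rows])
        for b in ablated_branches
    ]
    fcfg = TrainConfig(**{**cfg.__dict__, **(overrides or {}).get("classifier", {}),
                          "seed": derive_seeds(cfg.seed, "fusion.ablated")["fusion.ablated"]})
    masks = build_classifier_masks(data.n_terms, n_branches=2)
    clf_abl, _ = train_classifier(outputs_tr, data.y[fusion_rows], fcfg, masks)
    outputs_te = [
        stack.branches[b].predict_proba(data.branch_input(b)[test_idx])
        for b in ablated_branches
    ]
    report_ablated = evaluate(clf_abl.forward_branches(*outputs_te), y_test)
    return report_full, report_ablated
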