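"""Fully synthetic benchmark data with planted modality-to-term signal.

The generator emulates the four external inputs of the pipeline — protein
sequences (FASTA), domain hits (TSV), scored PPI links (TSV) and GO
annotations (GAF subset) — and plants a configurable, recoverable mapping
from data features to GO terms:

* a **domain** term is carried by exactly the proteins bearing its signal
  domain;
* a **motif** term by exactly the proteins whose sequence contains its
  planted 5-residue motif;
* a **ppi** term by exactly the members of its planted interaction cluster
  (cluster-internal links score in [700, 999], background links in
  [150, 699], so the standard 400-score filter keeps most signal and some
  noise).

True labels follow these rules and are then flipped independently with
probability ``label_noise``. Everything derives from named substreams of a
single seed, so datasets are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Literal, Sequence

import numpy as np

from . import io
from .errors import ConfigurationError
from .io import AMINO_ACIDS, AnnotationRecord, DomainHit, ScoredLink, SequenceRecord

SignalKind = Literal["domain", "motif", "ppi", "none"]


@dataclass(frozen=True)
class TermSignal:
    """How one GO term's true labels are generated."""

    term: str
    kind: SignalKind
    domain_id: str | None = None
    motif: str | None = None
    cluster: int | None = None


@dataclass
class SimConfig:
    """Knobs of the synthetic benchmark; defaults are the study conditions
    used throughout the tests (500 proteins, 20 terms, noiseless labels so
    the planted signal is exactly recoverable; ``label_noise`` flips labels
    independently when a harder, noisy variant is wanted)."""

    n_proteins: int = 500
    n_terms: int = 20
    n_domains: int = 30
    n_clusters: int = 7
    seq_len_range: tuple = (60, 200)
    domain_hits_range: tuple = (1, 5)
    overlap_fraction: float = 0.3
    link_density: float = 0.01          # background link probability per pair
    cluster_link_prob: float = 0.5      # within-cluster link probability
    signal_domain_prob: float = 0.3     # P(protein carries a given signal domain)
    motif_prob: float = 0.3             # P(protein carries a given motif)
    label_noise: float = 0.0
    ontology: str = "MF"
    motif_len: int = 5
    #: per-term signal kinds; None means round-robin domain/motif/ppi
    signal_kinds: Sequence[SignalKind] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_terms < 1 or self.n_domains < 1:
            raise ConfigurationError("counts must be positive")
        if not (0 <= self.label_noise < 0.5):
            raise ConfigurationError("label_noise must lie in [0, 0.5)")
        lo, hi = self.seq_len_range
        if not (self.motif_len <= lo <= hi <= 1500):
            raise ConfigurationError(
                f"seq_len_range {self.seq_len_range} must fit in "
                f"[{self.motif_len}, 1500]"
            )
        kinds = self.resolved_kinds()
        if sum(k == "domain" for k in kinds) > self.n_domains:
            raise ConfigurationError(
                "more domain-signal terms than available domains"
            )
        if sum(k == "ppi" for k in kinds) > self.n_clusters:
            raise ConfigurationError(
                "more ppi-signal terms than planted clusters"
            )

    def resolved_kinds(self) -> List[SignalKind]:
        if self.signal_kinds is not None:
            if len(self.signal_kinds) != self.n_terms:
                raise ConfigurationError(
                    f"signal_kinds has {len(self.signal_kinds)} entries for "
                    f"{self.n_terms} terms"
                )
            return list(self.signal_kinds)
        cycle: List[SignalKind] = ["domain", "motif", "ppi"]
        return [cycle[k % 3] for k in range(self.n_terms)]


@dataclass
class SyntheticDataset:
    """Generated records plus the realized truth (signals and cluster map)."""

    sequences: List[SequenceRecord]
    domain_hits: List[DomainHit]
    links: List[ScoredLink]
    annotations: List[AnnotationRecord]
    truth_signals: List[TermSignal]
    cluster_of: Dict[str, int]
    config: SimConfig = field(repr=False)

    @property
    def protein_ids(self) -> List[str]:
        return [r.protein_id for r in self.sequences]


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    names = ("sequence", "motif", "domain", "link", "label", "noise")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _place_hits(rng: np.random.Generator, length: int, n_hits: int,
                overlap_fraction: float) -> List[tuple[int, int]]:
    """1-based inclusive intervals; after the first, each hit is forced to
    overlap an earlier one (crossing or containing) with probability
    ``overlap_fraction`` and otherwise placed detached when space allows."""
    spans: List[tuple[int, int]] = []
    for i in range(n_hits):
        width = min(int(rng.integers(5, max(6, length // 8 + 1))), length)
        if i and rng.random() < overlap_fraction:
            a, b = spans[int(rng.integers(len(spans)))]
            start = int(rng.integers(a, b + 1))  # starts inside an earlier hit
        else:
            start = int(rng.integers(1, max(2, length - width + 2)))
            for _ in range(30):  # aim for a detached placement
                end = min(start + width - 1, length)
                if all(end < a or b < start for a, b in spans):
                    break
                start = int(rng.integers(1, max(2, length - width + 2)))
        end = min(start + width - 1, length)
        spans.append((start, end))
    return spans


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Draw a complete dataset from ``cfg`` (deterministic in ``cfg.seed``)."""
    cfg.validate()
    rng = _streams(cfg.seed)
    kinds = cfg.resolved_kinds()
    terms = [f"GO:{k + 1:07d}" for k in range(cfg.n_terms)]
    domain_ids = [f"D{d:04d}" for d in range(cfg.n_domains)]
    aa = np.array(list(AMINO_ACIDS))

    # realize per-term signals
    signals: List[TermSignal] = []
    next_domain, next_cluster = 0, 0
    for term, kind in zip(terms, kinds):
        if kind == "domain":
            signals.append(TermSignal(term, kind, domain_id=domain_ids[next_domain]))
            next_domain += 1
        elif kind == "motif":
            motif = "".join(rng["motif"].choice(aa, size=cfg.motif_len))
            signals.append(TermSignal(term, kind, motif=motif))
        elif kind == "ppi":
            signals.append(TermSignal(term, kind, cluster=next_cluster))
            next_cluster += 1
        else:
            signals.append(TermSignal(term, "none"))

    ids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    cluster_of = {
        pid: int(c)
        for pid, c in zip(ids, rng["link"].integers(0, cfg.n_clusters, cfg.n_proteins))
    }

    # sequences with injected motifs
    lo, hi = cfg.seq_len_range
    sequences: List[SequenceRecord] = []
    has_motif = np.zeros((cfg.n_proteins, cfg.n_terms), dtype=bool)
    for i, pid in enumerate(ids):
        length = int(rng["sequence"].integers(lo, hi + 1))
        seq = rng["sequence"].choice(aa, size=length)
        occupied: List[tuple[int, int]] = []
        for sig in signals:
            if sig.kind != "motif" or rng["sequence"].random() >= cfg.motif_prob:
                continue
            # non-overlapping placement so one motif cannot corrupt another
            for _ in range(20):
                pos = int(rng["sequence"].integers(0, length - cfg.motif_len + 1))
                if all(pos + cfg.motif_len <= a or pos >= b for a, b in occupied):
                    seq[pos : pos + cfg.motif_len] = list(sig.motif)
                    occupied.append((pos, pos + cfg.motif_len))
                    break
        seq_str = "".join(seq)
        # truth is actual substring presence (covers chance occurrences too)
        for k, sig in enumerate(signals):
            if sig.kind == "motif":
                has_motif[i, k] = sig.motif in seq_str
        sequences.append(SequenceRecord(pid, seq_str))

    # domain hits: planted signal domains + background hits with overlap mix
    signal_domains = [s.domain_id for s in signals if s.kind == "domain"]
    background = [d for d in domain_ids if d not in set(signal_domains)]
    hits: List[DomainHit] = []
    carries = np.zeros((cfg.n_proteins, cfg.n_terms), dtype=bool)
    h_lo, h_hi = cfg.domain_hits_range
    for i, (pid, rec) in enumerate(zip(ids, sequences)):
        length = len(rec.sequence)
        chosen: List[str] = []
        for k, sig in enumerate(signals):
            if sig.kind == "domain" and rng["domain"].random() < cfg.signal_domain_prob:
                chosen.append(sig.domain_id)
                carries[i, k] = True
        n_bg = int(rng["domain"].integers(h_lo, h_hi + 1))
        if background:
            chosen += list(rng["domain"].choice(background, size=n_bg))
        spans = _place_hits(rng["domain"], length, len(chosen), cfg.overlap_fraction)
        for dom, (s, e) in zip(chosen, spans):
            hits.append(DomainHit(pid, dom, s, e))

    # PPI links: dense high-scored clusters over a sparse low-scored background
    links: List[ScoredLink] = []
    lrng = rng["link"]
    for i in range(cfg.n_proteins):
        for j in range(i + 1, cfg.n_proteins):
            same = cluster_of[ids[i]] == cluster_of[ids[j]]
            if same and lrng.random() < cfg.cluster_link_prob:
                score = int(lrng.integers(700, 1000))
            elif lrng.random() < cfg.link_density:
                score = int(lrng.integers(150, 700))
            else:
                continue
            links.append(ScoredLink(ids[i], ids[j], score))

    # labels by rule, then independent flips
    truth = np.zeros((cfg.n_proteins, cfg.n_terms), dtype=bool)
    for k, sig in enumerate(signals):
        if sig.kind == "domain":
            truth[:, k] = carries[:, k]
        elif sig.kind == "motif":
            truth[:, k] = has_motif[:, k]
        elif sig.kind == "ppi":
            truth[:, k] = [cluster_of[pid] == sig.cluster for pid in ids]
    if cfg.label_noise > 0:
        flips = rng["noise"].random(truth.shape) < cfg.label_noise
        truth = truth ^ flips

    annotations = [
        AnnotationRecord(ids[i], terms[k], cfg.ontology)
        for i in range(cfg.n_proteins)
        for k in range(cfg.n_terms)
        if truth[i, k]
    ]
    return SyntheticDataset(
        sequences=sequences,
        domain_hits=hits,
        links=links,
        annotations=annotations,
        truth_signals=signals,
        cluster_of=cluster_of,
        config=cfg,
    )


def make_protvec_stub(alphabet: str = AMINO_ACIDS, dim: int = 100,
                      seed: int = 0) -> io.TrigramTable:
    """Deterministic unit-norm stand-in for a pre-trained trigram embedding
    table (synthetic: one pseudo-random vector per possible trigram)."""
    if dim < 1:
        raise ConfigurationError("embedding dim must be >= 1")
    tokens = [a + b + c for a in alphabet for b in alphabet for c in alphabet]
    rng = np.random.default_rng(seed)
    vecs = rng.normal(size=(len(tokens), dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return {tok: vecs[i] for i, tok in enumerate(tokens)}


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> Dict[str, Path]:
    """Emit FASTA + three TSVs + a truth JSON, all readable by :mod:`gofuse.io`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "sequences.fasta",
        "domains": directory / "domains.tsv",
        "links": directory / "links.tsv",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.json",
    }
    io.write_fasta(dataset.sequences, paths["fasta"])
    io.write_domain_table(dataset.domain_hits, paths["domains"])
    io.write_scored_links(dataset.links, paths["links"])
    io.write_annotations(dataset.annotations, paths["annotations"])
    truth = {
        "signals": [asdict(s) for s in dataset.truth_signals],
        "cluster_of": dataset.cluster_of,
        "config": asdict(dataset.config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def rule_based_scores(dataset: SyntheticDataset) -> np.ndarray:
    """Oracle classifier that reads the realized truth signals directly.

    With ``label_noise=0`` its predictions match the generated labels exactly
    (F-max 1.0), which validates the generator independently of any learning.
    """
    ids = dataset.protein_ids
    idx = {p: i for i, p in enumerate(ids)}
    n, t = len(ids), len(dataset.truth_signals)
    scores = np.zeros((n, t))
    domain_carriers: Dict[str, set] = {}
    for h in dataset.domain_hits:
        domain_carriers.setdefault(h.domain_id, set()).add(h.protein_id)
    for k, sig in enumerate(dataset.truth_signals):
        if sig.kind == "domain":
            for pid in domain_carriers.get(sig.domain_id, ()):
                scores[idx[pid], k] = 1.0
        elif sig.kind == "motif":
            for rec in dataset.sequences:
                if sig.motif in rec.sequence:
                    scores[idx[rec.protein_id], k] = 1.0
        elif sig.kind == "ppi":
            for pid in ids:
                if dataset.cluster_of[pid] == sig.cluster:
                    scores[idx[pid], k] = 1.0
    return scores
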