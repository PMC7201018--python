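"""Fixed-shape model inputs from raw records.

Four representations are produced per protein:

* a trigram embedding matrix from the padded amino-acid sequence (the paper's
  field-standard ProtVec-style encoding: pad to a fixed length, slide a
  3-residue window with step 1, embed each trigram as a 100-D vector, with
  padding-containing trigrams mapped to the zero vector);
* a "domain sentence": the protein's deduplicated domain hits sorted by
  regional center point and mapped to integer vocabulary indices, padded with
  the reserved index 0;
* a row of the thresholded PPI score matrix (STRING-style combined scores,
  kept only when strictly above the threshold);
* a binary label vector over the GO terms selected for an ontology by an
  annotation-count threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .errors import ConfigurationError, ShapeError, ValidationError
from .io import AnnotationRecord, DomainHit, ScoredLink, TrigramTable

#: Sequence padding symbol. A non-residue token, so padded trigrams can never
#: collide with real amino-acid trigrams.
PAD_CHAR = "0"

#: Default fixed sequence length; longer proteins are excluded upstream.
SEQ_TARGET_LEN = 1500

#: Default STRING-style combined-score threshold; links must score strictly higher.
PPI_SCORE_THRESHOLD = 400

#: Embedding width of the trigram table.
TRIGRAM_DIM = 100


def pad_sequence(seq: str, target_len: int = SEQ_TARGET_LEN, protein_id: str = "?") -> str:
    """Right-pad ``seq`` with :data:`PAD_CHAR` to exactly ``target_len``."""
    if len(seq) > target_len:
        raise ValidationError(
            f"protein {protein_id!r}: sequence length {len(seq)} exceeds {target_len}"
        )
    return seq + PAD_CHAR * (target_len - len(seq))


def extract_trigrams(padded: str) -> List[str]:
    """Slide a window of length 3 with step 1; a length-L string gives L-2 tokens."""
    if len(padded) < 3:
        raise ValidationError(f"sequence of length {len(padded)} has no trigrams")
    return [padded[i : i + 3] for i in range(len(padded) - 2)]


def embed_trigrams(
    tokens: Sequence[str],
    table: TrigramTable,
    expected_len: int | None = None,
    dim: int = TRIGRAM_DIM,
) -> np.ndarray:
    """Map trigram tokens to a (len(tokens), dim) float matrix.

    Tokens containing the padding symbol, and tokens absent from the table
    (e.g. containing X), map to the all-zero vector.
    """
    if expected_len is not None and len(tokens) != expected_len:
        raise ShapeError(f"expected {expected_len} trigram tokens, got {len(tokens)}")
    mat = np.zeros((len(tokens), dim), dtype=np.float32)
    for i, tok in enumerate(tokens):
        if PAD_CHAR in tok:
            continue
        vec = table.get(tok)
        if vec is not None:
            mat[i] = vec
    return mat


def encode_sequence(
    seq: str,
    table: TrigramTable,
    target_len: int = SEQ_TARGET_LEN,
    protein_id: str = "?",
) -> np.ndarray:
    """pad -> trigrams -> embed, returning a (target_len - 2, 100) matrix."""
    padded = pad_sequence(seq, target_len, protein_id)
    return embed_trigrams(extract_trigrams(padded), table, expected_len=target_len - 2)


def dedup_domain_hits(hits: Sequence[DomainHit]) -> List[DomainHit]:
    """Drop exact duplicates in (domain_id, start, end); first occurrence wins."""
    seen: set[tuple[str, int, int]] = set()
    out: List[DomainHit] = []
    for h in hits:
        key = (h.domain_id, h.start, h.end)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def center_point(hit: DomainHit) -> float:
    """Regional center point (start + end) / 2 of a domain hit's interval."""
    return (hit.start + hit.end) / 2.0


def sort_domains(hits: Sequence[DomainHit]) -> List[DomainHit]:
    """Order hits by ascending regional center point.

    For detached pairs this is simply left-to-right order; for crossing or
    containing pairs the hit whose interval midpoint lies further left comes
    first. Ties break by (start, end, domain_id) so the order is deterministic.
    """
    return sorted(hits, key=lambda h: (center_point(h), h.start, h.end, h.domain_id))


@dataclass(frozen=True)
class DomainVocabulary:
    """Mapping domain_id -> index in 1..D; index 0 is reserved for padding."""

    index: Dict[str, int]

    @property
    def size(self) -> int:
        """Number of rows of the lookup table: distinct domains + padding row."""
        return len(self.index) + 1

    def __getitem__(self, domain_id: str) -> int:
        return self.index[domain_id]


def build_domain_vocab(hits: Iterable[DomainHit]) -> DomainVocabulary:
    """Assign indices 1..D to distinct domain ids in sorted order."""
    distinct = sorted({h.domain_id for h in hits})
    return DomainVocabulary({d: i for i, d in enumerate(distinct, start=1)})


def encode_domain_sentence(
    sorted_hits: Sequence[DomainHit],
    vocab: DomainVocabulary,
    max_len: int,
    protein_id: str = "?",
) -> np.ndarray:
    """Integer index vector of length ``max_len``, zero-padded at the tail."""
    if len(sorted_hits) > max_len:
        raise ValidationError(
            f"protein {protein_id!r}: {len(sorted_hits)} domain hits exceed "
            f"the sentence length {max_len}"
        )
    sentence = np.zeros(max_len, dtype=np.int64)
    for i, h in enumerate(sorted_hits):
        sentence[i] = vocab[h.domain_id]
    return sentence


def build_ppi_matrix(
    links: Sequence[ScoredLink],
    proteins: Sequence[str],
    threshold: int = PPI_SCORE_THRESHOLD,
    normalize: bool = False,
) -> np.ndarray:
    """Symmetric N x N score matrix over ``proteins``.

    Only links scoring strictly above ``threshold`` contribute; endpoints not
    in ``proteins`` are ignored; the diagonal is zero. With ``normalize`` the
    retained scores are divided by 1000 to land in [0, 1].
    """
    if len(set(proteins)) != len(proteins):
        raise ValidationError("protein list for the PPI matrix contains duplicates")
    idx = {p: i for i, p in enumerate(proteins)}
    mat = np.zeros((len(proteins), len(proteins)), dtype=np.float32)
    for ln in links:
        if ln.score <= threshold:
            continue
        ia, ib = idx.get(ln.protein_a), idx.get(ln.protein_b)
        if ia is None or ib is None:
            continue
        val = ln.score / 1000.0 if normalize else float(ln.score)
        mat[ia, ib] = val
        mat[ib, ia] = val
    return mat


@dataclass(frozen=True)
class GoTermSet:
    """Ordered GO terms selected for one sub-ontology.

    Terms are ordered by descending distinct-protein annotation count with
    GO-id tie-break, so label vectors and classifier wiring are reproducible.
    """

    ontology: str
    terms: List[str]
    min_count: int
    counts: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)


def select_go_terms(
    annotations: Sequence[AnnotationRecord], ontology: str, min_count: int
) -> GoTermSet:
    """Keep terms annotated on at least ``min_count`` distinct proteins."""
    proteins_per_term: Dict[str, set] = {}
    for a in annotations:
        if a.ontology == ontology:
            proteins_per_term.setdefault(a.go_term, set()).add(a.protein_id)
    counts = {t: len(ps) for t, ps in proteins_per_term.items()}
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ConfigurationError(
            f"no {ontology} GO term reaches min_count={min_count}; "
            "the classifier would have no outputs"
        )
    return GoTermSet(ontology, kept, min_count, {t: counts[t] for t in kept})


def build_label_vector(
    protein_id: str,
    annotations: Sequence[AnnotationRecord],
    term_set: GoTermSet,
) -> np.ndarray:
    """Binary vector aligned with ``term_set.terms``; non-selected terms ignored."""
    annotated = {
        a.go_term
        for a in annotations
        if a.protein_id == protein_id and a.ontology == term_set.ontology
    }
    return np.asarray([1 if t in annotated else 0 for t in term_set.terms], dtype=np.float32)


def build_label_matrix(
    protein_ids: Sequence[str],
    annotations: Sequence[AnnotationRecord],
    term_set: GoTermSet,
) -> np.ndarray:
    """Stacked label vectors, one row per protein (vectorised convenience)."""
    tidx = {t: j for j, t in enumerate(term_set.terms)}
    pidx = {p: i for i, p in enumerate(protein_ids)}
    mat = np.zeros((len(protein_ids), len(term_set.terms)), dtype=np.float32)
    for a in annotations:
        if a.ontology != term_set.ontology:
            continue
        i, j = pidx.get(a.protein_id), tidx.get(a.go_term)
        if i is not None and j is not None:
            mat[i, j] = 1.0
    return mat
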