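"""Readers and writers for every external file the pipeline touches.

Formats are deliberately minimal, plain-text dialects of the field's standard
files: FASTA for sequences, a 4-column TSV of domain hits (InterPro-style,
1-based inclusive coordinates), a 3-column whitespace table of scored
protein-protein links (STRING-style combined scores in [0, 1000]), a 3-column
GAF subset for GO annotations, a ProtVec-style trigram embedding table, and a
CAFA-style 3-column prediction file.

All readers validate invariants eagerly and report the offending line or id;
all writers round-trip bit-faithfully through their reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List

import numpy as np
from Bio import SeqIO

from .errors import FormatError, ValidationError

GO_TERM_RE = re.compile(r"^GO:\d{7}$")
ONTOLOGIES = ("BP", "MF", "CC")

#: Amino-acid alphabet; X is tolerated as "unknown residue".
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence; ``protein_id`` is the FASTA header's first token."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"empty sequence for protein {self.protein_id!r}")


@dataclass(frozen=True)
class DomainHit:
    """A domain located on a protein; coordinates are 1-based inclusive."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain hit {self.domain_id!r} on {self.protein_id!r}: "
                f"need 1 <= start <= end, got start={self.start}, end={self.end}"
            )


@dataclass(frozen=True)
class ScoredLink:
    """A scored protein-protein link; integer confidence in [0, 1000]."""

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValidationError(f"self-link on protein {self.protein_a!r}")
        if not (0 <= self.score <= 1000):
            raise ValidationError(
                f"link ({self.protein_a!r}, {self.protein_b!r}): "
                f"score {self.score} outside [0, 1000]"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    """One GO annotation restricted to one of the three sub-ontologies."""

    protein_id: str
    go_term: str
    ontology: str

    def __post_init__(self) -> None:
        if not GO_TERM_RE.match(self.go_term):
            raise ValidationError(f"malformed GO identifier {self.go_term!r}")
        if self.ontology not in ONTOLOGIES:
            raise ValidationError(
                f"unknown ontology {self.ontology!r}; expected one of {ONTOLOGIES}"
            )


# TrigramTable: mapping trigram token -> length-100 (or table-wide dim) vector.
TrigramTable = Dict[str, np.ndarray]


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and wrapped lines joined; the id is the header
    token before the first whitespace. Duplicate ids raise ValidationError.
    """
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValidationError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(SequenceRecord(pid, str(entry.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _tsv_rows(path: str | Path, n_cols: int, skip_comment: str | None = None):
    """Yield (line_number, fields) for non-empty lines of a TSV-ish file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if skip_comment and line.startswith(skip_comment):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            yield lineno, fields


def read_domain_table(path: str | Path) -> List[DomainHit]:
    """Read a TSV of (protein_id, domain_id, start, end); file order preserved."""
    hits: List[DomainHit] = []
    for lineno, (pid, dom, s, e) in _tsv_rows(path, 4):
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        try:
            hits.append(DomainHit(pid, dom, start, end))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_id}\t{h.start}\t{h.end}\n")


def read_scored_links(path: str | Path) -> List[ScoredLink]:
    """Read (protein_a, protein_b, score) links; no thresholding at read time."""
    links: List[ScoredLink] = []
    for lineno, (a, b, s) in _tsv_rows(path, 3):
        try:
            score = int(s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer score {s!r}") from exc
        try:
            links.append(ScoredLink(a, b, score))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return links


def write_scored_links(links: Iterable[ScoredLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ln in links:
            fh.write(f"{ln.protein_a}\t{ln.protein_b}\t{ln.score}\n")


def read_annotations(path: str | Path) -> List[AnnotationRecord]:
    """Read a 3-column GAF subset; lines starting with '!' are comments."""
    anns: List[AnnotationRecord] = []
    for lineno, (pid, term, ont) in _tsv_rows(path, 3, skip_comment="!"):
        try:
            anns.append(AnnotationRecord(pid, term, ont))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return anns


def write_annotations(anns: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-subset: protein_id\tgo_term\tontology\n")
        for a in anns:
            fh.write(f"{a.protein_id}\t{a.go_term}\t{a.ontology}\n")


def read_trigram_table(path: str | Path, dim: int = 100) -> TrigramTable:
    """Read a ProtVec-style table: token followed by ``dim`` floats per line."""
    table: TrigramTable = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            token = fields[0]
            if len(fields) - 1 != dim:
                raise FormatError(
                    f"{path}:{lineno}: token {token!r} has {len(fields) - 1} "
                    f"components, expected {dim}"
                )
            table[token] = np.asarray([float(x) for x in fields[1:]], dtype=np.float64)
    return table


def write_trigram_table(table: TrigramTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for token in sorted(table):
            vec = "\t".join(format(v, ".17g") for v in table[token])
            fh.write(f"{token}\t{vec}\n")


def write_predictions(scores: "PredictionScores", path: str | Path) -> None:
    """Write CAFA-style rows ``protein_id  GO:term  score`` (3 decimals).

    Rows are emitted in deterministic order: by protein id, then by term id.
    """
    mat = np.asarray(scores.matrix, dtype=float)
    if mat.size and (mat.min() < 0.0 or mat.max() > 1.0):
        raise ValidationError("prediction scores must lie in [0, 1]")
    order_p = np.argsort(np.asarray(scores.protein_ids, dtype=object))
    order_t = np.argsort(np.asarray(scores.terms, dtype=object))
    with open(path, "w") as fh:
        for i in order_p:
            for j in order_t:
                fh.write(f"{scores.protein_ids[i]}\t{scores.terms[j]}\t{mat[i, j]:.3f}\n")


def read_predictions(path: str | Path) -> "PredictionScores":
    """Read a CAFA-style prediction file back into a score matrix."""
    from .models import PredictionScores

    rows: list[tuple[str, str, float]] = []
    for lineno, (pid, term, s) in _tsv_rows(path, 3):
        try:
            val = float(s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score {s!r}") from exc
        if not (0.0 <= val <= 1.0):
            raise ValidationError(f"{path}:{lineno}: score {val} outside [0, 1]")
        rows.append((pid, term, val))
    proteins = sorted({r[0] for r in rows})
    terms = sorted({r[1] for r in rows})
    pidx = {p: i for i, p in enumerate(proteins)}
    tidx = {t: j for j, t in enumerate(terms)}
    mat = np.zeros((len(proteins), len(terms)), dtype=float)
    for pid, term, val in rows:
        mat[pidx[pid], tidx[term]] = val
    return PredictionScores(protein_ids=proteins, terms=terms, matrix=mat)
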