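"""Readers, writers and domain types for the external formats the pipeline touches.

The pipeline's carriers are deliberately plain: a gene x sample count matrix
(:class:`pandas.DataFrame` of non-negative integers), a sample annotation
table (``sample_id`` index with ``kinase``, ``environment``, ``replicate``
columns), :class:`GeneSet` for signature/annotation collections (GMT files),
and :class:`PWM` for transcription-factor binding preferences (JASPAR text
PFM blocks). Gene and sample identifiers are opaque, case-sensitive strings;
mapping between systematic and common gene names is the caller's concern.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSet",
    "PWM",
    "ANNOTATION_COLUMNS",
    "read_count_matrix",
    "write_count_matrix",
    "validate_annotation",
    "read_gmt",
    "write_gmt",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta_promoters",
    "write_fasta_promoters",
]

ANNOTATION_COLUMNS = ("kinase", "environment", "replicate")

_BASES = "ACGT"
_PROMOTER_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersect(self, genes: Iterable[str]) -> frozenset[str]:
        return self.members.intersection(genes)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over A,C,G,T with an explicit background model.

    ``matrix`` holds column-stochastic probabilities, shape (4, L), rows in
    A,C,G,T order. Probabilities normally come from counts via
    ``(count + pseudocount) / (colsum + 4 * pseudocount)``.
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)
        if matrix.ndim != 2 or matrix.shape[0] != 4:
            raise ValueError(f"PWM {self.tf_name!r}: matrix must be 4 x L")
        if matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.tf_name!r}: motif length must be >= 4")
        colsums = matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.tf_name!r}: columns must sum to 1")
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError(f"PWM {self.tf_name!r}: background must be a 4-vector summing to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per base and position; -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        """Maximum achievable log-odds score over all sequences of length L."""
        return float(self.log_odds().max(axis=0).sum())

    @classmethod
    def from_counts(
        cls,
        tf_name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"PFM {tf_name!r}: expected 4 rows of counts")
        if (counts < 0).any():
            raise ValueError(f"PFM {tf_name!r}: negative count")
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
        kwargs = {} if background is None else {"background": background}
        return cls(tf_name=tf_name, matrix=probs, **kwargs)


# ---------------------------------------------------------------------------
# count matrix + annotation


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the sample annotation table and normalize its dtypes."""
    ann = annotation.copy()
    if ann.index.name != "sample_id":
        if "sample_id" in ann.columns:
            ann = ann.set_index("sample_id")
        else:
            raise ValueError("annotation must have a sample_id column or index")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    if ann.index.duplicated().any():
        dups = sorted(ann.index[ann.index.duplicated()].unique())
        raise ValueError(f"duplicate sample_ids in annotation: {dups}")
    ann["replicate"] = ann["replicate"].astype(int)
    if (ann["replicate"] < 1).any():
        bad = ann.index[ann["replicate"] < 1].tolist()
        raise ValueError(f"replicate must be >= 1; offending samples: {bad}")
    return ann


def read_count_matrix(
    path: str | Path, annotation_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count TSV together with its sample annotation.

    Returns ``(counts, annotation)`` with count columns reordered to the
    annotation's sample order. Raises ``ValueError`` naming the offending
    sample/gene on any mismatch.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = "gene"
    if counts.index.duplicated().any():
        dups = sorted(counts.index[counts.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in count matrix: {dups}")
    ann = validate_annotation(pd.read_csv(annotation_path, sep="\t"))
    missing = [s for s in counts.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples absent from annotation: {missing}")
    unmeasured = [s for s in ann.index if s not in counts.columns]
    if unmeasured:
        raise ValueError(f"annotated samples absent from count matrix: {unmeasured}")
    for col in counts.columns:
        values = counts[col]
        if not np.issubdtype(values.dtype, np.integer):
            as_float = values.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.rint(as_float)):
                bad_rows = counts.index[
                    ~np.isfinite(as_float) | (as_float != np.rint(as_float))
                ].tolist()
                raise ValueError(
                    f"non-integer count in column {col!r}, rows {bad_rows[:5]}"
                )
            counts[col] = as_float.astype(np.int64)
    if (counts.values < 0).any():
        raise ValueError("negative counts are not allowed")
    counts = counts[list(ann.index)]
    return counts, ann


def write_count_matrix(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    counts_path: str | Path,
    annotation_path: str | Path,
) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene")
    ann = annotation.reset_index() if annotation.index.name == "sample_id" else annotation
    ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> member1 <tab> member2 ...

    Order of lines is preserved; repeated members on a line are deduplicated.
    """
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            handle.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text


def read_jaspar_pfm(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Read JASPAR-style text PFM blocks (">ID NAME" then four A/C/G/T rows).

    Counts become column-stochastic probabilities through
    ``(count + pseudocount) / (colsum + 4 * pseudocount)``. The default
    pseudocount 0.5 keeps log-odds finite on zero counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    with open(path) as handle:
        text = handle.read()
    if not text.strip():
        return []
    try:
        parsed = bio_motifs.parse(_stdio.StringIO(text), "jaspar")
    except Exception as exc:  # malformed block, e.g. rows of unequal length
        raise ValueError(f"{path}: malformed JASPAR PFM ({exc})") from exc
    pwms: list[PWM] = []
    for motif in parsed:
        counts = np.array([motif.counts[b] for b in _BASES], dtype=float)
        name = motif.name or motif.matrix_id
        pwms.append(PWM.from_counts(name, counts, pseudocount=pseudocount))
    return pwms


def write_jaspar_pfm(pwms_or_counts: Sequence[tuple[str, np.ndarray]] | Sequence[PWM],
                     path: str | Path) -> None:
    """Write count matrices in JASPAR text format.

    Accepts ``(name, 4xL count array)`` pairs, or :class:`PWM` objects whose
    probability matrices are written scaled to 100 "counts" per column.
    """
    with open(path, "w") as handle:
        for item in pwms_or_counts:
            if isinstance(item, PWM):
                name, counts = item.tf_name, item.matrix * 100.0
            else:
                name, counts = item
                counts = np.asarray(counts, dtype=float)
            handle.write(f">{name} {name}\n")
            for base, row in zip(_BASES, counts):
                row_txt = " ".join(f"{v:.2f}".rstrip("0").rstrip(".") for v in row)
                handle.write(f"{base} [ {row_txt} ]\n")


# ---------------------------------------------------------------------------
# promoter FASTA


def read_fasta_promoters(path: str | Path) -> dict[str, str]:
    """Read promoter sequences keyed by gene id; uppercase, ACGTN alphabet."""
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in promoters:
            raise ValueError(f"duplicate promoter record id {record.id!r}")
        seq = str(record.seq).upper()
        for offset, char in enumerate(seq):
            if char not in _PROMOTER_ALPHABET:
                raise ValueError(
                    f"illegal character {char!r} at offset {offset} in record {record.id!r}"
                )
        promoters[record.id] = seq
    return promoters


def write_fasta_promoters(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")
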