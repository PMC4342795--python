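"""Clean-tag mapping, ambiguity filtering, counting and TPM normalization.

Observed tags are assigned to reference genes allowing at most one
mismatch.  Exact matches take priority over 1-mismatch matches; a tag whose
candidate gene set (at the winning distance) contains two or more genes is
ambiguous and filtered out.  Per-gene counts sum only unambiguous copies.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .taglib import ANCHOR, TAG_LENGTH, ReferenceTagLibrary, _VALID_BASES

#: assignment statuses, exhaustive and mutually exclusive
UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"
REJECTED = "rejected"

TPM_SCALE = 1_000_000


@dataclass
class TagCountSet:
    """One library's multiset of observed clean tags."""

    library_id: str
    counts: dict[str, int]

    @property
    def clean_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.counts.items())
        return pd.DataFrame(items, columns=["tag", "count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, library_id: str) -> "TagCountSet":
        counts = {
            tag: int(n) for tag, n in zip(frame["tag"], frame["count"])
        }
        return cls(library_id=library_id, counts=counts)


def validate_tag(tag: str) -> bool:
    """Structural QC: 21 nt, ACGT alphabet, leading anchor."""
    return (
        len(tag) == TAG_LENGTH
        and tag.startswith(ANCHOR)
        and _VALID_BASES.issuperset(tag)
    )


def assign_tag(tag: str, library: ReferenceTagLibrary) -> tuple[str, str | None]:
    """Assign one tag sequence; returns (status, gene_id or None).

    Ambiguity is evaluated at the gene level: multiple sites of the same
    gene do not make a tag ambiguous.
    """
    if not validate_tag(tag):
        return REJECTED, None
    genes = library.exact_genes(tag)
    if not genes:
        genes = library.neighbor_genes(tag)
    if len(genes) == 1:
        return UNAMBIGUOUS, next(iter(genes))
    if genes:
        return AMBIGUOUS, None
    return UNMAPPED, None


@dataclass
class MappingResult:
    """Per-library mapping outcome."""

    library_id: str
    gene_counts: dict[str, int]
    tag_status: dict[str, tuple[str, str | None]]
    copies: dict[str, int] = field(default_factory=dict)
    clean_total: int = 0

    @property
    def summary(self) -> dict[str, float]:
        """Distinct-tag fractions and copy-number accounting."""
        distinct = len(self.tag_status)
        n_gene = sum(1 for s, _ in self.tag_status.values() if s == UNAMBIGUOUS)
        n_ref = sum(
            1 for s, _ in self.tag_status.values() if s in (UNAMBIGUOUS, AMBIGUOUS)
        )
        return {
            "distinct_tags": distinct,
            "distinct_gene_fraction": n_gene / distinct if distinct else 0.0,
            "distinct_reference_fraction": n_ref / distinct if distinct else 0.0,
            "copies_unambiguous": self.copies.get(UNAMBIGUOUS, 0),
            "copies_ambiguous": self.copies.get(AMBIGUOUS, 0),
            "copies_unmapped": self.copies.get(UNMAPPED, 0),
            "copies_rejected": self.copies.get(REJECTED, 0),
            "clean_total": self.clean_total,
        }


def count_library(
    tags: TagCountSet,
    library: ReferenceTagLibrary,
    min_copies: int = 1,
) -> MappingResult:
    """Map every distinct tag of a library and total unambiguous copies.

    ``min_copies`` drops low-copy distinct tags before mapping (default 1,
    i.e. no filtering); dropped copies are counted as rejected so that
    copy-number conservation holds.
    """
    gene_counts: Counter[str] = Counter()
    tag_status: dict[str, tuple[str, str | None]] = {}
    copies: Counter[str] = Counter()
    for tag, n in tags.counts.items():
        if n < min_copies:
            tag_status[tag] = (REJECTED, None)
            copies[REJECTED] += n
            continue
        status, gene = assign_tag(tag, library)
        tag_status[tag] = (status, gene)
        copies[status] += n
        if status == UNAMBIGUOUS:
            gene_counts[gene] += n
    return MappingResult(
        library_id=tags.library_id,
        gene_counts=dict(gene_counts),
        tag_status=tag_status,
        copies=dict(copies),
        clean_total=tags.clean_total,
    )


@dataclass
class ExpressionMatrix:
    """Gene x library raw unambiguous tag counts with per-library totals.

    ``tpm[g, l] = raw[g, l] * 1e6 / clean_total[l]``.
    """

    raw: pd.DataFrame
    clean_totals: pd.Series
    tpm: pd.DataFrame | None = None

    @property
    def libraries(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.raw.index)


def build_matrix(
    results: Iterable[MappingResult],
    library_order: list[str] | None = None,
) -> ExpressionMatrix:
    """Assemble mapping results into a gene x library count matrix."""
    results = list(results)
    if library_order is None:
        library_order = [r.library_id for r in results]
    by_id = {r.library_id: r for r in results}
    missing = [lib for lib in library_order if lib not in by_id]
    if missing:
        raise ValueError(f"mapping results missing for libraries: {missing}")
    genes = sorted({g for r in results for g in r.gene_counts})
    raw = pd.DataFrame(
        {
            lib: [by_id[lib].gene_counts.get(g, 0) for g in genes]
            for lib in library_order
        },
        index=pd.Index(genes, name="gene"),
        dtype=np.int64,
    )
    totals = pd.Series(
        {lib: by_id[lib].clean_total for lib in library_order},
        name="clean_total",
    )
    return ExpressionMatrix(raw=raw, clean_totals=totals)


def normalize_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill the TPM view: tags per million clean tags."""
    for lib in matrix.libraries:
        if matrix.clean_totals[lib] <= 0:
            raise ValueError(f"library {lib!r} has clean_total <= 0")
    matrix.tpm = matrix.raw * TPM_SCALE / matrix.clean_totals
    return matrix


def from_counts(
    counts: Mapping[str, Mapping[str, int]],
    clean_totals: Mapping[str, int],
    library_order: list[str] | None = None,
) -> ExpressionMatrix:
    """Build a matrix directly from per-library gene-count mappings."""
    order = library_order or list(counts)
    genes = sorted({g for lib in counts.values() for g in lib})
    raw = pd.DataFrame(
        {lib: [counts[lib].get(g, 0) for g in genes] for lib in order},
        index=pd.Index(genes, name="gene"),
        dtype=np.int64,
    )
    totals = pd.Series({lib: int(clean_totals[lib]) for lib in order}, name="clean_total")
    return normalize_tpm(ExpressionMatrix(raw=raw, clean_totals=totals))


def mapping_summary_frame(results: Iterable[MappingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"library": r.library_id}
        row.update(r.summary)
        rows.append(row)
    return pd.DataFrame(rows)
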