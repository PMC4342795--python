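"""Virtual reference tag library construction.

A reference tag is the restriction-anchor tetramer ``CATG`` plus the 17 nt
immediately downstream, read from the sense strand of a coding sequence.
Libraries built from two genomes are merged with a priority rule: when a
genome-D gene's canonical (3'-most) tag is identical to — or within Hamming
distance 1 of — a genome-A canonical tag, the D gene's entries are dropped
and the A entry kept.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

TAG_LENGTH = 21
ANCHOR = "CATG"
SUFFIX_LENGTH = TAG_LENGTH - len(ANCHOR)
_VALID_BASES = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True, order=True)
class ReferenceTag:
    """One extractable tag site of a coding sequence.

    ``site_rank`` is 1 for the 3'-most qualifying anchor site and increases
    toward the 5' end.
    """

    sequence: str
    gene_id: str
    genome: str
    site_rank: int

    def __post_init__(self) -> None:
        if len(self.sequence) != TAG_LENGTH:
            raise ValueError(
                f"tag must be {TAG_LENGTH} nt, got {len(self.sequence)}"
            )
        if not self.sequence.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.sequence}")
        if not _VALID_BASES.issuperset(self.sequence):
            raise ValueError(f"tag has non-ACGT characters: {self.sequence}")


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def extract_tags(cds: str, gene_id: str, genome: str) -> list[ReferenceTag]:
    """Extract every anchor+17 nt tag from the sense strand of a CDS.

    One tag is produced per ``CATG`` occurrence that has at least 17 nt
    downstream; site_rank 1 is the 3'-most such occurrence.  Returns an
    empty list when no site qualifies.
    """
    cds = cds.upper()
    if not _VALID_BASES.issuperset(cds):
        bad = sorted(set(cds) - _VALID_BASES)
        raise InvalidSequenceError(
            f"gene {gene_id}: non-ACGT characters {bad} in CDS"
        )
    positions = []
    start = cds.find(ANCHOR)
    while start != -1:
        if len(cds) - (start + len(ANCHOR)) >= SUFFIX_LENGTH:
            positions.append(start)
        start = cds.find(ANCHOR, start + 1)
    tags = []
    # Ranks count from the 3' end: last qualifying site gets rank 1.
    for rank, pos in enumerate(reversed(positions), start=1):
        tags.append(
            ReferenceTag(
                sequence=cds[pos : pos + TAG_LENGTH],
                gene_id=gene_id,
                genome=genome,
                site_rank=rank,
            )
        )
    return tags


def _wildcard_keys(sequence: str) -> Iterator[str]:
    for i in range(len(sequence)):
        yield f"{i}:{sequence[:i]}*{sequence[i + 1:]}"


class ReferenceTagLibrary:
    """Non-redundant tag collection with exact and Hamming-1 lookup.

    Neighbour lookup uses positional wildcard keys (one key per masked
    position), which gives exact Hamming-distance-1 semantics.
    """

    def __init__(
        self,
        tags: Iterable[ReferenceTag],
        provenance: dict[str, int] | None = None,
    ) -> None:
        self.tags: list[ReferenceTag] = list(tags)
        self.provenance: dict[str, int] = dict(provenance or {})
        self._exact: dict[str, list[ReferenceTag]] = defaultdict(list)
        self._wild: dict[str, set[str]] = defaultdict(set)
        for tag in self.tags:
            self._exact[tag.sequence].append(tag)
        for seq in self._exact:
            for key in _wildcard_keys(seq):
                self._wild[key].add(seq)

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._exact

    def exact_genes(self, sequence: str) -> set[str]:
        """Gene ids whose reference tags equal ``sequence`` exactly."""
        return {t.gene_id for t in self._exact.get(sequence, ())}

    def neighbor_genes(self, sequence: str) -> set[str]:
        """Gene ids with a reference tag at Hamming distance exactly 1."""
        hits: set[str] = set()
        for key in _wildcard_keys(sequence):
            for seq in self._wild.get(key, ()):
                if seq != sequence:
                    hits.update(t.gene_id for t in self._exact[seq])
        return hits

    def within_radius(self, sequence: str) -> bool:
        """True if any library tag is within Hamming distance <= 1."""
        return sequence in self._exact or bool(self.neighbor_genes(sequence))

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (t.sequence, t.gene_id, t.genome, t.site_rank)
                for t in self.tags
            ],
            columns=["tag", "gene_id", "genome", "site_rank"],
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, provenance: dict[str, int] | None = None
    ) -> "ReferenceTagLibrary":
        tags = [
            ReferenceTag(row.tag, row.gene_id, row.genome, int(row.site_rank))
            for row in frame.itertuples(index=False)
        ]
        return cls(tags, provenance)


def canonical_tags(tags: Iterable[ReferenceTag]) -> dict[str, ReferenceTag]:
    """Map gene_id -> its site_rank-1 tag (genes without one are skipped)."""
    out: dict[str, ReferenceTag] = {}
    for tag in tags:
        if tag.site_rank == 1:
            if tag.gene_id in out:
                raise ValueError(f"gene {tag.gene_id} has two rank-1 tags")
            out[tag.gene_id] = tag
    return out


def merge_genomes(
    tags_a: Iterable[ReferenceTag],
    tags_d: Iterable[ReferenceTag],
    canonical_only: bool = False,
) -> ReferenceTagLibrary:
    """Merge two genomes' tag lists with A-genome priority.

    Canonical (site_rank 1) tags are compared across genomes; a D gene whose
    canonical tag lies within Hamming distance <= 1 of any A canonical tag
    is redundant and all of its tag entries are dropped.  Within-genome
    duplicates are retained (they resolve as ambiguous at mapping time).
    Result is independent of input ordering: D genes are processed in
    lexicographic gene_id order.

    With ``canonical_only`` the retained library keeps only site_rank-1 tags.
    """
    tags_a = list(tags_a)
    tags_d = list(tags_d)
    canon_a = canonical_tags(tags_a)
    canon_d = canonical_tags(tags_d)

    a_index = ReferenceTagLibrary(canon_a.values())

    dropped_genes_d: set[str] = set()
    dropped_identical = 0
    dropped_one_mismatch = 0
    for gene_id in sorted(canon_d):
        seq = canon_d[gene_id].sequence
        if seq in a_index:
            dropped_genes_d.add(gene_id)
            dropped_identical += 1
        elif a_index.neighbor_genes(seq):
            dropped_genes_d.add(gene_id)
            dropped_one_mismatch += 1

    kept: list[ReferenceTag] = []
    for tag in tags_a:
        if not canonical_only or tag.site_rank == 1:
            kept.append(tag)
    dropped_tags_d = 0
    for tag in tags_d:
        if tag.gene_id in dropped_genes_d:
            dropped_tags_d += 1
            continue
        if not canonical_only or tag.site_rank == 1:
            kept.append(tag)

    genes_d = {t.gene_id for t in tags_d}
    provenance = {
        "genes_a": len({t.gene_id for t in tags_a}),
        "genes_d": len(genes_d),
        "genes_d_dropped": len(dropped_genes_d),
        "genes_d_dropped_identical": dropped_identical,
        "genes_d_dropped_one_mismatch": dropped_one_mismatch,
        "genes_d_kept": len(genes_d) - len(dropped_genes_d),
        "tags_a_kept": sum(1 for t in kept if t.genome == "A"),
        "tags_d_dropped": dropped_tags_d,
    }
    return ReferenceTagLibrary(kept, provenance)
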