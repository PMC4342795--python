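"""Annotation-set over-representation analysis.

Consumes GMT-style term -> gene tables (pathways, GO slims, TF families,
hormone categories are all the same shape) and tests one-sided
over-representation of a study set against a background universe with the
hypergeometric upper tail, BH-corrected per namespace.  GO-DAG propagation
is deliberately not performed; tables must be pre-propagated if DAG
semantics are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .de import DegSet, bh_fdr

DEFAULT_ALPHA = 0.05


@dataclass
class AnnotationTable:
    namespace: str
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, term: str, name: str, genes: Iterable[str]) -> None:
        gene_set = frozenset(genes)
        if not gene_set:
            raise ValueError(f"term {term!r} has an empty gene set")
        self.terms[term] = (name, gene_set)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, namespace: str = "pathway") -> AnnotationTable:
    """GMT-style TSV: term <tab> name <tab> gene1 <tab> gene2 ..."""
    table = AnnotationTable(namespace=namespace)
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            table.add(parts[0], parts[1], parts[2:])
    return table


def write_gmt(table: AnnotationTable, path) -> None:
    with open(path, "w") as handle:
        for term, (name, genes) in sorted(table.terms.items()):
            handle.write("\t".join([term, name, *sorted(genes)]) + "\n")


def overrep_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided upper-tail hypergeometric P(X >= k) for a study of size n
    drawn from N with K marked."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    study: Iterable[str],
    background: Iterable[str],
    table: AnnotationTable,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One row per term with >= 1 background gene; BH across the namespace.

    Columns mirror the usual enrichment-report layout: term, name,
    gene_number (study hits), study_size, background_number, background_size,
    p_value, corrected_p, significant.
    """
    study_set = set(study)
    background_set = set(background)
    offenders = sorted(study_set - background_set)
    if offenders:
        raise ValueError(
            f"study genes missing from background: {offenders[:10]}"
        )
    n = len(study_set)
    big_n = len(background_set)
    rows = []
    for term, (name, genes) in table.terms.items():
        in_background = genes & background_set
        big_k = len(in_background)
        if big_k == 0:
            continue
        k = len(in_background & study_set)
        rows.append(
            {
                "term": term,
                "name": name,
                "gene_number": k,
                "study_size": n,
                "background_number": big_k,
                "background_size": big_n,
                "p_value": overrep_pvalue(k, n, big_k, big_n),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "gene_number", "study_size",
            "background_number", "background_size", "p_value",
        ],
    )
    if len(frame):
        frame["corrected_p"] = bh_fdr(frame["p_value"].to_numpy())
        frame["significant"] = frame["corrected_p"] < alpha
    else:
        frame["corrected_p"] = []
        frame["significant"] = []
    frame.attrs["namespace"] = table.namespace
    return frame


def summarize_directions(
    degs: DegSet,
    table: AnnotationTable,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term counts of up / down / complex DE genes.

    Direction labels default to the DegSet's own pairwise-direction
    summary; a mapping (e.g. from cluster types) may be supplied instead.
    Counts sum to |term intersect DEG| for every term.
    """
    raw_labels = dict(directions) if directions is not None else degs.directions()
    # cluster-type labels are accepted and folded onto directions
    alias = {"type_I": "down", "type_II": "up"}
    labels = {g: alias.get(v, v) for g, v in raw_labels.items()}
    rows = []
    for term, (name, genes) in table.terms.items():
        hits = genes & degs.genes
        counts = {"up": 0, "down": 0, "complex": 0}
        for gene in hits:
            counts[labels.get(gene, "complex")] += 1
        rows.append(
            {
                "term": term,
                "name": name,
                "total": len(hits),
                "upregulated": counts["up"],
                "downregulated": counts["down"],
                "complex": counts["complex"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term", "name", "total", "upregulated", "downregulated", "complex"],
    )
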