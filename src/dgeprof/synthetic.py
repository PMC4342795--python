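"""Ground-truthed synthetic data for the tag-profiling pipeline.

Generates a pair of divergent "A" / "D" genomes with controllable homeolog
structure, per-gene time-course abundance trajectories, and multinomially
sampled tag libraries with an optional per-base sequencing error model.
Every output records the generating seed and carries enough truth to serve
as an oracle for the mapping, differential-expression, clustering and
qPCR stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import taglib
from .mapping import TagCountSet
from .taglib import ANCHOR, SUFFIX_LENGTH, TAG_LENGTH

_BASES = np.array(list("ACGT"))

PATTERNS = ("down", "up", "peak", "flat")

#: abundance max/min ratio at or above which a gene is true-DE (four-fold)
DE_TRUTH_RATIO = 4.0


@dataclass
class SimulationConfig:
    """All knobs of the simulator; invalid values raise at construction."""

    n_genes_a: int = 2000
    n_genes_d: int = 2000
    homeolog_fraction: float = 0.5
    divergence: int = 1  # substitutions in the 17-nt tag suffix per pair
    n_timepoints: int = 6
    library_size: int = 100_000
    error_rate: float = 0.0
    seed: int = 0
    cds_length: int = 120
    tagless_fraction: float = 0.0
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {"down": 0.35, "up": 0.30, "peak": 0.10, "flat": 0.25}
    )
    de_fold: float = 8.0
    abundance_sigma: float = 1.0  # lognormal spread of per-gene base level
    dirichlet_noise: float = 0.0  # optional overdispersion; 0 = plain multinomial

    def __post_init__(self) -> None:
        if min(self.n_genes_a, self.n_genes_d) < 0 or self.library_size < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must lie in [0, 0.25]")
        if not 0.0 <= self.homeolog_fraction <= 1.0:
            raise ValueError("homeolog_fraction must lie in [0, 1]")
        if self.divergence < 0 or self.divergence > SUFFIX_LENGTH:
            raise ValueError(
                f"divergence must lie in [0, {SUFFIX_LENGTH}] (tag suffix length)"
            )
        if self.cds_length < TAG_LENGTH:
            raise ValueError(f"cds_length must be >= {TAG_LENGTH}")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pattern mixture proportions must sum to 1")
        if any(p not in PATTERNS for p in self.pattern_mix):
            raise ValueError(f"patterns must be among {PATTERNS}")
        if self.de_fold <= 1.0:
            raise ValueError("de_fold must exceed 1")

    def timepoint_labels(self) -> list[str]:
        """Default labels mirror a 15..65 day design when six points."""
        return [f"{15 + 10 * t}d" for t in range(self.n_timepoints)]


@dataclass
class SyntheticGenomePair:
    """Two genomes' CDS sets plus the homeolog pairing with divergences."""

    genes_a: list[tuple[str, str]]
    genes_d: list[tuple[str, str]]
    homeolog_map: list[tuple[str, str, int]]
    tagless: set[str] = field(default_factory=set)
    seed: int = 0

    def all_genes(self) -> list[tuple[str, str, str]]:
        """(gene_id, cds, genome) over both genomes."""
        return [(g, s, "A") for g, s in self.genes_a] + [
            (g, s, "D") for g, s in self.genes_d
        ]

    def canonical_tag(self, gene_id: str) -> str | None:
        seq = dict(self.genes_a + self.genes_d)[gene_id]
        tags = taglib.extract_tags(seq, gene_id, "?")
        return tags[0].sequence if tags else None


@dataclass
class TrajectoryTruth:
    gene_id: str
    pattern: str
    abundances: np.ndarray
    is_de_truth: bool


def _random_cds(rng: np.random.Generator, length: int, tagless: bool) -> str:
    seq = rng.choice(_BASES, size=length)
    if tagless:
        # scrub every anchor occurrence so no tag is extractable
        s = "".join(seq)
        while ANCHOR in s:
            pos = s.find(ANCHOR)
            s = s[:pos] + "A" + s[pos + 1 :]
        return s
    # guaranteed 3'-most tag: anchor exactly 17 nt from the 3' end
    seq[length - TAG_LENGTH : length - SUFFIX_LENGTH] = list(ANCHOR)
    return "".join(seq)


def _diverge_tag_region(
    rng: np.random.Generator, cds: str, k: int
) -> tuple[str, int]:
    """Substitute k distinct bases inside the 17-nt suffix of the 3' tag."""
    chars = list(cds)
    positions = rng.choice(SUFFIX_LENGTH, size=k, replace=False)
    for p in positions:
        idx = len(chars) - SUFFIX_LENGTH + int(p)
        old = chars[idx]
        choices = [b for b in "ACGT" if b != old]
        chars[idx] = choices[int(rng.integers(3))]
    return "".join(chars), k


def simulate_genomes(config: SimulationConfig) -> SyntheticGenomePair:
    """Generate the A/D genome pair with controlled homeolog divergence.

    D homeologs are copies of their A partner whose 3'-most tag suffix
    carries exactly ``config.divergence`` substitutions; divergence outside
    the tag region is not modelled because the pipeline never reads it.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_tagless_a = int(round(config.tagless_fraction * config.n_genes_a))
    genes_a = []
    for i in range(config.n_genes_a):
        gid = f"GA{i:05d}"
        tagless = i < n_tagless_a
        genes_a.append((gid, _random_cds(rng, config.cds_length, tagless)))

    n_pairs = int(round(config.homeolog_fraction * min(config.n_genes_a, config.n_genes_d)))
    # homeologs derive from taggable A genes only
    taggable_a = [(g, s) for g, s in genes_a if ANCHOR in s][:n_pairs]
    genes_d: list[tuple[str, str]] = []
    homeolog_map: list[tuple[str, str, int]] = []
    for j, (ga, seq_a) in enumerate(taggable_a):
        gid = f"GD{j:05d}"
        seq_d, k = _diverge_tag_region(rng, seq_a, config.divergence)
        genes_d.append((gid, seq_d))
        homeolog_map.append((ga, gid, k))
    for j in range(len(genes_d), config.n_genes_d):
        gid = f"GD{j:05d}"
        genes_d.append((gid, _random_cds(rng, config.cds_length, False)))

    tagless = {
        g
        for g, s in genes_a + genes_d
        if not taglib.extract_tags(s, g, "?")
    }
    return SyntheticGenomePair(
        genes_a=genes_a,
        genes_d=genes_d,
        homeolog_map=homeolog_map,
        tagless=tagless,
        seed=config.seed,
    )


def _pattern_vector(
    pattern: str, base: float, fold: float, n: int
) -> np.ndarray:
    t = np.arange(n, dtype=float)
    if pattern == "flat":
        return np.full(n, base)
    if pattern == "down":
        return base * fold ** (-t / (n - 1))
    if pattern == "up":
        return base * fold ** (t / (n - 1)) / fold
    if pattern == "peak":
        mid = (n - 1) / 2.0
        return base * fold ** (-np.abs(t - mid) / mid)
    raise ValueError(f"unknown pattern {pattern!r}")


def simulate_trajectories(
    genes: Sequence[str], config: SimulationConfig
) -> list[TrajectoryTruth]:
    """Assign each gene a pattern and a strictly positive abundance vector.

    ``is_de_truth`` is set iff max/min abundance ratio >= 4 (the four-fold
    cut-off used downstream).
    """
    rng = np.random.default_rng([config.seed, 1])
    patterns = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[p] for p in patterns])
    out = []
    for gene in genes:
        pattern = patterns[int(rng.choice(len(patterns), p=probs))]
        base = float(np.exp(rng.normal(0.0, config.abundance_sigma)))
        vec = _pattern_vector(pattern, base, config.de_fold, config.n_timepoints)
        ratio = float(vec.max() / vec.min())
        out.append(
            TrajectoryTruth(
                gene_id=gene,
                pattern=pattern,
                abundances=vec,
                is_de_truth=ratio >= DE_TRUTH_RATIO,
            )
        )
    return out


@dataclass
class SimulatedLibrary:
    """One sampled tag library plus per-tag gene-of-origin truth."""

    tag_counts: TagCountSet
    origins: dict[str, dict[str, int]]
    true_gene_counts: dict[str, int]


def _mutate(rng: np.random.Generator, tag: str, n_errors: int) -> str:
    chars = list(tag)
    positions = rng.choice(TAG_LENGTH, size=n_errors, replace=False)
    for p in positions:
        old = chars[int(p)]
        choices = [b for b in "ACGT" if b != old]
        chars[int(p)] = choices[int(rng.integers(3))]
    return "".join(chars)


def simulate_tag_library(
    genomes: SyntheticGenomePair,
    truth: Sequence[TrajectoryTruth],
    timepoint: int,
    config: SimulationConfig,
) -> SimulatedLibrary:
    """Sample one library multinomially from canonical tags.

    Copy numbers are drawn from a multinomial over the taggable genes'
    abundances at ``timepoint``; each sampled copy is then independently
    mutated per base at ``config.error_rate``.  The returned truth maps
    every distinct observed tag to its generating genes.
    """
    if not 0 <= timepoint < config.n_timepoints:
        raise ValueError(f"timepoint {timepoint} out of range")
    rng = np.random.default_rng([config.seed, 2, timepoint])

    tag_of: dict[str, str] = {}
    for gene, seq, _genome in genomes.all_genes():
        tags = taglib.extract_tags(seq, gene, _genome)
        if tags:
            tag_of[gene] = tags[0].sequence
    truth_by_gene = {t.gene_id: t for t in truth}
    genes = [g for g in tag_of if g in truth_by_gene]
    if not genes:
        raise ValueError("all genes are tagless; nothing to sample")

    weights = np.array([truth_by_gene[g].abundances[timepoint] for g in genes])
    probs = weights / weights.sum()
    if config.dirichlet_noise > 0:
        probs = rng.dirichlet(probs / config.dirichlet_noise)
    gene_counts = rng.multinomial(config.library_size, probs)

    counts: dict[str, int] = {}
    origins: dict[str, dict[str, int]] = {}

    def _record(tag: str, gene: str, n: int) -> None:
        counts[tag] = counts.get(tag, 0) + n
        origins.setdefault(tag, {})
        origins[tag][gene] = origins[tag].get(gene, 0) + n

    if config.error_rate == 0.0:
        for g, n in zip(genes, gene_counts):
            if n:
                _record(tag_of[g], g, int(n))
    else:
        for g, n in zip(genes, gene_counts):
            if not n:
                continue
            n_err_per_copy = rng.binomial(TAG_LENGTH, config.error_rate, size=int(n))
            clean = int(np.sum(n_err_per_copy == 0))
            if clean:
                _record(tag_of[g], g, clean)
            for k in n_err_per_copy[n_err_per_copy > 0]:
                _record(_mutate(rng, tag_of[g], int(k)), g, 1)

    label = config.timepoint_labels()[timepoint]
    return SimulatedLibrary(
        tag_counts=TagCountSet(library_id=label, counts=counts),
        origins=origins,
        true_gene_counts={g: int(n) for g, n in zip(genes, gene_counts) if n},
    )


def simulate_all_libraries(
    genomes: SyntheticGenomePair,
    truth: Sequence[TrajectoryTruth],
    config: SimulationConfig,
) -> list[SimulatedLibrary]:
    return [
        simulate_tag_library(genomes, truth, t, config)
        for t in range(config.n_timepoints)
    ]


# ---- qPCR emulation ----------------------------------------------------


def simulate_qpcr(
    tpm: pd.DataFrame,
    genes: Sequence[str],
    sigma: float,
    seed: int,
    reference_gene: str = "actin",
    reference_ct: float = 15.0,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Emulate Ct tables whose expression tracks the TPM profiles.

    Target Ct = 30 - log2(TPM + floor) + Gaussian noise (sd ``sigma``);
    the reference gene is constant across samples.  Three technical
    replicates per well.  Returns a tidy frame (gene, sample, replicate, ct).
    """
    rng = np.random.default_rng([seed, 3])
    rows = []
    for sample in tpm.columns:
        for rep in range(1, 4):
            rows.append(
                {"gene": reference_gene, "sample": sample, "replicate": rep,
                 "ct": reference_ct}
            )
        for gene in genes:
            ct = 30.0 - np.log2(tpm.loc[gene, sample] + floor)
            for rep in range(1, 4):
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "replicate": rep,
                        "ct": float(ct + rng.normal(0.0, sigma)),
                    }
                )
    return pd.DataFrame(rows)


# ---- serialization -----------------------------------------------------


def truth_frame(truth: Sequence[TrajectoryTruth], config: SimulationConfig) -> pd.DataFrame:
    labels = config.timepoint_labels()
    rows = []
    for t in truth:
        row = {"gene": t.gene_id, "pattern": t.pattern, "is_de_truth": t.is_de_truth}
        for lab, a in zip(labels, t.abundances):
            row[f"abundance_{lab}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def annotation_sets_from_truth(
    truth: Sequence[TrajectoryTruth], min_size: int = 1
) -> dict[str, tuple[str, list[str]]]:
    """Pattern-derived annotation sets (term -> (name, genes)) for the
    enrichment stage's synthetic input."""
    by_pattern: dict[str, list[str]] = {}
    for t in truth:
        by_pattern.setdefault(t.pattern, []).append(t.gene_id)
    return {
        f"set:{p}": (f"{p}-trajectory genes", genes)
        for p, genes in sorted(by_pattern.items())
        if len(genes) >= min_size
    }


def write_fasta(genes: list[tuple[str, str]], genome: str, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=gid, description=f"genome={genome}")
        for gid, seq in genes
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
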