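"""End-to-end orchestration: simulate -> build-lib -> map -> de -> cluster
-> enrich -> qpcr, driven by a single config with manifest-tracked outputs.

Every stage communicates with the next only through its declared files, so
stages can also be run individually from the CLI.  Outputs are
deterministic under a fixed seed; the manifest records checksums and
per-stage wall clock.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cluster, de, enrich, io, mapping, qpcr, synthetic, taglib

DEFAULT_THRESHOLDS = {
    "fdr": 0.001,
    "min_abs_log2": 2.0,
    "min_raw": 10,
    "k": 42,
    "alpha": 0.05,
}


class PreflightError(RuntimeError):
    """Raised before any computation when a requested input is missing."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    timepoints: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "build_lib": True,
            "map": True,
            "de": True,
            "cluster": True,
            "enrich": True,
            "qpcr": True,
        }
    )
    canonical_only: bool = False
    qpcr_sigma: float = 0.2
    qpcr_genes: int = 20
    paths: dict = field(default_factory=dict)  # external inputs when not simulating

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if not 0 < self.thresholds["fdr"] < 1:
            raise ValueError("fdr threshold must lie in (0, 1)")
        if self.thresholds["min_raw"] < 0 or self.thresholds["k"] < 1:
            raise ValueError("invalid thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): io.sha256_file(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def skip(self, stage: str) -> None:
        self.stages[stage] = {"skipped": True}

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {"version": self.version, "config": self.config, "stages": self.stages},
                handle,
                indent=2,
                default=str,
            )


def _simulation_config(config: RunConfig) -> synthetic.SimulationConfig:
    kwargs = dict(config.synthetic)
    kwargs.setdefault("seed", config.seed)
    return synthetic.SimulationConfig(**kwargs)


def run_all(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order; any failure aborts the run."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())
    cfg_dict = config.as_dict()
    sim = _simulation_config(config) if config.stages.get("simulate") else None
    if not config.timepoints:
        if sim is None:
            raise PreflightError("timepoints must be given when not simulating")
        config.timepoints = sim.timepoint_labels()

    # ---- simulate ------------------------------------------------------
    if config.stages.get("simulate", True):
        t0 = time.perf_counter()
        genomes = synthetic.simulate_genomes(sim)
        gene_ids = [g for g, _ in genomes.genes_a] + [g for g, _ in genomes.genes_d]
        truth = synthetic.simulate_trajectories(gene_ids, sim)
        fasta_a = out / "genome_A.fasta"
        fasta_d = out / "genome_D.fasta"
        synthetic.write_fasta(genomes.genes_a, "A", fasta_a)
        synthetic.write_fasta(genomes.genes_d, "D", fasta_d)
        truth_path = out / "truth.tsv"
        io.write_tsv(synthetic.truth_frame(truth, sim), truth_path, cfg_dict)
        tag_paths = []
        for t in range(sim.n_timepoints):
            lib = synthetic.simulate_tag_library(genomes, truth, t, sim)
            path = out / f"tags_{lib.tag_counts.library_id}.tsv"
            io.write_tsv(lib.tag_counts.to_frame(), path, cfg_dict)
            tag_paths.append(path)
        gmt_path = out / "annotations.gmt"
        sets = synthetic.annotation_sets_from_truth(truth)
        table = enrich.AnnotationTable(namespace="pattern")
        for term, (name, genes) in sets.items():
            table.add(term, name, genes)
        enrich.write_gmt(table, gmt_path)
        manifest.record(
            "simulate",
            [fasta_a, fasta_d, truth_path, gmt_path, *tag_paths],
            time.perf_counter() - t0,
        )
        config.paths.setdefault("genome_a", str(fasta_a))
        config.paths.setdefault("genome_d", str(fasta_d))
        config.paths.setdefault("annotations", str(gmt_path))
        config.paths.setdefault(
            "tags", {lab: str(out / f"tags_{lab}.tsv") for lab in config.timepoints}
        )
    else:
        manifest.skip("simulate")

    # ---- preflight for file-driven stages ------------------------------
    for key in ("genome_a", "genome_d"):
        if config.stages.get("build_lib", True) and key not in config.paths:
            raise PreflightError(f"missing input path {key!r}")

    # ---- build-lib -----------------------------------------------------
    lib_path = out / "library.tsv"
    if config.stages.get("build_lib", True):
        t0 = time.perf_counter()
        library = build_library(
            config.paths["genome_a"],
            config.paths["genome_d"],
            canonical_only=config.canonical_only,
        )
        io.write_tsv(library.to_frame(), lib_path, cfg_dict)
        prov_path = out / "library_provenance.tsv"
        io.write_tsv(
            pd.DataFrame([library.provenance]), prov_path, cfg_dict
        )
        manifest.record("build_lib", [lib_path, prov_path], time.perf_counter() - t0)
    else:
        manifest.skip("build_lib")
        library = None

    # ---- map -----------------------------------------------------------
    matrix_path = out / "expression_matrix.tsv"
    if config.stages.get("map", True):
        t0 = time.perf_counter()
        if library is None:
            library = taglib.ReferenceTagLibrary.from_frame(io.read_tsv(lib_path))
        results = []
        for label in config.timepoints:
            tag_path = config.paths["tags"][label]
            tcs = mapping.TagCountSet.from_frame(io.read_tsv(tag_path), label)
            results.append(mapping.count_library(tcs, library))
        matrix = mapping.build_matrix(results, config.timepoints)
        mapping.normalize_tpm(matrix)
        io.write_tsv(matrix_frame(matrix), matrix_path, cfg_dict)
        summary_path = out / "mapping_summary.tsv"
        io.write_tsv(mapping.mapping_summary_frame(results), summary_path, cfg_dict)
        manifest.record("map", [matrix_path, summary_path], time.perf_counter() - t0)
    else:
        manifest.skip("map")
        matrix = None

    # ---- de ------------------------------------------------------------
    degs_path = out / "degs.tsv"
    if config.stages.get("de", True):
        t0 = time.perf_counter()
        if matrix is None:
            matrix = read_matrix(matrix_path, config.timepoints)
        th = config.thresholds
        frames = de.all_pairwise(
            matrix,
            config.timepoints,
            fdr=th["fdr"],
            min_abs_log2=th["min_abs_log2"],
            min_raw=th["min_raw"],
        )
        outputs = []
        for frame in frames:
            lib_i, lib_j = frame.attrs["comparison"]
            path = out / f"de_{lib_i}_vs_{lib_j}.tsv"
            io.write_tsv(frame, path, cfg_dict, extra_header=frame.attrs["thresholds"])
            outputs.append(path)
        deg_set = de.union_degs(frames)
        io.write_tsv(deg_set.records, degs_path, cfg_dict)
        outputs.append(degs_path)
        manifest.record("de", outputs, time.perf_counter() - t0)
    else:
        manifest.skip("de")
        deg_set = None

    # ---- cluster -------------------------------------------------------
    if config.stages.get("cluster", True):
        t0 = time.perf_counter()
        if matrix is None:
            matrix = read_matrix(matrix_path, config.timepoints)
        if deg_set is None:
            records = io.read_tsv(degs_path)
            deg_set = de.DegSet(genes=set(records["gene"]), records=records)
        outputs = []
        if len(deg_set.genes) >= 2:
            k = min(config.thresholds["k"], len(deg_set.genes))
            profiles = cluster.build_profiles(matrix, deg_set)
            assignment = cluster.kmeans_cluster(profiles, k, seed=config.seed)
            cluster.classify_cluster_types(assignment)
            clusters_path = out / "clusters.tsv"
            frame = pd.DataFrame(
                {
                    "gene": assignment.labels.index,
                    "cluster": assignment.labels.to_numpy(),
                    "type": assignment.gene_types().to_numpy(),
                }
            )
            io.write_tsv(frame, clusters_path, cfg_dict)
            means_path = out / "cluster_means.tsv"
            io.write_tsv(
                assignment.means.reset_index(), means_path, cfg_dict
            )
            _, leaf_order = cluster.hierarchical_cluster(profiles)
            order_path = out / "leaf_order.txt"
            order_path.write_text("\n".join(leaf_order) + "\n")
            outputs = [clusters_path, means_path, order_path]
        manifest.record("cluster", outputs, time.perf_counter() - t0)
    else:
        manifest.skip("cluster")

    # ---- enrich --------------------------------------------------------
    if config.stages.get("enrich", True):
        t0 = time.perf_counter()
        if "annotations" not in config.paths:
            raise PreflightError("missing input path 'annotations'")
        if matrix is None:
            matrix = read_matrix(matrix_path, config.timepoints)
        if deg_set is None:
            records = io.read_tsv(degs_path)
            deg_set = de.DegSet(genes=set(records["gene"]), records=records)
        table = enrich.read_gmt(config.paths["annotations"])
        background = set(matrix.genes)
        study = deg_set.genes & background
        result = enrich.fisher_enrich(
            study, background, table, alpha=config.thresholds["alpha"]
        )
        enrich_path = out / "enrichment.tsv"
        io.write_tsv(result, enrich_path, cfg_dict)
        dirs_path = out / "directions.tsv"
        io.write_tsv(enrich.summarize_directions(deg_set, table), dirs_path, cfg_dict)
        manifest.record("enrich", [enrich_path, dirs_path], time.perf_counter() - t0)
    else:
        manifest.skip("enrich")

    # ---- qpcr ----------------------------------------------------------
    if config.stages.get("qpcr", True):
        t0 = time.perf_counter()
        if matrix is None:
            matrix = read_matrix(matrix_path, config.timepoints)
        if "qpcr" in config.paths:
            ct = qpcr.read_ct_table(config.paths["qpcr"])
        else:
            genes = sorted(matrix.genes)[: config.qpcr_genes]
            ct = synthetic.simulate_qpcr(
                matrix.tpm, genes, sigma=config.qpcr_sigma, seed=config.seed
            )
        rel = qpcr.ddct(ct, calibrator=config.timepoints[0])
        rel_path = out / "qpcr_relative.tsv"
        io.write_tsv(rel, rel_path, cfg_dict)
        per_gene, mean_r = qpcr.correlate_platforms(rel, matrix)
        corr = per_gene.rename_axis("gene").reset_index()
        corr_path = out / "qpcr_correlation.tsv"
        io.write_tsv(
            corr, corr_path, cfg_dict, extra_header={"mean_r": f"{mean_r:.6f}"}
        )
        manifest.record("qpcr", [rel_path, corr_path], time.perf_counter() - t0)
    else:
        manifest.skip("qpcr")

    manifest.write(out / "manifest.json")
    return manifest


def build_library(
    fasta_a, fasta_d, canonical_only: bool = False
) -> taglib.ReferenceTagLibrary:
    """Read two CDS FASTAs and build the merged reference tag library."""
    tags_a = []
    for gid, seq in synthetic.read_fasta(fasta_a):
        tags_a.extend(taglib.extract_tags(seq, gid, "A"))
    tags_d = []
    for gid, seq in synthetic.read_fasta(fasta_d):
        tags_d.extend(taglib.extract_tags(seq, gid, "D"))
    return taglib.merge_genomes(tags_a, tags_d, canonical_only=canonical_only)


def matrix_frame(matrix: mapping.ExpressionMatrix) -> pd.DataFrame:
    """Wide per-gene table: raw and TPM columns per library."""
    frame = pd.DataFrame(index=matrix.raw.index)
    for lib in matrix.libraries:
        frame[f"raw_{lib}"] = matrix.raw[lib]
        frame[f"tpm_{lib}"] = matrix.tpm[lib]
    frame.attrs["clean_totals"] = dict(matrix.clean_totals)
    return frame.reset_index()


def read_matrix(path, timepoints: list[str]) -> mapping.ExpressionMatrix:
    """Round-trip counterpart of :func:`matrix_frame`.

    Clean totals are recovered from raw/TPM pairs (TPM = raw * 1e6 / total),
    using the first gene with a nonzero raw count in each library.
    """
    frame = io.read_tsv(path).set_index("gene")
    raw = frame[[f"raw_{lib}" for lib in timepoints]].copy()
    raw.columns = timepoints
    totals = {}
    for lib in timepoints:
        nz = frame[frame[f"raw_{lib}"] > 0]
        if len(nz) == 0:
            raise ValueError(f"library {lib} has no mapped counts")
        row = nz.iloc[0]
        totals[lib] = int(round(row[f"raw_{lib}"] * mapping.TPM_SCALE / row[f"tpm_{lib}"]))
    matrix = mapping.ExpressionMatrix(
        raw=raw.astype(int), clean_totals=pd.Series(totals)
    )
    return mapping.normalize_tpm(matrix)
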