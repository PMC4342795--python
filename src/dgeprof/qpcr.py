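"""Comparative-Ct qPCR quantification and cross-platform correlation.

Relative expression is 2^-ddCt with ddCt = (Ct_target - Ct_reference) at a
sample minus the same difference at the calibrator sample; technical
replicate Cts are arithmetic-averaged before any differencing.  Gene-wise
Pearson correlation against tag-count TPM profiles summarizes agreement
between the two platforms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mapping import ExpressionMatrix

DEFAULT_CALIBRATOR = "15d"
DEFAULT_REFERENCE = "actin"


def read_ct_table(path) -> pd.DataFrame:
    """Tidy Ct TSV with columns gene, sample, replicate, ct."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "sample", "replicate", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return frame


def ddct(
    records: pd.DataFrame,
    calibrator: str = DEFAULT_CALIBRATOR,
    reference_gene: str = DEFAULT_REFERENCE,
) -> pd.DataFrame:
    """2^-ddCt relative expression per gene x sample.

    Requires the reference gene's Cts in every sample and the calibrator
    sample for every target gene; the calibrator row is exactly 1.0 by
    construction.
    """
    if (records["ct"] <= 0).any():
        raise ValueError("non-positive Ct value in records")
    mean_ct = records.groupby(["gene", "sample"])["ct"].mean()
    if reference_gene not in mean_ct.index.get_level_values("gene"):
        raise ValueError(f"reference gene {reference_gene!r} absent from records")
    ref_ct = mean_ct.loc[reference_gene]
    rows = []
    for gene in mean_ct.index.get_level_values("gene").unique():
        if gene == reference_gene:
            continue
        gene_ct = mean_ct.loc[gene]
        missing_ref = sorted(set(gene_ct.index) - set(ref_ct.index))
        if missing_ref:
            raise ValueError(
                f"reference gene missing for samples {missing_ref} (gene {gene})"
            )
        if calibrator not in gene_ct.index:
            raise ValueError(f"calibrator sample {calibrator!r} missing for {gene}")
        dct = gene_ct - ref_ct.loc[gene_ct.index]
        ddct_vals = dct - dct.loc[calibrator]
        for sample, v in ddct_vals.items():
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "ddct": float(v),
                    "rel_expr": float(2.0 ** (-v)),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "sample", "ddct", "rel_expr"])


def correlate_platforms(
    rel_expr: pd.DataFrame,
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    min_points: int = 3,
    log_scale: bool = False,
    exclude: set[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-gene Pearson r between qPCR and TPM profiles, plus the mean r.

    Genes with fewer than ``min_points`` shared samples or zero variance on
    either platform are reported as NaN (with a warning) and excluded from
    the mean.  ``exclude`` mirrors failed-amplification drop lists.
    """
    if matrix.tpm is None:
        raise ValueError("matrix has no TPM view; run normalize_tpm first")
    exclude = exclude or set()
    wide = rel_expr.pivot(index="gene", columns="sample", values="rel_expr")
    if genes is None:
        genes = [g for g in wide.index if g in matrix.tpm.index]
    out: dict[str, float] = {}
    for gene in genes:
        if gene in exclude:
            continue
        if gene not in wide.index or gene not in matrix.tpm.index:
            warnings.warn(f"gene {gene!r} missing on one platform; skipped")
            continue
        q = wide.loc[gene].dropna()
        shared = [s for s in q.index if s in matrix.tpm.columns]
        if len(shared) < min_points:
            warnings.warn(f"gene {gene!r} has <{min_points} shared samples; skipped")
            continue
        a = q.loc[shared].to_numpy(dtype=float)
        b = matrix.tpm.loc[gene, shared].to_numpy(dtype=float)
        if log_scale:
            a = np.log2(a)
            b = np.log2(b + 1.0)
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"gene {gene!r} has zero variance; r undefined")
            out[gene] = float("nan")
            continue
        out[gene] = float(np.corrcoef(a, b)[0, 1])
    series = pd.Series(out, name="pearson_r", dtype=float)
    valid = series.dropna()
    mean_r = float(valid.mean()) if len(valid) else float("nan")
    return series, mean_r
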