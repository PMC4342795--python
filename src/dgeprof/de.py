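"""Pairwise differential expression for two-library tag counts.

Implements the exact two-library count statistic for tag/SAGE data: given a
gene observed ``x`` times among ``N1`` clean tags in one library, the
probability of observing ``y`` among ``N2`` in the other is

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which for N1 = N2 reduces to C(x+y, x) / 2^(x+y+1).  Two-sided p-values
are doubled minimal tail sums, capped at 1.  Genes pass when FDR <= 0.001,
|log2 ratio| >= 2 (four-fold) and the larger raw count is >= 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mapping import TPM_SCALE, ExpressionMatrix

DEFAULT_FDR = 0.001
DEFAULT_MIN_ABS_LOG2 = 2.0
DEFAULT_MIN_RAW = 10


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def ac_log_probability(x: int, y, n1: float, n2: float):
    """log p(y | x); ``y`` may be a scalar or an integer array."""
    y = np.asarray(y)
    r = n2 / n1
    return (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )


def ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """Exact probability p(y | x) of the two-library count statistic."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(ac_log_probability(x, int(y), n1, n2)))


def _two_sided_raw(x: int, y: int, n1: float, n2: float) -> float:
    ys = np.arange(0, int(y) + 1)
    probs = np.exp(ac_log_probability(x, ys, n1, n2))
    lower = float(probs.sum())
    upper = max(0.0, 1.0 - float(probs[:-1].sum()))
    return min(1.0, 2.0 * min(lower, upper))


def ac_two_sided_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided p-value: 2 * min(lower tail, upper tail), capped at 1.

    The lower tail sums p(y'|x) over y' <= y; the upper tail is
    1 - sum over y' < y, clamped at 0 against roundoff.  Because the
    doubled-tail construction is not invariant to which library is
    conditioned on, the statistic is symmetrized by taking the smaller of
    the two conditionings, which makes swapping (x, N1) with (y, N2) exact.
    Values within 1e-12 of 1 are snapped to 1 (the cap is exact in exact
    arithmetic when x = y and N1 = N2).
    """
    _check_counts(x, y, n1, n2)
    p = min(_two_sided_raw(x, y, n1, n2), _two_sided_raw(y, x, n2, n1))
    if p > 1.0 - 1e-12:
        return 1.0
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def by_fdr(p_values) -> np.ndarray:
    """Benjamini–Yekutieli adjustment (BH scaled by the harmonic number)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    c = np.sum(1.0 / np.arange(1, p.size + 1))
    return np.minimum(bh_fdr(p) * c, 1.0)


_FDR_METHODS = {"bh": bh_fdr, "by": by_fdr}


def call_pairwise(
    matrix: ExpressionMatrix,
    lib_i: str,
    lib_j: str,
    fdr: float = DEFAULT_FDR,
    min_abs_log2: float = DEFAULT_MIN_ABS_LOG2,
    min_raw: int = DEFAULT_MIN_RAW,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Test every gene with signal in at least one of two libraries.

    Returns one row per tested gene with columns ``gene, x, y, tpm_i,
    tpm_j, log2_ratio, p_value, fdr, passes_fdr, passes_fold, passes_raw,
    is_de``.  log2_ratio is log2(TPM_j / TPM_i); a zero TPM is floored at
    the TPM equivalent of one raw tag in its library so ratios stay
    finite.  FDR is adjusted across the tested genes of this comparison
    only (zero/zero genes are excluded from the family).
    """
    if lib_i == lib_j:
        raise ValueError("pairwise comparison requires two distinct libraries")
    if matrix.tpm is None:
        raise ValueError("matrix has no TPM view; run normalize_tpm first")
    for lib in (lib_i, lib_j):
        if lib not in matrix.raw.columns:
            raise ValueError(f"library {lib!r} not in matrix")

    x = matrix.raw[lib_i]
    y = matrix.raw[lib_j]
    tested = (x + y) > 0
    genes = matrix.raw.index[tested]
    xv = x[tested].to_numpy()
    yv = y[tested].to_numpy()
    n1 = float(matrix.clean_totals[lib_i])
    n2 = float(matrix.clean_totals[lib_j])

    tpm_i = matrix.tpm.loc[genes, lib_i].to_numpy()
    tpm_j = matrix.tpm.loc[genes, lib_j].to_numpy()
    floor_i = TPM_SCALE / n1
    floor_j = TPM_SCALE / n2
    log2_ratio = np.log2(np.where(tpm_j > 0, tpm_j, floor_j)) - np.log2(
        np.where(tpm_i > 0, tpm_i, floor_i)
    )

    p_values = np.array(
        [ac_two_sided_p(int(a), int(b), n1, n2) for a, b in zip(xv, yv)]
    )
    adjusted = _FDR_METHODS[fdr_method](p_values)

    passes_fdr = adjusted <= fdr
    passes_fold = np.abs(log2_ratio) >= min_abs_log2
    passes_raw = np.maximum(xv, yv) >= min_raw
    frame = pd.DataFrame(
        {
            "gene": genes,
            "x": xv,
            "y": yv,
            "tpm_i": tpm_i,
            "tpm_j": tpm_j,
            "log2_ratio": log2_ratio,
            "p_value": p_values,
            "fdr": adjusted,
            "passes_fdr": passes_fdr,
            "passes_fold": passes_fold,
            "passes_raw": passes_raw,
            "is_de": passes_fdr & passes_fold & passes_raw,
        }
    )
    frame.attrs["comparison"] = (lib_i, lib_j)
    frame.attrs["thresholds"] = {
        "fdr": fdr,
        "min_abs_log2": min_abs_log2,
        "min_raw": min_raw,
        "fdr_method": fdr_method,
    }
    return frame


def all_pairwise(
    matrix: ExpressionMatrix,
    libraries: list[str] | None = None,
    **thresholds,
) -> list[pd.DataFrame]:
    """Run call_pairwise over every unordered library pair, in order."""
    libs = libraries or matrix.libraries
    frames = []
    for a in range(len(libs)):
        for b in range(a + 1, len(libs)):
            frames.append(call_pairwise(matrix, libs[a], libs[b], **thresholds))
    return frames


@dataclass
class DegSet:
    """Genes differentially expressed in at least one pairwise comparison."""

    genes: set[str]
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def directions(self) -> dict[str, str]:
        """Per-gene direction: up / down if all fired comparisons agree,
        otherwise complex."""
        out: dict[str, str] = {}
        for gene, group in self.records.groupby("gene"):
            signs = set(np.sign(group["log2_ratio"]))
            if signs == {1.0}:
                out[gene] = "up"
            elif signs == {-1.0}:
                out[gene] = "down"
            else:
                out[gene] = "complex"
        return out


def union_degs(all_pairwise_frames: list[pd.DataFrame]) -> DegSet:
    """Union of per-comparison DE calls with per-gene direction records."""
    rows = []
    for frame in all_pairwise_frames:
        lib_i, lib_j = frame.attrs.get("comparison", ("i", "j"))
        hits = frame[frame["is_de"]]
        for row in hits.itertuples(index=False):
            rows.append(
                {
                    "gene": row.gene,
                    "comparison": f"{lib_i}:{lib_j}",
                    "log2_ratio": row.log2_ratio,
                    "direction": "up" if row.log2_ratio > 0 else "down",
                }
            )
    records = pd.DataFrame(rows, columns=["gene", "comparison", "log2_ratio", "direction"])
    return DegSet(genes=set(records["gene"]), records=records)
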