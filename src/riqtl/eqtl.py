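"""Transcript-level genome scans and probe filters feeding candidate triage.

Each probe's log2 expression is treated as a microtrait and scanned like the
phenotype.  A gene is cis-modulated when its peak marker lies on the gene's
own chromosome within a window of the gene position (default half-width
5 Mb, i.e. a 10 Mb window centered on the gene; configurable because the
wording is ambiguous between total and half width) and the peak LRS clears a
threshold (default: the probe's own suggestive permutation threshold).

Probe eligibility requires a SNP-free hybridization target, supplied as a
boolean annotation flag; detection requires strain-mean log2 expression at
or above 6.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError
from .io_formats import ExpressionDataset, GenotypeMatrix
from .mapping import _ols_lrs, scan_grid


@dataclass
class EqtlResult:
    probe_id: str
    gene_id: str | None
    peak_chromosome: str
    peak_Mb: float
    peak_lrs: float
    is_cis: bool = False
    detected: bool = False


def detection_filter(expr: ExpressionDataset, threshold: float = 6.8,
                     summary: str = "mean") -> np.ndarray:
    """Per-probe detected flag: strain summary (mean or max) >= threshold."""
    stat = expr.values.max(axis=1) if summary == "max" else expr.values.mean(axis=1)
    return stat >= threshold


def probe_snp_filter(expr: ExpressionDataset) -> np.ndarray:
    """Eligible probes hybridize to SNP-free targets (flag is False)."""
    flags = expr.probes["snp_overlap"]
    missing = flags.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} probes lack a SNP-overlap flag; excluded",
                      stacklevel=2)
    eligible = np.zeros(len(flags), bool)
    ok = (~missing).to_numpy()
    eligible[ok] = ~flags[~missing].astype(bool).to_numpy()
    return eligible


def eqtl_scan(expr: ExpressionDataset, g: GenotypeMatrix,
              probe_ids: list[str] | None = None,
              step_cM: float | None = None,
              detection_threshold: float = 6.8) -> list[EqtlResult]:
    """Batch genome scans (HK at typed markers by default) for many probes."""
    shared = [s for s in g.strains if s in expr.strains]
    if len(shared) < 10:
        raise DataError(f"only {len(shared)} strains shared with the expression data")
    gs = g.subset_strains(shared)
    positions, D = scan_grid(gs, step_cM)
    col = [expr.strains.index(s) for s in shared]
    probes = expr.probes
    if probe_ids is not None:
        sel = probes.index[probes["probe_id"].isin(probe_ids)].to_numpy()
    else:
        sel = probes.index.to_numpy()
    detected = detection_filter(expr, detection_threshold)
    results = []
    for i in sel:
        y = expr.values[i, col]
        if np.ptp(y) == 0:
            results.append(EqtlResult(probe_id=probes["probe_id"].iloc[i],
                                      gene_id=probes["gene_id"].iloc[i],
                                      peak_chromosome="", peak_Mb=np.nan,
                                      peak_lrs=0.0, detected=bool(detected[i])))
            continue
        lrs, _ = _ols_lrs(D, y)
        j = int(np.argmax(lrs))
        results.append(EqtlResult(
            probe_id=probes["probe_id"].iloc[i], gene_id=probes["gene_id"].iloc[i],
            peak_chromosome=str(positions["chromosome"].iloc[j]),
            peak_Mb=float(positions["Mb"].iloc[j]), peak_lrs=float(lrs[j]),
            detected=bool(detected[i])))
    return results


def eqtl_peak(expr: ExpressionDataset, probe_id: str, g: GenotypeMatrix,
              step_cM: float | None = None) -> EqtlResult:
    """Genome scan of one probe's strain values."""
    res = eqtl_scan(expr, g, probe_ids=[probe_id], step_cM=step_cM)
    if not res:
        raise DataError(f"probe {probe_id!r} not in the dataset")
    return res[0]


def suggestive_thresholds(expr: ExpressionDataset, g: GenotypeMatrix,
                          probe_ids: list[str], n_perm: int = 200,
                          seed: int = 0, step_cM: float | None = None
                          ) -> pd.Series:
    """Per-probe suggestive (genome-wide p = 0.63) max-LRS thresholds.

    All probes share the same strain permutations (the null is exchangeable
    over strains), which lets one matrix product serve every probe.
    """
    shared = [s for s in g.strains if s in expr.strains]
    gs = g.subset_strains(shared)
    _, D = scan_grid(gs, step_cM)
    col = [expr.strains.index(s) for s in shared]
    probes = expr.probes
    sel = probes.index[probes["probe_id"].isin(probe_ids)].to_numpy()
    Y = expr.values[np.ix_(sel, col)]                       # probes x strains
    n = len(shared)
    Dc = D - D.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Dc, Dc)
    keep = sxx > 1e-12
    Dc, sxx = Dc[keep], sxx[keep]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    syy = np.where(syy > 0, syy, np.inf)
    rng = np.random.default_rng(seed)
    maxes = np.empty((n_perm, len(sel)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        num = Dc @ Yc[:, perm].T                            # positions x probes
        r2 = np.clip(num ** 2 / (sxx[:, None] * syy[None, :]), 0.0, 1.0 - 1e-15)
        maxes[b] = (-n * np.log1p(-r2)).max(axis=0)
    thr = np.quantile(maxes, 1.0 - 0.63, axis=0)
    return pd.Series(thr, index=probes["probe_id"].iloc[sel].to_numpy())


def classify_cis(res: EqtlResult, gene_chromosome: str, gene_Mb: float,
                 window_Mb: float = 5.0, min_lrs: float = 0.0) -> bool:
    """Cis call: same chromosome, |peak - gene| <= window (inclusive),
    peak LRS at or above the threshold."""
    if gene_Mb is None or (isinstance(gene_Mb, float) and np.isnan(gene_Mb)):
        raise DataError(f"gene position unknown for probe {res.probe_id!r}")
    return (res.peak_chromosome == str(gene_chromosome)
            and abs(res.peak_Mb - float(gene_Mb)) <= window_Mb
            and res.peak_lrs >= min_lrs)
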