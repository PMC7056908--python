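"""Seven-criterion positional-candidate triage and cross-trait comparison.

The cascade over genes in the mapped interval:

  c1  positional: gene start inside the closed interval;
  c2  cis-modulated (retina and/or eye);
  c3  among the top-N trait correlates (any SNP-free probe, either tissue);
  c4  detected: expression at or above the detection threshold;
  c5  has at least one SNP-free probe set;
  c6  harbors a protein-altering variant (nonsynonymous SNP, indel or
      transcript variant);
  c7  its correlate network is enriched for a plausible cellular component
      (keyword-matched terminal GO term) -- an explicit operationalization
      of a qualitative judgment, configurable and disableable.

Tier 1 = all seven criteria; tier 2 = exactly one failure (the Wdr25
pattern); a relaxed pass waives the cis requirement.  Criteria that involve
probes (c3, c4, c5) are satisfied if ANY SNP-free probe of the gene
satisfies them; correlate ranking is by |r| (sign-blind), ties broken by
probe id.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError
from .io_formats import AnnotationTables, ExpressionDataset

ACCEPTED_VARIANT_CLASSES = frozenset(
    {"nonsynonymous_snp", "indel", "transcript_variant"})

CRITERIA = ["c1_positional", "c2_cis", "c3_correlated", "c4_detected",
            "c5_probe_clean", "c6_variant", "c7_network"]


@dataclass
class TriageConfig:
    interval: tuple[str, float, float]
    top_n_correlates: int = 1000
    detection_threshold: float = 6.8
    cis_window_Mb: float = 5.0
    variant_classes: frozenset = ACCEPTED_VARIANT_CLASSES
    network_keywords: tuple[str, ...] = ("mitochondri*", "axon*", "cytoskelet*")
    comparison_top_n: int = 2000

    def __post_init__(self) -> None:
        _, lo, hi = self.interval
        if not lo < hi:
            raise DataError("interval must have Mb_lo < Mb_hi")
        if self.top_n_correlates <= 0 or self.comparison_top_n <= 0:
            raise DataError("top-N counts must be positive")


def genes_in_interval(annotations: AnnotationTables,
                      interval: tuple[str, float, float]) -> pd.DataFrame:
    """Genes whose start lies within the closed [lo, hi] Mb interval."""
    if annotations.genes.empty:
        raise DataError("empty gene annotation")
    chrom, lo, hi = interval
    g = annotations.genes
    sel = (g["chromosome"] == str(chrom)) & (g["position_Mb"] >= lo) & (g["position_Mb"] <= hi)
    return g[sel].reset_index(drop=True)


def trait_correlates(trait: pd.DataFrame, expr: ExpressionDataset,
                     n_top: int) -> pd.DataFrame:
    """Probes ranked by |Pearson r| with the trait over shared strains.

    Returns probe_id, gene_id, r, rank, in_top; zero-variance probes are
    excluded (count reported via a warning).
    """
    shared = [s for s in expr.strains if s in trait.index]
    if len(shared) < 4:
        raise DataError("need >= 4 shared strains for correlate ranking")
    col = [expr.strains.index(s) for s in shared]
    y = trait.loc[shared, "value"].to_numpy(float)
    X = expr.values[:, col]
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / np.sqrt(sxx * syy)
    ok = sxx > 0
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} zero-variance probes excluded from ranking",
                      stacklevel=2)
    df = pd.DataFrame({"probe_id": expr.probes["probe_id"],
                       "gene_id": expr.probes["gene_id"], "r": r})[ok]
    df = df.sort_values(["r", "probe_id"], key=lambda c: -c.abs() if c.name == "r" else c,
                        kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["in_top"] = df["rank"] <= n_top
    return df


def gene_variants(gene_id: str, variants: pd.DataFrame,
                  accepted: frozenset = ACCEPTED_VARIANT_CLASSES
                  ) -> tuple[bool, list[str]]:
    """c6 flag plus the list of accepted variant classes found."""
    classes = variants.loc[variants["gene_id"] == gene_id, "class"].tolist()
    hit = sorted(set(classes) & accepted)
    return bool(hit), hit


def triage(cfg: TriageConfig, interval_genes: pd.DataFrame,
           eqtl_results: dict[str, list], correlate_ranks: dict[str, pd.DataFrame],
           annotations: AnnotationTables,
           network_flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Assemble the per-gene criterion matrix and assign tiers.

    ``eqtl_results`` and ``correlate_ranks`` are keyed by tissue; a gene
    missing from any input table fails that criterion with a provenance note
    rather than silently.
    """
    network_flags = network_flags or {}
    probe_ann = annotations.probes
    clean_probes = probe_ann[~probe_ann["snp_overlap"].astype(bool)]
    eqtl_by_tissue = {
        t: pd.DataFrame([vars(r) for r in res]) if res else pd.DataFrame()
        for t, res in eqtl_results.items()
    }
    rows = []
    for gene in interval_genes.itertuples(index=False):
        gid = gene.gene_id
        notes = []
        my_clean = set(clean_probes.loc[clean_probes["gene_id"] == gid, "probe_id"])
        c5 = bool(my_clean)
        if not my_clean and probe_ann[probe_ann["gene_id"] == gid].empty:
            notes.append("no probes annotated")
        c2 = c3 = c4 = False
        for tissue, eq in eqtl_by_tissue.items():
            if len(eq):
                mine = eq[eq["probe_id"].isin(my_clean)]
                for rec in mine.itertuples(index=False):
                    if rec.is_cis:
                        c2 = True
                    if rec.detected:
                        c4 = True
            else:
                notes.append(f"no eQTL results ({tissue})")
            ranks = correlate_ranks.get(tissue)
            if ranks is not None and len(ranks):
                if ranks.loc[ranks["probe_id"].isin(my_clean), "in_top"].any():
                    c3 = True
            else:
                notes.append(f"no correlate ranks ({tissue})")
        c6, classes = gene_variants(gid, annotations.variants, cfg.variant_classes)
        c7 = bool(network_flags.get(gid, False))
        if gid not in network_flags:
            notes.append("no network result")
        flags = {"c1_positional": True, "c2_cis": c2, "c3_correlated": c3,
                 "c4_detected": c4, "c5_probe_clean": c5, "c6_variant": c6,
                 "c7_network": c7}
        n_false = sum(not v for v in flags.values())
        tier = "1" if n_false == 0 else ("2" if n_false == 1 else "excluded")
        relaxed = all(v for k, v in flags.items() if k != "c2_cis")
        rows.append({"gene_id": gid, "symbol": gene.symbol, **flags,
                     "n_criteria_met": 7 - n_false, "tier": tier,
                     "relaxed_pass": relaxed,
                     "variant_classes": ",".join(classes),
                     "provenance": ";".join(sorted(set(notes)))})
    return pd.DataFrame(rows)


def match_network_keywords(term_names: list[str],
                           keywords: tuple[str, ...]) -> bool:
    """True when any term name matches any shell-style keyword pattern."""
    lowered = [t.lower() for t in term_names]
    return any(fnmatch.fnmatch(name, pat.lower())
               for name in lowered for pat in keywords)


# ---------------------------------------------------------------------------
# cross-trait comparison
# ---------------------------------------------------------------------------

def trait_correlation(trait_a: pd.DataFrame, trait_b: pd.DataFrame
                      ) -> tuple[float, float, int]:
    """Pearson r between two strain-mean traits with the two-sided t p-value."""
    shared = trait_a.index.intersection(trait_b.index)
    if len(shared) < 4:
        raise DataError("need >= 4 shared strains")
    a = trait_a.loc[shared, "value"].to_numpy(float)
    b = trait_b.loc[shared, "value"].to_numpy(float)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(len(shared))


def shared_correlates(trait_a: pd.DataFrame, trait_b: pd.DataFrame,
                      expr_a: ExpressionDataset, expr_b: ExpressionDataset,
                      annotations: AnnotationTables, n_top: int = 2000,
                      detect: float = 6.8) -> dict:
    """Overlap between the detection-filtered top-N correlate gene lists.

    Each trait's top-N probes are detection-filtered, mapped to unique gene
    symbols (case-insensitive), and intersected.
    """
    from .eqtl import detection_filter

    symbols = annotations.genes.set_index("gene_id")["symbol"]

    def gene_list(trait, expr):
        ranks = trait_correlates(trait, expr, n_top)
        det = pd.Series(detection_filter(expr, detect),
                        index=expr.probes["probe_id"].to_numpy())
        top = ranks[ranks["in_top"]]
        top = top[det.reindex(top["probe_id"]).fillna(False).to_numpy(bool)]
        syms = top["gene_id"].map(symbols).dropna().str.lower()
        return set(syms)

    genes_a = gene_list(trait_a, expr_a)
    genes_b = gene_list(trait_b, expr_b)
    shared = genes_a & genes_b
    return {"count_a_detected": len(genes_a), "count_b_detected": len(genes_b),
            "shared_genes": sorted(shared), "shared_count": len(shared)}
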