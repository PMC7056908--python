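"""GO cellular-component over-representation of correlate networks.

For a candidate gene, the network is the detection-filtered top-N correlates
of its own probe.  Over-representation per term is the upper-tail
hypergeometric probability P(X >= observed) with population = background
(all detection-passing genes on the platform), successes = term size within
the background, draws = correlate-set size; Benjamini-Hochberg FDR across
tested terms.  The plotted selection keeps significant terms that are
"terminal branches": no significant descendant in the annotation DAG.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._errors import DataError
from .io_formats import AnnotationTables, ExpressionDataset


def gene_correlate_set(expr: ExpressionDataset, gene_id: str,
                       annotations: AnnotationTables, n_top: int = 1000,
                       detect: float = 6.8) -> set[str]:
    """Unique gene ids among the detection-filtered top correlates of
    ``gene_id``'s probe (seed gene excluded from its own set)."""
    from .candidates import trait_correlates
    from .eqtl import detection_filter

    probes = expr.probes
    mine = probes.index[probes["gene_id"] == gene_id]
    if len(mine) == 0:
        raise DataError(f"gene {gene_id!r} has no probe in the dataset")
    # seed with the gene's best-expressed SNP-free probe when one exists
    clean = [i for i in mine if not bool(probes["snp_overlap"].iloc[i])]
    pool = clean if clean else list(mine)
    seed_idx = max(pool, key=lambda i: expr.values[i].mean())
    if expr.values[seed_idx].mean() < detect:
        warnings.warn(f"seed gene {gene_id} below detection; empty correlate set",
                      stacklevel=2)
        return set()
    seed_trait = pd.DataFrame({"value": expr.values[seed_idx]},
                              index=pd.Index(expr.strains, name="strain"))
    ranks = trait_correlates(seed_trait, expr, n_top)
    det = pd.Series(detection_filter(expr, detect),
                    index=probes["probe_id"].to_numpy())
    top = ranks[ranks["in_top"]]
    top = top[det.reindex(top["probe_id"]).fillna(False).to_numpy(bool)]
    genes = set(top["gene_id"].dropna()) - {gene_id}
    return genes


def go_ora(gene_set: set[str], annotations: AnnotationTables,
           background: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` per GO term.

    Columns: term_id, name, observed, expected, ratio, p, fdr.  Only terms
    with at least one background gene are tested; expected = draws *
    term_size / background_size.
    """
    if not gene_set:
        return pd.DataFrame(columns=["term_id", "name", "observed", "expected",
                                     "ratio", "p", "fdr"])
    if not gene_set <= background:
        raise DataError("gene set must be a subset of the background")
    M = len(background)
    N = len(gene_set)
    rows = []
    for term in annotations.go_terms.itertuples(index=False):
        term_genes = set(term.genes) & background
        K = len(term_genes)
        if K == 0:
            continue
        obs = len(gene_set & term_genes)
        expected = N * K / M
        p = float(hypergeom.sf(obs - 1, M, K, N))
        rows.append({"term_id": term.term_id, "name": term.name, "observed": obs,
                     "expected": expected,
                     "ratio": obs / expected if expected > 0 else np.nan,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def terminal_significant(results: pd.DataFrame, annotations: AnnotationTables,
                         alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Significant terms (fdr < alpha) with no significant descendant."""
    go = annotations.go_terms
    children: dict[str, list[str]] = {}
    for term in go.itertuples(index=False):
        for p in term.parents:
            children.setdefault(p, []).append(term.term_id)

    def descendants(t: str) -> set[str]:
        out: set[str] = set()
        stack = list(children.get(t, []))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(children.get(c, []))
        return out

    if results.empty:
        return results.assign(terminal=pd.Series(dtype=bool))
    sig = set(results.loc[results["fdr"] < alpha_fdr, "term_id"])
    keep = [t for t in sig if not (descendants(t) & sig)]
    out = results[results["term_id"].isin(keep)].copy()
    out["terminal"] = True
    return out.sort_values("fdr").reset_index(drop=True)


def network_flag(expr_by_tissue: dict[str, ExpressionDataset], gene_id: str,
                 annotations: AnnotationTables, keywords: tuple[str, ...],
                 n_top: int = 1000, detect: float = 6.8,
                 alpha_fdr: float = 0.05) -> bool:
    """Network-plausibility criterion: in any tissue, a keyword-matching GO
    term is terminal-significant in the gene's correlate network."""
    from .candidates import match_network_keywords
    from .eqtl import detection_filter

    for expr in expr_by_tissue.values():
        det = detection_filter(expr, detect)
        background = set(expr.probes.loc[det, "gene_id"].dropna())
        try:
            corr = gene_correlate_set(expr, gene_id, annotations, n_top, detect)
        except DataError:
            continue
        corr &= background
        if not corr:
            continue
        ora = go_ora(corr, annotations, background)
        term = terminal_significant(ora, annotations, alpha_fdr)
        if len(term) and match_network_keywords(list(term["name"]), keywords):
            return True
    return False
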