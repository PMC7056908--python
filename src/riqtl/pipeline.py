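"""One-command orchestration of the full analysis.

Stage order mirrors the study's cascade: aggregate animal counts ->
outlier handling / winsorization -> heritability -> Haley-Knott scan ->
permutation thresholds -> support interval -> mixed-model scan ->
robustness scenarios -> eQTL + correlate ranking -> seven-criterion triage
-> correlate-network enrichment -> cross-trait comparison.  Every stage
writes a TSV under the output directory and is logged in a run manifest
(config snapshot, seeds, file digests, row counts, durations), so reruns
with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError
from . import io_formats as iof
from . import mapping, phenotypes, eqtl as eqtl_mod, candidates as cand, enrichment
from .simulate import (ChromosomeSpec, ExpressionSpec, OutlierSpec, SimConfig,
                       make_fixture, write_fixture)


def _sim_config(block: dict, seed: int | None) -> SimConfig:
    kwargs = dict(block)
    if "chromosomes" in kwargs:
        kwargs["chromosomes"] = [ChromosomeSpec(**c) for c in kwargs["chromosomes"]]
    if "expression" in kwargs:
        kwargs["expression"] = ExpressionSpec(**kwargs["expression"])
    if "outliers" in kwargs:
        kwargs["outliers"] = OutlierSpec(**kwargs["outliers"])
    if "qtl" in kwargs:
        kwargs["qtl"] = [tuple(q) for q in kwargs["qtl"]]
    if "interval" in kwargs:
        kwargs["interval"] = tuple(kwargs["interval"])
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute the full analysis; returns the output directory.

    ``config`` is a dict or a YAML path with a ``simulate:`` block (synthetic
    mode) or an ``inputs:`` block of file paths (real exports).
    """
    if not isinstance(config, dict):
        with open(config, "rt", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config, default=str)),
                      "seed": seed, "version": __version__, "stages": {}}
    t_all = time.perf_counter()

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    map_cfg = config.get("mapping", {})
    step_cM = map_cfg.get("step_cM", 1.0)
    n_perm = map_cfg.get("n_perm", 1000)
    map_seed = (seed if seed is not None else config.get("seed", 0)) or 0

    # ------------------------------------------------------------------ inputs
    if "simulate" in config:
        sim = _sim_config(config["simulate"], seed)
        fx = stage("simulate", lambda: make_fixture(sim))
        write_fixture(fx, out / "fixture")
        g, animals = fx.genotypes, fx.animals
        expr = fx.expression
        ann = fx.annotations
        second_trait = fx.second_trait
        truth = fx.truth
    else:
        inputs = config.get("inputs")
        if not inputs:
            raise ConfigError("config needs a 'simulate' or 'inputs' block")
        for key in ("geno", "trait"):
            if key not in inputs:
                raise ConfigError(f"inputs missing required key '{key}'")
        g = iof.read_geno(inputs["geno"])
        animals = None
        trait_in = iof.read_trait_table(inputs["trait"])
        ann = iof.read_annotations(inputs["genes"], inputs["probes"],
                                   inputs["variants"], inputs["go_terms"]) \
            if "genes" in inputs else None
        expr = {}
        for tissue in ("retina", "eye"):
            key = f"expression_{tissue}"
            if key in inputs:
                expr[tissue] = iof.read_expression_matrix(
                    inputs[key], ann, strain_order=g.strains, tissue=tissue)
        second_trait = iof.read_trait_table(inputs["second_trait"]) \
            if "second_trait" in inputs else None
        truth = None

    # --------------------------------------------------------------- phenotype
    summary_rows = {}
    if animals is not None:
        trait_raw = stage("aggregate", lambda: phenotypes.strain_summary(animals))
        iof.write_trait_table(trait_raw, out / "trait_raw.tsv")
        herit = stage("heritability", lambda: phenotypes.heritability(animals))
        mean_m, mean_f, sex_p = phenotypes.sex_compare(animals)
        age_slope, age_r2 = phenotypes.age_regression(animals)
        summary_rows.update(mean_male=mean_m, mean_female=mean_f, sex_p=sex_p,
                            age_slope=age_slope, age_r2=age_r2)
    else:
        trait_raw = trait_in
        try:
            herit = phenotypes.heritability(trait_raw)
        except Exception:
            herit = None

    high, low = stage("outliers", lambda: phenotypes.detect_outliers(trait_raw))
    trait = stage("winsorize", lambda: phenotypes.winsorize(trait_raw, high, low))
    iof.write_trait_table(trait, out / "trait_winsorized.tsv")

    # ----------------------------------------------------------------- mapping
    scan = stage("hk_scan", lambda: mapping.hk_scan(g, trait, step_cM))
    iof.write_scan(scan, out / "scan_hk.tsv")
    thr = stage("permutations", lambda: mapping.permutation_thresholds(
        g, trait, n_perm=n_perm, seed=map_seed, step_cM=step_cM))
    interval = stage("support_interval", lambda: mapping.support_interval(scan))
    lmm = stage("lmm_scan", lambda: mapping.lmm_scan(g, trait))
    iof.write_scan(lmm, out / "scan_lmm.tsv")
    robust = stage("robustness", lambda: mapping.robustness_suite(
        g, trait_raw, high, low, step_cM))
    robust.to_csv(out / "robustness.tsv", sep="\t", index=False, float_format="%.6g")

    # ------------------------------------------------------------------ triage
    triage_cfg_block = dict(config.get("triage", {}))
    triage_interval = tuple(triage_cfg_block.pop("interval", interval))
    result = {"peak": scan.peak().to_dict(), "lmm_peak": lmm.peak().to_dict(),
              "thresholds": asdict(thr), "support_interval": list(interval),
              **summary_rows}
    if herit is not None:
        result["heritability"] = asdict(herit)

    triage_table = None
    if expr and ann is not None:
        tcfg = cand.TriageConfig(interval=triage_interval, **triage_cfg_block)
        interval_genes = stage("genes_in_interval",
                               lambda: cand.genes_in_interval(ann, triage_interval))
        probe_ids = ann.probes.loc[ann.probes["gene_id"].isin(interval_genes["gene_id"]),
                                   "probe_id"].tolist()

        def run_eqtl():
            results = {}
            for tissue, ds in expr.items():
                res = eqtl_mod.eqtl_scan(ds, g, probe_ids=probe_ids,
                                         detection_threshold=tcfg.detection_threshold)
                sugg = eqtl_mod.suggestive_thresholds(ds, g, probe_ids,
                                                      n_perm=max(100, n_perm // 5),
                                                      seed=map_seed)
                gene_pos = ann.genes.set_index("gene_id")
                for r in res:
                    if r.gene_id in gene_pos.index and r.peak_chromosome:
                        r.is_cis = eqtl_mod.classify_cis(
                            r, gene_pos.loc[r.gene_id, "chromosome"],
                            gene_pos.loc[r.gene_id, "position_Mb"],
                            window_Mb=tcfg.cis_window_Mb,
                            min_lrs=float(sugg.get(r.probe_id, 0.0)))
                results[tissue] = res
            return results

        eqtl_results = stage("eqtl", run_eqtl)
        for tissue, res in eqtl_results.items():
            pd.DataFrame([vars(r) for r in res]).to_csv(
                out / f"eqtl_{tissue}.tsv", sep="\t", index=False, float_format="%.6g")

        ranks = stage("correlates", lambda: {
            tissue: cand.trait_correlates(trait, ds, tcfg.top_n_correlates)
            for tissue, ds in expr.items()})

        def run_network():
            flags = {}
            pre = cand.triage(tcfg, interval_genes, eqtl_results, ranks, ann, {})
            screen = pre[(pre["c4_detected"]) & (pre["c5_probe_clean"])]["gene_id"]
            for gid in screen:
                flags[gid] = enrichment.network_flag(
                    expr, gid, ann, tcfg.network_keywords,
                    n_top=tcfg.top_n_correlates, detect=tcfg.detection_threshold)
            return flags

        net_flags = stage("network", run_network)
        triage_table = stage("triage", lambda: cand.triage(
            tcfg, interval_genes, eqtl_results, ranks, ann, net_flags))
        triage_table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        result["n_interval_genes"] = int(len(interval_genes))
        result["tier1_genes"] = triage_table.loc[triage_table["tier"] == "1",
                                                 "gene_id"].tolist()
        result["tier2_genes"] = triage_table.loc[triage_table["tier"] == "2",
                                                 "gene_id"].tolist()

        if second_trait is not None:
            r, p, n = cand.trait_correlation(trait_raw, second_trait)
            tissue_a = "eye" if "eye" in expr else next(iter(expr))
            tissue_b = "retina" if "retina" in expr else tissue_a
            overlap = cand.shared_correlates(
                second_trait, trait_raw, expr[tissue_a], expr[tissue_b], ann,
                n_top=tcfg.comparison_top_n, detect=tcfg.detection_threshold)
            result["trait_comparison"] = {
                "r": r, "p": p, "n": n,
                "count_a_detected": overlap["count_a_detected"],
                "count_b_detected": overlap["count_b_detected"],
                "shared_count": overlap["shared_count"]}

    if truth is not None:
        result["truth"] = {k: v for k, v in truth.items()
                           if k in ("causal_gene", "interval", "h2_conventional")}

    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(result, fh, indent=2, default=float)
    (out / "report.txt").write_text(report(result, triage_table), encoding="utf-8")

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    manifest["digests"] = {p.name: _digest(p) for p in sorted(out.rglob("*"))
                           if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def triage_on_fixture(fx, tcfg: "cand.TriageConfig | None" = None, seed: int = 0,
                      n_perm: int = 200) -> pd.DataFrame:
    """Run the correlate/eQTL/network/triage cascade on a PanelFixture.

    Uses the fixture's planted interval (the study fixed its interval from
    the map before triage); mapping stages are not re-run here.
    """
    trait = phenotypes.strain_summary(fx.animals)
    high, low = phenotypes.detect_outliers(trait)
    trait = phenotypes.winsorize(trait, high, low)
    if tcfg is None:
        tcfg = cand.TriageConfig(interval=tuple(fx.truth["interval"]),
                                 top_n_correlates=100, comparison_top_n=200)
    ann = fx.annotations
    g = fx.genotypes
    interval_genes = cand.genes_in_interval(ann, tcfg.interval)
    probe_ids = ann.probes.loc[ann.probes["gene_id"].isin(interval_genes["gene_id"]),
                               "probe_id"].tolist()
    gene_pos = ann.genes.set_index("gene_id")
    eqtl_results = {}
    for tissue, ds in fx.expression.items():
        res = eqtl_mod.eqtl_scan(ds, g, probe_ids=probe_ids,
                                 detection_threshold=tcfg.detection_threshold)
        sugg = eqtl_mod.suggestive_thresholds(ds, g, probe_ids, n_perm=n_perm, seed=seed)
        for r in res:
            if r.gene_id in gene_pos.index and r.peak_chromosome:
                r.is_cis = eqtl_mod.classify_cis(
                    r, gene_pos.loc[r.gene_id, "chromosome"],
                    gene_pos.loc[r.gene_id, "position_Mb"],
                    window_Mb=tcfg.cis_window_Mb,
                    min_lrs=float(sugg.get(r.probe_id, 0.0)))
        eqtl_results[tissue] = res
    ranks = {tissue: cand.trait_correlates(trait, ds, tcfg.top_n_correlates)
             for tissue, ds in fx.expression.items()}
    pre = cand.triage(tcfg, interval_genes, eqtl_results, ranks, ann, {})
    flags = {}
    for gid in pre[(pre["c4_detected"]) & (pre["c5_probe_clean"])]["gene_id"]:
        flags[gid] = enrichment.network_flag(
            fx.expression, gid, ann, tcfg.network_keywords,
            n_top=tcfg.top_n_correlates, detect=tcfg.detection_threshold)
    return cand.triage(tcfg, interval_genes, eqtl_results, ranks, ann, flags)


def report(result: dict, triage_table: pd.DataFrame | None = None) -> str:
    """Human-readable run summary (peak table, thresholds, criteria matrix)."""
    lines = ["Run summary", "==========="]
    pk = result.get("peak", {})
    thr = result.get("thresholds", {})
    lines.append(f"HK peak: chr {pk.get('chromosome')} at {pk.get('Mb'):.2f} Mb, "
                 f"LRS {pk.get('lrs'):.2f} (additive {pk.get('additive'):+.1f}/allele)")
    if "lmm_peak" in result:
        lp = result["lmm_peak"]
        lines.append(f"LMM peak: chr {lp.get('chromosome')} at {lp.get('Mb'):.2f} Mb, "
                     f"LRS {lp.get('lrs'):.2f}")
    lines.append(f"Thresholds (LRS): significant {thr.get('significant_lrs'):.2f}, "
                 f"suggestive {thr.get('suggestive_lrs'):.2f} "
                 f"({thr.get('n_perm')} permutations)")
    if "support_interval" in result:
        c, lo, hi = result["support_interval"]
        lines.append(f"1.5-LOD support interval: chr {c}: {lo:.2f}-{hi:.2f} Mb")
    if "heritability" in result:
        h = result["heritability"]
        lines.append(f"Heritability: conventional {100 * h['h2_conventional']:.0f}%, "
                     f"strain-mean (RIx) {100 * h['h2_rix']:.0f}%")
    if triage_table is not None:
        tier1 = triage_table[triage_table["tier"] == "1"]
        if len(tier1):
            lines.append(f"Tier-1 candidates ({len(tier1)}): "
                         + ", ".join(tier1["symbol"]))
        else:
            lines.append("no tier-1 candidates")
        lines.append("")
        lines.append("Criteria matrix (1 row per interval gene):")
        cols = ["symbol"] + cand.CRITERIA + ["tier"]
        lines.append(triage_table[cols].to_string(index=False))
    if "trait_comparison" in result:
        tc = result["trait_comparison"]
        lines.append(f"Cross-trait: r = {tc['r']:.3f} (p = {tc['p']:.2e}, "
                     f"n = {tc['n']}); shared correlates "
                     f"{tc['shared_count']} of {tc['count_a_detected']}/"
                     f"{tc['count_b_detected']} detected")
    return "\n".join(lines) + "\n"
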