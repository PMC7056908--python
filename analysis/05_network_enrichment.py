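"""GO cellular-component enrichment of the top candidate's correlate network.

Builds the detection-filtered top-100 correlate set of the leading tier-1
gene in the retina, runs hypergeometric over-representation against the
expressed background with BH FDR, and keeps terminal significant terms.
Writes results/enrichment_top_candidate.tsv.
"""

import importlib.util, pathlib
spec = importlib.util.spec_from_file_location(
    "common", pathlib.Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec); spec.loader.exec_module(common)
common.parse_seed(__doc__)

import pandas as pd
from riqtl import enrichment as enr
from riqtl.eqtl import detection_filter

fx = common.load_panel()
cands = pd.read_csv(common.RESULTS / "candidates.tsv", sep="\t")
top = cands[cands["tier"] == "1"].iloc[0]
ds = fx.expression["retina"]
det = detection_filter(ds)
background = set(ds.probes.loc[det, "gene_id"].dropna())
corr = enr.gene_correlate_set(ds, top["gene_id"], fx.annotations,
                              n_top=100) & background
ora = enr.go_ora(corr, fx.annotations, background)
terminal = enr.terminal_significant(ora, fx.annotations)
ora.assign(terminal=ora["term_id"].isin(terminal["term_id"])).to_csv(
    common.RESULTS / "enrichment_top_candidate.tsv", sep="\t", index=False,
    float_format="%.4g")
print(f"candidate {top['symbol']}: {len(corr)} correlate genes in background "
      f"of {len(background)}")
for row in terminal.itertuples(index=False):
    print(f"  terminal significant: {row.name}  observed/expected = "
          f"{row.observed}/{row.expected:.1f} (ratio {row.ratio:.1f}), "
          f"FDR = {row.fdr:.2g}")
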