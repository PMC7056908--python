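"""Cross-trait comparison: necrosis vs the IOP-like trait.

Correlates the two strain-mean traits and intersects their
detection-filtered top-200 correlate gene lists (eye list for the IOP-like
trait, retina list for necrosis), the scaled analog of the published
top-2,000 comparison. Writes results/trait_comparison.tsv.
"""

import importlib.util, pathlib
spec = importlib.util.spec_from_file_location(
    "common", pathlib.Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec); spec.loader.exec_module(common)
common.parse_seed(__doc__)

import pandas as pd
from riqtl import candidates as cand
from riqtl.io_formats import read_trait_table

fx = common.load_panel()
necrosis = read_trait_table(common.RESULTS / "trait_raw.tsv")
iop = fx.second_trait

r, p, n = cand.trait_correlation(necrosis, iop)
print(f"IOP-like vs necrosis across {n} strains: r = {r:.3f} (p = {p:.2e})")

out = cand.shared_correlates(iop, necrosis, fx.expression["eye"],
                             fx.expression["retina"], fx.annotations,
                             n_top=200)
pd.DataFrame([{"r": r, "p": p, "n": n,
               "iop_detected": out["count_a_detected"],
               "necrosis_detected": out["count_b_detected"],
               "shared": out["shared_count"]}]).to_csv(
    common.RESULTS / "trait_comparison.tsv", sep="\t", index=False,
    float_format="%.4g")
print(f"top-200 correlates above detection: {out['count_a_detected']} (IOP, eye) "
      f"vs {out['count_b_detected']} (necrosis, retina); shared genes: "
      f"{out['shared_count']}")
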