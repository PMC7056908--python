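"""Generate the synthetic RI panel under the study conditions.

75 strains, 19 chromosomes at 2 cM marker spacing, 1-10 replicate animals
per strain with per-field axon counts, a planted +380 counts/allele QTL on
the chromosome-12 analog at 112 Mb, retina and eye expression (2,000 probes)
with 12 planted cis genes in the 109-112.5 Mb interval, a 60-gene
trait-correlated module, and an IOP-like second trait planted at r = -0.296.
Writes results/fixture/ (.geno, animal/trait/expression/annotation TSVs,
truth.json).
"""

import importlib.util, pathlib
spec = importlib.util.spec_from_file_location(
    "common", pathlib.Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec); spec.loader.exec_module(common)

seed = common.parse_seed(__doc__)

from riqtl.simulate import SimConfig, make_fixture, write_fixture

fx = make_fixture(SimConfig(seed=seed))
write_fixture(fx, common.FIXTURE)
print(f"panel written to {common.FIXTURE}")
print(f"  strains: {fx.genotypes.n_strains}, markers: {fx.genotypes.n_markers}, "
      f"animals: {len(fx.animals)}")
print(f"  planted QTL: chr {fx.truth['qtl'][0]['chromosome']} at "
      f"{fx.truth['qtl'][0]['Mb']} Mb, +{fx.truth['qtl'][0]['additive']:g}/allele")
print(f"  causal gene: {fx.truth['causal_gene']}  "
      f"(plug-in h2 ~ {fx.truth['h2_conventional']:.2f} before field noise)")
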