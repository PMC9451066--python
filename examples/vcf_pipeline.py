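"""End-to-end pipeline from a VCF file to ancestry fractions and plots.

Writes a synthetic VCF fixture, then runs the same steps the `archepop`
command-line tool performs: read genotypes, impute, MAF-filter, project
with the SVD, fit archetypes, and save the .Q-style fraction table plus
a compositional plot and a stacked bar plot.
"""

import tempfile
from pathlib import Path

import numpy as np

from archepop import (
    AAConfig,
    archetypes_in_snp_space,
    filter_rare_variants,
    fit,
    fit_projection,
    impute_missing,
    read_vcf,
    simulate_panel,
    write_fixture_vcf,
    write_fractions,
)
from archepop.plotting import ancestry_barplot, compositional_plot

workdir = Path(tempfile.mkdtemp(prefix="archepop_demo_"))
vcf = workdir / "panel.vcf"
panel, truth = simulate_panel(n=120, m=400, k=3, seed=5)
write_fixture_vcf(panel, vcf, seed=6)
print(f"wrote fixture VCF: {vcf}")

g = read_vcf(vcf)
g.populations = panel.populations
g = impute_missing(g)
g = filter_rare_variants(g, threshold=0.1)
print(f"after MAF filter: {g.n_samples} samples x {g.n_variants} SNPs")

pm = fit_projection(g)
res = fit(pm.scores, AAConfig(K=3, seed=0))
print(f"K=3 fit: RSS={res.rss:.1f}, explained variance={res.explained_variance:.3f}")

write_fractions(res.alpha, workdir / "panel.alpha.Q", sample_ids=g.sample_ids)
arch = archetypes_in_snp_space(g, res.beta)
print(f"SNP-space archetypes: {arch.shape[0]} x {arch.shape[1]}, entries in "
      f"[{arch.min():.2f}, {arch.max():.2f}] (inside observed dosage range)")

compositional_plot(res.alpha, labels=g.populations, out=workdir / "compositional.png")
ancestry_barplot(res.alpha, group_labels=g.populations, out=workdir / "barplot.png")
print(f"outputs in {workdir}: panel.alpha.Q, compositional.png, barplot.png")
print("-> the .Q file holds one simplex-valued ancestry row per individual,")
print("   directly comparable to ADMIXTURE output.")
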