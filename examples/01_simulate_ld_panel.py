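"""Simulate an LD panel and study sample, and look at what came out.

Runs a scaled-down neutral two-phase history (the full protocol uses 2000
loci and sizes 500/100 over 1050 generations), selects one marker per
10-locus bin plus the QTL closest to allele frequency 0.5, lays out the
1 cM analysis window with the QTL 0.3 cM from the first marker, and draws
a phenotyped study sample.
"""

import numpy as np

from gfmap.ld_simulator import DemographyConfig, simulate_study

locus_map, pop, panel, study = simulate_study(
    marker_spacing_cM=0.1,
    n=300,
    qtl_variance_fraction=0.05,
    seed=7,
    n_loci=400,  # 40 bins; the full protocol uses 2000
)

freqs = pop.allele_frequencies()
print(f"final generation {pop.generation}, census {pop.population_size}")
print(
    f"segregating loci: {np.mean((freqs > 0) & (freqs < 1)):.0%}; "
    f"QTL locus {panel.qtl_index} at frequency {freqs[panel.qtl_index]:.3f}"
)
print(
    f"window: {panel.n_window_markers} markers at {panel.marker_spacing_cM} cM "
    f"spacing; QTL at {panel.qtl_position_cM} cM from the first marker"
)
print(
    f"study: n={study.n_individuals}, phenotype variance {np.var(study.y):.3f} "
    f"(QTL explains {study.qtl_variance_fraction:.0%}, effect {study.mu_true:.3f})"
)
# The QTL genotype is simulation truth, hidden from the mapping methods:
corr = np.corrcoef(study.qtl_genotype, study.y)[0, 1]
print(f"corr(QTL genotype, phenotype) = {corr:.3f} (≈ sqrt of variance fraction)")
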