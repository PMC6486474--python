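"""RNA-seq counts with an eQTL, differential expression and ASE reads.

One gene carries both a cis-eQTL (fold change 1.5: genotype means mu,
1.5 mu, 2 mu) and a case-control fold change of 1.5. Heterozygotes emit
allele-specific reads (0.5% of the gene total, beta-binomially split).
"""

import numpy as np

from omicsim import (DEGeneSpec, EQTLSpec, RecombinationMap, drop_unrelated,
                     generate_reference_panel, generate_rnaseq_profile,
                     simulate_rnaseq)
from omicsim.distributions import LogNormal, PointMass

rng = np.random.default_rng(4)
profile = generate_rnaseq_profile(20, 50, LogNormal(5.3, 0.8), PointMass(0.1),
                                  LogNormal(0.0, 0.15), seed=1)
panel = generate_reference_panel(1000, 1, PointMass(0.4), seed=2)
panel.variant_ids = ["eqtl"]
geno = drop_unrelated(panel, RecombinationMap.zero(1), 1000, rng)
status = np.r_[np.ones(500, dtype=bool), np.zeros(500, dtype=bool)]

cm = simulate_rnaseq(profile, status,
                     de=[DEGeneSpec("gene1", 1.5)],
                     eqtl=[EQTLSpec("eqtl", "gene1", 1.5)],
                     genotypes=geno, rng=rng)

g = cm.row("gene1")
adj = cm.counts[g] / cm.c
print("case/control adjusted mean ratio:",
      round(float(adj[status].mean() / adj[~status].mean()), 3))
dose = geno.dosage()[:, 0]
means = [adj[dose == d].mean() for d in (0, 1, 2)]
print("genotype means (AA, Aa, aa):", [round(float(m), 1) for m in means])
print("aa/AA ratio (expect 2h-1 = 2):", round(float(means[2] / means[0]), 2))

het = cm.ase["het"][0]
tot_as = cm.ase["ref"][0] + cm.ase["alt"][0]
alt_frac = cm.ase["alt"][0][het].sum() / tot_as[het].sum()
print("ASE fraction of total reads:",
      round(float(tot_as[het].sum() / cm.counts[g, het].sum()), 4))
print("alt-allele read fraction in heterozygotes:", round(float(alt_frac), 3))
# Fold change and genotype means recover their configured values; ASE reads
# are 0.5% of the total with alt fraction 2^e/(1+2^e) = 2/3 for e = log2(2).
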