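"""Silencing-effect scores from a pooled shRNA dropout screen.

Scores each hairpin as the log2 ratio of its replicate-mean abundance
in a cell line over the initial DNA pool, collapses genes to their
top-scoring hairpin, and compares planted tumour suppressors against
background genes.
"""

import logging

import numpy as np

import driverlens as dl

logging.getLogger("driverlens").setLevel(logging.ERROR)

bundle, truth = dl.generate(dl.SyntheticConfig(n_samples=10, n_genes=400, seed=8))
screen = bundle.screen
line = screen.cell_lines[0]
print(f"screen: {screen.scores.shape[0]} probes x {screen.scores.shape[1]} conditions, "
      f"{len(screen.cell_lines)} cell lines + DNA pool")

supp = sorted(truth.suppressors)[0]
probe = screen.probes_for_gene(supp)[0]
print(f"\nprobe {probe}: log2ratio in {line} = "
      f"{dl.probe_log2ratio(screen, line, probe):+.3f}")
eff = dl.gene_effect(screen, line, supp)
print(f"gene {supp} (top of {eff.n_probes} probes): {eff.log2ratio:+.3f}")

count = dl.proliferation_count(screen, supp, screen.cell_lines)
print(f"{supp} increased proliferation in {count['n_increased']}/"
      f"{len(screen.cell_lines)} cell lines")

rng = np.random.default_rng(0)
background = rng.choice(
    sorted(set(bundle.genes) - truth.suppressors - set(bundle.known_cancer_set)),
    size=50, replace=False,
)
supp_eff = [dl.gene_effect(screen, line, g).log2ratio for g in sorted(truth.suppressors)]
bg_eff = [dl.gene_effect(screen, line, g).log2ratio for g in background]
res = dl.compare_silencing_groups(supp_eff, bg_eff)
print(f"\nsuppressors vs background in {line}: medians "
      f"{res['median_a']:+.2f} vs {res['median_b']:+.2f}, "
      f"rank-sum p = {res['wilcoxon_p']:.3g}")
# Silencing a tumour suppressor boosts proliferation, so its hairpins
# are enriched over the pool: positive medians, and a decisive p-value.
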