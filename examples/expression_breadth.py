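"""Expression breadth over a healthy-tissue panel.

Calls expression from probe detection p-values, classifies genes into
housekeeping / intermediate / tissue-selective, and contrasts the
expressed fraction of known cancer genes against the rest of the
genome — the volcano-plot statistic.
"""

import pandas as pd

import driverlens as dl

# the at-least-half-of-probes rule at alpha = 0.05
probes = pd.DataFrame(
    {
        "probe_id": ["p1", "p2", "p3"],
        "gene_id": ["G1", "G1", "G1"],
        "context_id": ["liver", "liver", "liver"],
        "detection_p": [0.01, 0.02, 0.90],
    }
)
matrix = dl.call_expression(probes)
print(f"G1 in liver with detection p {list(probes.detection_p)}: "
      f"{matrix.call('liver', 'G1')} (2 of 3 probes detected)")

# class boundaries on a 109-tissue panel
cuts = dl.breadth_cutoffs(109)
print(f"109-tissue panel: housekeeping >= {cuts['housekeeping_min']} tissues, "
      f"tissue-selective <= {cuts['tissue_selective_max']}")
for n in (108, 50, 20):
    print(f"  expressed in {n}/109 tissues -> {dl.classify_breadth(n, 109)}")

# group contrast on a synthetic tissue panel
bundle, _ = dl.generate(dl.SyntheticConfig(n_samples=10, n_genes=400, seed=5))
panel = bundle.tissue_expression
genes = set(panel.genes)
known = set(bundle.known_cancer_set)
rest = genes - known
cmp = dl.expressed_fraction_comparison(known, rest, panel.contexts[0], panel)
print(f"\nknown vs rest in {panel.contexts[0]}: "
      f"f_known={cmp.f_group:.2f}, f_rest={cmp.f_rest:.2f}, "
      f"log2ratio={cmp.log2ratio if cmp.log2ratio is None else round(cmp.log2ratio, 3)}, "
      f"chi2={cmp.chi2_stat:.2f}, p={cmp.p_value:.3g}")

# breadth distributions compared by rank-sum (Shapiro-Wilk reported only)
breadth = panel.breadth()
known_counts = breadth.loc[sorted(known & genes), "n_expressed"]
rest_counts = breadth.loc[sorted(rest)[:100], "n_expressed"]
res = dl.compare_breadth_distributions(known_counts, rest_counts)
print(f"breadth medians {res['median_a']:.0f} vs {res['median_b']:.0f} tissues, "
      f"rank-sum p={res['wilcoxon_p']:.3g}")
# On this synthetic panel breadth is random, so expect a non-significant p.
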