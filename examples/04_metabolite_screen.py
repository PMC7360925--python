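"""Two-stage metabolite screening on a genotype-structured matrix.

Generates a log-abundance matrix for 6 host genotypes (half carrying the
facultative symbiont) with strong genotype effects and one planted
status-affected feature, then runs the screen: t-test prefilter, mixed
model with genotype as a random effect, Benjamini–Hochberg adjustment.
"""

import numpy as np

from symbiofba import gen_metabolomics_matrix, metabolite_screen

effects = np.zeros(120)
effects[17] = 4.0  # one strongly status-affected metabolite

matrix, design = gen_metabolomics_matrix(
    n_genotypes=6, n_reps=5, genotype_sd=1.0,
    status_effects=effects, noise_sd=0.5, seed=3,
)
table = metabolite_screen(matrix, design)

n_stage1 = int(table["candidate"].sum())
hits = table[table["significant"]]
print(f"features screened:      {len(table)}")
print(f"stage-1 t-test flags:   {n_stage1}")
print(f"BH-significant (mixed): {len(hits)}  ->  {list(hits.index)}")
print(f"strongest stage-1 hit:  {table['p_t'].idxmin()}")
print()
print(table.loc[["metab_18"], ["t_stat", "p_t", "mixed_stat", "p_mixed", "p_adj"]])
print(
    "\nGenotype structure inflates the naive t-test flag count far above the\n"
    "5% false-positive rate.  The planted feature dominates stage 1 and stays\n"
    "near the top of the mixed-stage ranking, but because symbiont status\n"
    "varies only between genotypes (6 of them), the genotype-corrected test\n"
    "has little power and nothing survives adjustment.  That null outcome is\n"
    "the screen working as intended — resolving such effects takes\n"
    "genotype-controlled (isogenic) designs, not cross-genotype comparisons."
)
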