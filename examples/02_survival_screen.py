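"""Screen modules for survival stratification in a simulated tumor cohort.

The cohort's immune-infiltrate fraction raises module-gene expression and
halves the death hazard in the upper infiltrate half (log hazard ratio
beta = -1, protective).  Each module's score (median expression of its
genes) splits the cohort at the median; the log-rank test compares the two
strata and Harrell's C measures the score's discrimination.
"""

from immunomod.modules import build_all_modules
from immunomod.survival import screen
from immunomod.synthdata import generate_reference_panel, generate_tumor_cohort

ref_expr, markers, truth = generate_reference_panel(
    n_blocks=3, n_background_genes=1000, n_samples=336, seed=42)
collection = build_all_modules(ref_expr, markers)

expr, clinical, cohort_truth = generate_tumor_cohort(
    n_samples=300, reference_truth=truth, beta=-1.0, seed=43)
print(f"cohort: {len(clinical.sample_ids)} samples, "
      f"{int(clinical.event.sum())} deaths observed")

result = screen(expr, clinical, collection)
print(result.results[["chi_square", "p", "n_hi", "n_lo", "direction",
                      "concordance_oriented"]].round(4))
print(f"modules significant at p<1e-3: "
      f"{result.significant_counts[1e-3]}/{len(result.results)}")
# direction = +1 means the module-hi half survives longer, matching the
# planted protective effect; oriented C near 0.6 indicates moderate
# discrimination of the continuous score.
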