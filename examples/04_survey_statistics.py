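"""Survey statistics: prevalence intervals, composition, sex ratios, agreement.

Works directly from the printed survey counts of a 77-dog flea survey
(43 infested; 199 fleas: 115 C. canis, 53 C. orientis, 22 P. irritans,
9 unidentified) and from the observer-vs-cox1 contingency counts.
"""

from fleagm.survey_stats import agreement_table, prevalence_ci, sex_ratio, species_composition

ci = prevalence_ci(43, 77)
print(f"infestation prevalence: {ci['percent']}% "
      f"(95% Wald CI {ci['lower']}-{ci['upper']}%), k={ci['k']}, n={ci['n']}")

comp = species_composition({"canis": 115, "orientis": 53, "irritans": 22, "unidentified": 9})
print("species composition (%):", comp)

print(f"sex ratio F:M  C. orientis 45/8 = {sex_ratio(45, 8)},  "
      f"P. irritans 20/2 = {sex_ratio(20, 2)}")

print(f"cox1 sequencing success: {prevalence_ci(166, 175)['percent']}% (166/175)")

# observer (morphological key) against the cox1 reference identification
truth = ["orientis"] * 7
assigned = ["canis"] * 4 + ["orientis"] * 3
_, rates = agreement_table(truth, assigned)
print(f"morphological misidentification of male C. orientis: {rates['orientis']}% (4/7)")
truth = ["orientis"] * 51
assigned = ["canis"] * 16 + ["orientis"] * 35
_, rates = agreement_table(truth, assigned)
print(f"morphological misidentification of female C. orientis: {rates['orientis']}% (16/51)")
# These are the error rates the shape-based classifier is measured against.
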