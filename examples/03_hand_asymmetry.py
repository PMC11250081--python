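"""Left-right asymmetry of finger biomechanics: healthy vs dystonic cohorts.

Generates score tables for 20 healthy and 16 dystonic pianists (six finger
functions per hand), standardizes each score against the healthy reference,
computes the per-subject asymmetry norm Assym = ||z_L - z_R||, and compares
the groups per function with the Mann-Whitney U test under Benjamini-
Hochberg correction.
"""

import dystonia_screen as ds

# the dystonic cohort's affected hand is degraded on the two multi-finger
# control functions (simultaneous-force reduction ratio and independence)
table = ds.gen_biomech_cohort(n_healthy=20, n_md=16, seed=7)
result = ds.compare_groups(table)

print(result.per_function.to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}"))
print()
for _, row in result.per_function.iterrows():
    verdict = "differs between groups" if row["significant"] else "no group difference"
    print(f"  {row['function']:>15}: adjusted p = {row['p_adj']:.3f} -> {verdict}")
print("\nonly the multi-finger-control functions should come out significant: "
      "their asymmetry is larger in the dystonic cohort, while strength, "
      "agility and range of motion are left intact by construction")
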