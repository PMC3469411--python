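"""MMR correction factors from paired rate measurements.

The correction factor is the mutation rate of an MMR-deficient (msh2-null)
strain divided by its MMR-proficient partner's; 1 - 1/CF is the fraction of
replication errors that mismatch repair removes. Inputs here are the
published overall rates of three mutator-polymerase backgrounds.
"""

from strandmmr import combine_orientations, correction_factor, repair_efficiency

backgrounds = {
    "Pol epsilon mutator (leading strand)": (1.6e-5, 6.5e-8),
    "Pol alpha mutator (lagging strand)": (5.2e-5, 7.0e-8),
    "Pol delta mutator (lagging strand)": (2.2e-5, 1.4e-7),
}
for name, (deficient, proficient) in backgrounds.items():
    cf = correction_factor(deficient, proficient)
    eff = repair_efficiency(cf)
    print(
        f"{name}: CF = {cf.value:.0f} (reported {cf.display_value:.0f}x), "
        f"{eff.percent:.1f}% of errors repaired"
    )

# orientation averaging is geometric: factors are ratios
or1 = correction_factor(1e-5, 1e-7)   # 100x in orientation 1
or2 = correction_factor(2e-5, 5e-8)   # 400x in orientation 2
combined = combine_orientations(or1, or2)
print(f"\nOR1 100x and OR2 400x combine to {combined.value:.0f}x (geometric mean)")

# zero observations on the deficient side give an upper bound
bounded = correction_factor(
    0.0, 1e-7, count_deficient=0, count_proficient=6, pseudocount_rate=4e-7
)
print(
    f"0 deficient observations -> CF <= {bounded.value:.1f} "
    f"(count raised to 1, flagged upper bound: {bounded.is_upper_bound})"
)
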