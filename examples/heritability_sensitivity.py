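"""Prevalence-sensitivity heritability table from a published odds ratio.

The matched case-control analysis of the source cohort reported an odds
ratio of 2.22 (95% CI 1.03-4.81) for tinnitus in adoptees with at least
one affected biological parent, with 383 of 11 060 adoptees carrying that
exposure.  Since the population prevalence of clinically significant
tinnitus is uncertain, the tetrachoric correlation of liability -- and
hence heritability h2 = r / 0.5 for parent-offspring pairs -- is solved
under a grid of assumed prevalences.
"""

from adoptherit import sensitivity_table

table = sensitivity_table(
    or_obs=2.22,
    or_ci=(1.03, 4.81),
    exposure_prevalence=383 / 11_060,
)

print(table.round(3).to_string(index=False))
print(
    "\nEach row: assumed population prevalence, the liability correlation"
    "\nr between adoptee and biological-parent status implied by OR 2.22,"
    "\nits delta-method SE, and heritability h2 = r / 0.5 with SE."
    "\nHeritability rises from ~19% at 0.01% prevalence to ~35% at 5%."
)
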