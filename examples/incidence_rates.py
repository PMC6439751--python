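"""Cohort incidence rates and ratios by parental tinnitus exposure.

Recomputes the cohort-study incidence block from its published counts:
events and person-years among adoptees with vs without an affected
biological (then adoptive) parent.
"""

from adoptherit import incidence_rate, rate_ratio

print("Biological-parent exposure")
unexposed = incidence_rate(201, 495_278)
exposed = incidence_rate(13, 18_122)
for label, r in (("  not affected", unexposed), ("  affected    ", exposed)):
    print(f"{label}: {r.rate_per_1000:.2f} per 1000 py "
          f"({r.ci_low:.2f}-{r.ci_high:.2f})")
rr = rate_ratio(exposed, unexposed)
print(f"  incidence ratio: {rr.ratio:.2f} ({rr.ci_low:.2f}-{rr.ci_high:.2f})")

print("\nAdoptive-parent exposure")
unexposed = incidence_rate(204, 490_606)
exposed = incidence_rate(10, 22_794)
rr = rate_ratio(exposed, unexposed)
print(f"  affected rate : {exposed.rate_per_1000:.2f} per 1000 py")
print(f"  incidence ratio: {rr.ratio:.2f} ({rr.ci_low:.2f}-{rr.ci_high:.2f})")

print(
    "\nAdoptees with an affected biological parent develop clinically"
    "\nsignificant tinnitus ~1.8x faster; an affected adoptive parent"
    "\nconfers no excess (ratio ~1), separating genes from rearing"
    "\nenvironment."
)
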