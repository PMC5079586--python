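# Life history of the Galapagos sailfin grouper (bacalao), the default
# assessment configuration shipped with the package.
l_inf: 110.0          # asymptotic length L-infinity (cm)
cv_linf: 0.10         # CV of L-infinity among individuals
m_nat: 0.29           # natural mortality M (1/yr), from a congener
m_over_k: 2.7         # M/k life-history ratio
t0: 0.0               # von Bertalanffy age at zero length (yr)
lm50: 65.3            # length at 50% maturity (cm)
lm95: 71.83           # length at 95% maturity (cm), 1.1 x lm50
fec_b: 3.0            # fecundity-length exponent (eggs ~ length^b)
am: 6.5               # female age at maturity (yr)
tmax: 21.0            # maximum age (yr)
max_len: 120.0        # maximum reported length (cm)
# module defaults
bin_width: 2.0        # length bin width (cm)
n_gtg: 13             # growth-type groups
max_sd: 2.5           # GTG quantile span (sd units)
n_boot: 100           # bootstrap replicates for LB-SPR SDs
limb_rule: peak       # catch-curve descending-limb rule
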