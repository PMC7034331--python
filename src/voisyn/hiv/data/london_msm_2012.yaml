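# HIV surveillance observations, MSM in London, 2012.
# ypop is the ONS mid-2012 estimate of men aged 15-44 resident in London
# (the age range of this model lineage; a configuration datum treated as
# one Poisson count).
ypop: 2050000
# NATSAL survey: GMSM / NGMSM / PMSM out of all men surveyed
y_G: 7
y_N: 38
y_P: 10
y_NAT: 824
# SOPHID register: prevalent diagnosed HIV among MSM
y_M: 8390
# HANDD: new GUM-clinic diagnoses among prevalent diagnosed MSM
y_H: 630
# GUMCAD testing cascade: visitors -> undiagnosed -> offered -> accepted -> diagnosed
g1: 35121
g2: 34187
g3: 30570
g4: 29529
g5: 855
# GUM Anon survey: positives out of previously undiagnosed attenders tested
g_A: 4
g_AN: 85
# GMSHS venue survey: positives / tested among GMSM and NGMSM
# (the NGMSM denominator is 452; a figure of 492 appearing once elsewhere
#  in the source material is treated as a typo)
y_G_GM: 20
n_G_GM: 493
y_N_GM: 20
n_N_GM: 452
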