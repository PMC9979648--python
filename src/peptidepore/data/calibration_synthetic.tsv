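# Synthetic beta-barrel calibration table: conductance (1 M KCl) vs pore diameter.
# Placeholder values consistent with the 0.4 nS~1.1 nm / 0.8 nS~1.5 nm /
# 1.1 nS~1.7 nm correspondences used elsewhere in the package; replace with
# literature values for real analyses.
protein	conductance_ns	diameter_nm
OmpA	0.30	1.00
CymA	0.45	1.15
OmpG	0.85	1.50
OmpF	1.10	1.70
Vdac	2.00	2.45
FhuA	2.60	3.00
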