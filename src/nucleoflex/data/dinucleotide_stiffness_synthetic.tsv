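# Synthetic dinucleotide stiffness/equilibrium table (constructed for this
# package; literature-flavoured magnitudes, not fitted to any ensemble).
# Units: translations A, rotations deg; stiffness kcal/mol per (A|deg)^2.
# Parameter order: shift, slide, rise, tilt, roll, twist.
# Couplings kept within the strand-symmetric pairs (shift,tilt), (slide,rise), (roll,twist).
context	shift0	slide0	rise0	tilt0	roll0	twist0	t11	t12	t13	t14	t15	t16	t22	t23	t24	t25	t26	t33	t34	t35	t36	t44	t45	t46	t55	t56	t66
AA	-0.03	-0.18	3.32	-1.0	0.2	35.8	1.90	0	0	0.012	0	0	3.40	0.20	0	0	0	8.20	0	0	0	0.085	0	0	0.075	-0.005	0.055
AC	0.13	-0.59	3.36	-0.5	0.7	31.8	1.55	0	0	0.012	0	0	2.53	0.20	0	0	0	6.80	0	0	0	0.042	0	0	0.030	-0.005	0.040
AG	0.09	-0.33	3.34	-1.7	4.5	32.3	1.48	0	0	0.012	0	0	2.24	0.20	0	0	0	6.40	0	0	0	0.040	0	0	0.028	-0.005	0.036
AT	0.00	-0.65	3.31	0.0	1.1	30.5	2.00	0	0	0.012	0	0	3.60	0.20	0	0	0	8.40	0	0	0	0.090	0	0	0.080	-0.005	0.060
CA	0.09	0.53	3.33	0.5	4.7	34.5	1.10	0	0	0.012	0	0	1.45	0.20	0	0	0	4.30	0	0	0	0.026	0	0	0.016	-0.005	0.020
CC	0.05	-0.22	3.36	-0.1	3.6	33.7	1.35	0	0	0.012	0	0	2.05	0.20	0	0	0	5.90	0	0	0	0.036	0	0	0.026	-0.005	0.033
CG	0.00	0.41	3.35	0.0	5.4	34.6	1.05	0	0	0.012	0	0	1.40	0.20	0	0	0	4.10	0	0	0	0.025	0	0	0.016	-0.005	0.019
GA	-0.28	-0.01	3.38	-1.5	1.9	36.9	1.40	0	0	0.012	0	0	2.10	0.20	0	0	0	6.00	0	0	0	0.037	0	0	0.027	-0.005	0.034
GC	0.00	0.40	3.38	0.0	0.3	36.1	1.25	0	0	0.012	0	0	1.85	0.20	0	0	0	5.50	0	0	0	0.032	0	0	0.024	-0.005	0.030
TA	0.00	0.05	3.34	0.0	3.3	36.3	0.95	0	0	0.012	0	0	1.20	0.20	0	0	0	3.80	0	0	0	0.022	0	0	0.013	-0.005	0.016
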