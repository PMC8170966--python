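# Dinucleotide helical step parameters (crystallographic averages);
# reverse-complement symmetric (Tilt and Shift change sign). Raw values;
# each index is standardized to mean 0 / SD 1 at load time.
oligo	Twist	Tilt	Roll	Shift	Slide	Rise
AA	35.10	-1.40	0.70	-0.03	-0.08	3.27
AC	31.50	-0.10	0.70	0.13	-0.58	3.36
AG	31.90	-1.70	4.50	0.09	-0.25	3.34
AT	29.30	0.00	1.10	0.00	-0.59	3.31
CA	37.30	0.50	4.70	0.09	0.53	3.33
CC	32.90	-0.10	3.60	0.05	-0.22	3.42
CG	36.10	0.00	5.40	0.00	0.41	3.39
CT	31.90	1.70	4.50	-0.09	-0.25	3.34
GA	36.30	-1.50	1.90	-0.28	0.09	3.37
GC	33.60	0.00	0.30	0.00	-0.11	3.40
GG	32.90	0.10	3.60	-0.05	-0.22	3.42
GT	31.50	0.10	0.70	-0.13	-0.58	3.36
TA	37.80	0.00	3.30	0.00	0.05	3.42
TC	36.30	1.50	1.90	0.28	0.09	3.37
TG	37.30	-0.50	4.70	-0.09	0.53	3.33
TT	35.10	1.40	0.70	0.03	-0.08	3.27
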