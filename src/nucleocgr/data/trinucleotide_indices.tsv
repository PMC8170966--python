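# Trinucleotide indices: DNase-I-derived bendability consensus scale
# (complement-symmetric) and RollMean, the mean Roll of the two helical
# steps inside the trinucleotide (derived from the dinucleotide table).
# Raw values; standardized to mean 0 / SD 1 at load time.
oligo	Bendability	RollMean
AAA	-0.274	0.70
AAC	-0.205	0.70
AAG	-0.081	2.60
AAT	-0.280	0.90
ACA	-0.006	2.70
ACC	-0.032	2.15
ACG	-0.033	3.05
ACT	-0.183	2.60
AGA	0.027	3.20
AGC	0.017	2.40
AGG	-0.057	4.05
AGT	-0.183	2.60
ATA	0.182	2.20
ATC	-0.110	1.50
ATG	0.134	2.90
ATT	-0.280	0.90
CAA	0.015	2.70
CAC	0.040	2.70
CAG	0.175	4.60
CAT	0.134	2.90
CCA	-0.246	4.15
CCC	-0.012	3.60
CCG	-0.136	4.50
CCT	-0.057	4.05
CGA	-0.003	3.65
CGC	-0.077	2.85
CGG	-0.136	4.50
CGT	-0.033	3.05
CTA	0.090	3.90
CTC	0.031	3.20
CTG	0.175	4.60
CTT	-0.081	2.60
GAA	-0.037	1.30
GAC	-0.013	1.30
GAG	0.031	3.20
GAT	-0.110	1.50
GCA	0.076	2.50
GCC	0.107	1.95
GCG	-0.077	2.85
GCT	0.017	2.40
GGA	0.013	2.75
GGC	0.107	1.95
GGG	-0.012	3.60
GGT	-0.032	2.15
GTA	0.025	2.00
GTC	-0.013	1.30
GTG	0.040	2.70
GTT	-0.205	0.70
TAA	0.068	2.00
TAC	0.025	2.00
TAG	0.090	3.90
TAT	0.182	2.20
TCA	0.194	3.30
TCC	0.013	2.75
TCG	-0.003	3.65
TCT	0.027	3.20
TGA	0.194	3.30
TGC	0.076	2.50
TGG	-0.246	4.15
TGT	-0.006	2.70
TTA	0.068	2.00
TTC	-0.037	1.30
TTG	0.015	2.70
TTT	-0.274	0.70
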