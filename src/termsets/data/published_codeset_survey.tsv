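# 31 published cohort-definition code sets (Read v2) and the sizes of their
# term-set conversions, as printed in the source survey. Columns: label,
# code-set size, inclusion terms, exclusion terms, printed proportion (%).
# The printed proportion is preserved verbatim; for the Residence row it
# disagrees with the printed counts (92+111 over 168 computes to 120.8).
label	codeset_size	n_inclusion	n_exclusion	proportion_pct
Type 2 diabetes mellitus	116	5	9	12.1
Cancer except non-melanoma skin cancer	1395	67	144	15.1
Total knee replacement	40	2	8	25
Polymyalgia rheumatic	3	1	0	33.3
Asthma specific	120	4	51	45.8
Hidradenitis suppurativa (HS)	2	1	0	50
Shortness of breath excluded	29	11	4	51.7
Shortness of breath	48	11	14	52.1
Dementia	74	8	31	52.7
Non acute heart failure	40	22	0	55
Ethnicity	183	46	63	59.6
Potential hospitalized infections	3219	1383	537	59.6
Tuberculosis	151	4	95	65.6
Shoulder dislocation	18	2	10	66.7
Country of birth	467	241	88	70.4
Giant cell arteritis	7	4	1	71.4
Type 1 diabetes mellitus	35	4	25	82.9
Psoriatic arthritis	7	5	1	85.7
Possible undiagnosed HS	47	40	2	89.4
Religion	112	72	29	90.2
Fragility fracture	18	3	14	94.4
Rheumatoid arthritis	57	13	42	96.5
Living alone	65	39	25	98.5
Colorectal cancer	23	9	14	100
Stevens-Johnson syndrome	1	1	0	100
Toxic epidermal necrolysis	5	4	1	100
Myotonic dystrophy type 1	2	2	0	100
Marital status	148	34	131	111.5
Cohabitation	85	22	79	118.8
Residence	168	92	111	120.1
Heart failure	55	20	48	123.6
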