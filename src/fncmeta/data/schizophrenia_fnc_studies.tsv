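study_id	first_author	year	n_patients	male_patients	n_controls	male_controls	mean_age_pat	mean_age_con	criteria	medicated	illness_duration_months	panss_total	panss_pos	panss_neg	scanner	sequence	global_signal_removed	smoothing_fwhm_mm	tr_ms	te_ms	slice_thickness_mm	corr_threshold	fnc_type	reporting_p	reporting_corrected	n_coordinates	shared_control_group
chen2015_1	Chen	2015	42	19	84	42	24.6	24.7	DSM-IV	yes	39.2	86.0	23.2	20.5	GE	EPI	yes	6	2000	30	4	0.25	weighted	0.01	yes	3	a
chen2015_2	Chen	2015	42	21	84	42	24.7	24.7	DSM-IV	yes	49.0	86.0	22.7	20.6	GE	EPI	yes	6	2000	30	4	0.25	weighted	0.01	yes	3	a
chen2022_1	Chen	2022	46	21	48	23	21.7	21.9	DSM-V	no	NA	82.3	20.1	20.2	GE	GRE-SS-EPI	no	6	2000	30	4	0.2	weighted	0.05	yes	4	b
chen2022_2	Chen	2022	39	18	48	23	20.2	21.9	DSM-V	no	NA	81.6	18.1	21.0	GE	GRE-SS-EPI	no	6	2000	30	4	0.2	weighted	0.05	yes	7	b
chen2018	Chen	2018	52	45	128	99	28.0	27.1	DSM-IV	yes	71.1	66.5	18.4	17.2	Siemens	EPI	no	4	2000	30	4	0.2	binary	0.05	yes	1	NA
chen2019	Chen	2019	30	22	30	17	25.8	25.0	DSM-IV	yes	51.5	88.0	23.8	22.1	Siemens	EPI	no	6	2000	30	4	0.2	binary	0.05	yes	6	NA
chen2019s_1	Chen	2019	26	12	33	14	25.1	27.3	SCID-IV	yes	52.0	44.2	8.8	10.7	GE	Gradient-recalled EPI	yes	4	2000	35	3.6	0.25	weighted	0.05	yes	7	c
chen2019s_2	Chen	2019	31	14	33	14	24.9	27.3	SCID-IV	yes	55.6	48.1	13.2	10.9	GE	Gradient-recalled EPI	yes	4	2000	35	3.6	0.25	weighted	0.05	yes	4	c
ding2019	Ding	2019	44	28	44	23	23.5	23.6	DSM-IV	no	22.3	90.7	22.5	22.5	Siemens	GRE-EPI	no	4	2000	30	4	NA	weighted	0.05	yes	7	NA
guo2015	Guo	2015	49	30	50	23	22.7	23.5	DSM-IV	no	22.5	91.3	22.3	22.8	Siemens	GRE-EPI	no	8	2000	30	4	NA	weighted	0.001	yes	3	NA
guo2017	Guo	2017	17	8	24	11	33.1	30.7	DSM-IV	no	12.0	88.1	23.0	20.2	Philips	GRE-EPI	no	4	2000	30	5	NA	weighted	0.001	yes	6	NA
kang2020	Kang	2020	52	20	51	22	26.0	26.0	DSM-IV	no	NA	NA	NA	NA	Siemens	EPI	no	6	3000	30	3	0.6	binary	0.05	yes	5	NA
li2020	Li	2020	32	16	32	21	30.9	31.4	DSM-IV	no	8.9	77.4	20.0	20.6	Siemens	GRE-EPI	no	NA	2000	30	4	NA	weighted	0.05	yes	4	NA
lei2015	Lei	2015	124	61	102	50	24.5	24.8	DSM-IV	no	6.8	88.4	15.3	15.7	GE	EPI	yes	6	2000	30	5	0.25	binary	0.05	yes	2	NA
miao2020_1	Miao	2020	15	10	20	6	35.2	35.1	DSM-IV	yes	178.8	71.5	19.3	16.8	GE	NA	no	4	2000	40	5	0.2	weighted	0.05	yes	7	d
miao2020_2	Miao	2020	19	7	20	6	34.6	35.1	DSM-IV	yes	156.0	75.1	20.7	19.8	GE	NA	no	4	2000	40	5	0.2	weighted	0.05	yes	4	d
palaniyappan2014	Palaniyappan	2014	39	30	34	23	34.2	33.8	DSM-IV	yes	NA	NA	NA	NA	Philips	GRE-EPI	yes	8	2500	NA	4	0.25	binary	0.05	yes	13	NA
skatun2016	Skatun	2016	71	44	196	113	28.2	31.5	DSM-IV	yes	63.6	58.1	13.3	14.8	GE	GRE-EPI	no	6	2638	30	3	NA	binary	0.05	yes	12	NA
wang2018	Wang	2018	56	23	56	25	25.5	25.8	DSM-IV	no	NA	NA	NA	NA	Siemens	EPI	no	8	3000	30	3	0.6	binary	0.05	yes	2	NA
wang2017	Wang	2017	35	20	30	13	15.5	15.3	DSM-IV-TR	no	16.0	74.6	20.4	20.9	Siemens	EPI	no	6	2000	30	4	NA	binary	0.05	yes	7	NA
yang2020	Yang	2020	11	6	19	10	41.2	37.6	DSM-IV	yes	NA	84.9	23.6	22.2	Philips	EPI	no	6	2000	30	4	0.3	binary	0.005	no	2	NA
yu2021	Yu	2021	22	11	60	38	33.4	32.9	DSM-IV-TR	no	15.5	93.5	27.2	19.8	Siemens	GRE-EPI	no	6	2000	30	4	0.25	binary	0.05	yes	4	NA
zhao2022	Zhao	2022	48	21	31	14	15.8	15.4	DSM-IV-TR	no	5.4	75.1	21.5	17.9	Siemens	EPI	no	4	2000	30	NA	NA	weighted	0.05	yes	5	NA
zhou2022	Zhou	2022	20	7	21	8	16.8	16.8	DSM-IV	no	6.0	92.8	24.5	25.7	Siemens	GRE-EPI	no	8	2000	30	4	0.25	weighted	0.05	yes	3	NA
zhuo2017	Zhuo	2017	95	54	93	45	33.6	33.0	DSM-IV	yes	121.4	71.5	17.1	20.3	GE	GRE-SS-EPI	no	6	2000	45	4	0.6	binary	0.05	yes	13	NA
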