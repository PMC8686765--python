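strain	mu	mu_sd	r_glc	r_glc_sd	r_eth	r_eth_sd	r_ace	r_ace_sd	r_for	r_for_sd	r_lac	r_lac_sd	r_suc	r_suc_sd	r_atpm	r_atpm_sd	y_bm	y_bm_sd	y_eth	y_eth_sd	y_ace	y_ace_sd	y_for	y_for_sd	y_lac	y_lac_sd	y_suc	y_suc_sd
WT	0.0	0.0	1.90	0.11	1.43	0.21	1.55	0.07	2.23	0.18	0.12	0.02	0.75	0.03	4.16	0.27	0.0	0.0	0.738	0.009	0.840	0.021	1.114	0.039	0.063	0.006	0.383	0.026
WT_IPTG	0.0	0.0	2.02	0.06	1.43	0.04	1.50	0.02	2.09	0.03	0.22	0.04	0.71	0.02	4.29	0.08	0.0	0.0	0.703	0.035	0.758	0.004	0.993	0.056	0.084	0.003	0.341	0.007
LC_control	0.0	0.0	2.34	0.34	1.47	0.04	1.58	0.04	2.10	0.10	0.32	0.12	0.95	0.02	4.59	0.23	0.0	0.0	0.658	0.011	0.704	0.015	0.915	0.055	0.128	0.023	0.413	0.003
LC_ATPase	0.0	0.0	8.96	0.36	4.78	0.35	4.69	0.28	7.65	0.47	5.71	0.12	2.20	0.08	18.62	0.82	0.0	0.0	0.497	0.011	0.467	0.014	0.645	0.018	0.728	0.013	0.227	0.002
MC_control	0.0	0.0	2.18	0.06	1.43	0.09	1.54	0.03	2.04	0.07	0.49	0.19	0.89	0.06	4.63	0.12	0.0	0.0	0.683	0.010	0.709	0.028	0.901	0.058	0.221	0.036	0.407	0.006
MC_ATPase	0.0	0.0	10.46	0.43	3.16	0.40	2.56	0.54	4.28	0.82	11.31	0.54	1.95	0.01	19.31	0.78	0.0	0.0	0.284	0.015	0.259	0.011	0.305	0.018	1.177	0.032	0.155	0.005
HC_control	0.0	0.0	2.95	0.09	1.34	0.06	1.43	0.06	2.17	0.12	1.51	0.10	0.94	0.04	5.42	0.14	0.0	0.0	0.512	0.032	0.406	0.024	0.520	0.036	0.734	0.023	0.289	0.008
HC_ATPase	0.0	0.0	8.10	0.60	0.66	0.14	0.60	0.03	0.42	0.03	13.78	0.36	0.35	0.04	15.63	0.60	0.0	0.0	0.076	0.003	0.092	0.003	0.059	0.001	1.740	0.036	0.043	0.002
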