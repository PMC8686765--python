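strain	mu	mu_sd	r_glc	r_glc_sd	r_eth	r_eth_sd	r_ace	r_ace_sd	r_for	r_for_sd	r_lac	r_lac_sd	r_suc	r_suc_sd	r_atpm	r_atpm_sd	y_bm	y_bm_sd	y_eth	y_eth_sd	y_ace	y_ace_sd	y_for	y_for_sd	y_lac	y_lac_sd	y_suc	y_suc_sd
HC_ATPase	0.063	0.009	5.13	0.51	2.29	0.51	3.28	0.39	4.69	0.96	2.95	0.13	0.45	0.17	6.99	0.73	0.065	0.015	0.460	0.066	0.650	0.004	0.899	0.087	0.570	0.078	0.083	0.017
HC_ATPase_pfkA	0.134	0.013	7.51	0.47	5.05	0.26	5.56	0.54	9.32	0.84	2.41	0.15	1.17	0.05	9.26	0.23	0.099	0.005	0.667	0.040	0.732	0.030	1.239	0.039	0.320	0.039	0.163	0.003
HC_ATPase_pflB	0.079	0.009	7.59	0.94	5.81	1.02	6.32	0.79	10.88	1.38	1.18	0.22	0.89	0.03	12.67	2.02	0.053	0.009	0.690	0.101	0.794	0.025	1.387	0.016	0.147	0.062	0.113	0.011
HC_ATPase_pfkA_pflB	0.098	0.006	7.87	0.32	6.26	0.28	6.84	0.29	11.44	0.33	1.01	0.55	1.07	0.08	12.97	0.39	0.068	0.004	0.761	0.026	0.854	0.057	1.434	0.057	0.128	0.070	0.131	0.002
HC_ATPase_pgk	0.074	0.003	4.92	0.67	2.12	0.21	3.36	0.35	5.38	0.32	2.33	0.22	0.80	0.04	5.47	0.34	0.075	0.005	0.407	0.067	0.663	0.105	1.078	0.170	0.592	0.084	0.163	0.033
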