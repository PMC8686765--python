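strain	mu	mu_sd	r_glc	r_glc_sd	r_eth	r_eth_sd	r_ace	r_ace_sd	r_for	r_for_sd	r_lac	r_lac_sd	r_suc	r_suc_sd	r_atpm	r_atpm_sd	y_bm	y_bm_sd	y_eth	y_eth_sd	y_ace	y_ace_sd	y_for	y_for_sd	y_lac	y_lac_sd	y_suc	y_suc_sd
WT	0.476	0.004	13.48	0.04	10.81	0.14	11.90	0.19	21.88	0.37	0.83	0.05	1.77	0.02	4.41	0.54	0.155	0.005	0.696	0.024	0.753	0.016	1.299	0.031	0.184	0.004	0.125	0.007
WT_IPTG	0.449	0.007	12.78	0.48	9.99	0.15	10.73	0.30	19.54	0.26	0.67	0.05	1.72	0.02	3.27	0.31	0.160	0.001	0.716	0.008	0.774	0.007	1.309	0.010	0.166	0.003	0.130	0.005
LC_control	0.458	0.004	14.05	0.42	10.38	0.24	10.74	0.23	20.78	1.07	0.89	0.07	1.73	0.10	3.30	0.43	0.149	0.002	0.678	0.009	0.665	0.008	1.280	0.014	0.177	0.005	0.118	0.001
LC_ATPase	0.376	0.007	16.38	0.56	13.23	0.33	13.23	0.22	26.99	0.86	1.30	0.11	1.80	0.07	14.63	1.04	0.104	0.003	0.770	0.007	0.790	0.006	1.542	0.010	0.161	0.005	0.106	0.003
MC_control	0.461	0.002	15.02	0.15	10.51	0.19	10.93	0.37	21.21	0.30	0.98	0.07	1.85	0.05	3.61	0.82	0.146	0.001	0.668	0.015	0.666	0.010	1.251	0.019	0.184	0.003	0.124	0.001
MC_ATPase	0.197	0.003	17.70	0.47	15.63	0.94	14.90	0.59	30.24	0.25	0.84	0.34	1.66	0.08	29.06	0.67	0.050	0.000	0.857	0.022	0.840	0.029	1.572	0.013	0.143	0.001	0.085	0.001
HC_control	0.431	0.004	12.93	1.11	9.84	0.52	9.89	0.24	20.46	0.66	0.83	0.09	1.65	0.09	2.67	1.05	0.136	0.002	0.655	0.013	0.645	0.010	1.268	0.013	0.246	0.000	0.125	0.002
HC_ATPase	0.063	0.009	5.13	0.51	2.29	0.51	3.28	0.39	4.69	0.96	2.95	0.13	0.45	0.17	6.99	0.73	0.065	0.015	0.460	0.066	0.650	0.004	0.899	0.087	0.570	0.078	0.083	0.017
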