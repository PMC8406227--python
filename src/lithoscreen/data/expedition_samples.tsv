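sample_id	lithology	depth_mbsf	cell_density	pcr	seq	pfc_interior	pfc_exterior
68B-1R1-1.44	Rubble: Metagabbro, with talc-amph overprinting	1.44	158	+	+	9e4	ADL
68B-3R1-3.77	Metasomatized serpentinite (top 10 to 13 cm, possibly gabbroic domains)	3.77	13	+	-	1e5	1e5
68B-3R1-3.80	Serpentinized harzburgite	3.80	61	+	+	5e3	2e5
68B-7R1-7.73	Mixed rubble: serpentinized harzburgite, talc-amph-chlorite schist	7.73	BMQL (4.4)	+	+	1e5	3e5
68B-8R1-9.02	Rubble: serpentinized harzburgite, talc-amph-chlorite schist	9.02	BMQL (4.4)	-	n.a.	1e4	4e5
69A-4R1-5.41	Foraminiferal carbonate sand	5.41	16000	+	+	BDL	BDL
69A-4R1-5.91	Foraminiferal carbonate sand with basalt fragments	5.91	5010	+	+	BDL	2e2
69A-5R1-8.17	Metadolerite with carbonate veins	8.17	9	n.c.	n.a.	BDL	BDL
69A-7R1-11.05	Metadolerite rubble	11.05	5-16	n.c.	n.a.	2e2	BDL
69A-9R2-14.61	Serpentinized dunite with carbonate veins	14.61	10-24	+	+	3e2	BDL-2e2
70C-1R1-0.59	Carbonate-hosted basalt breccia	0.59	29	-	n.a.	6e2	3e4
70C-3R1-3.55	Carbonate-hosted basalt breccia	3.55	88	+	+	1e5	1e6
71A-1R2-0.58	Serpentinized dunite, oxidized and with carbonate veins	0.58	405	-	n.a.	BDL	7e4
71B-2R1-2.33	Metagabbro (chloride-rich)	2.33	38	n.c.	n.a.	BDL	BDL
71C-2R1-3.51	Serpentinized harzburgite	3.51	n.d.	-	n.a.	BDL	1e5
71C-3R1-5.1	Serpentinized harzburgite	5.1	n.d.	-	n.a.	BDL	6e4
71C-6R1-10.25	Metadolerite	10.25	n.d.	n.c.	n.a.	BDL	2e4
72A-1R1-0.53	Rubble: basalt-breccia; carbonate matrix	0.53	18-499	n.c.	n.a.	BDL	BDL
72B-1R1-0.62	Rubble: basalt-breccia; carbonate matrix	0.62	241	n.c.	n.a.	1	1e1
72B-3R1-3.78	Rubble of metabasalt, metagabbro, and serpentinized harzburgite	3.78	n.d.	n.c.	n.a.	1e0	BDL
72B-5R1-6.50	Talc-amphibole-chlorite schist	6.50	13	n.c.	n.a.	1e0	6e0
72B-7R1-10.08	Metagabbro	10.08	4	n.c.	n.a.	BDL	n.d.
74A-1R1-0.1	Carbonate sand (highly disturbed during core recovery)	0.1	22400	-	n.a.	n.a.	BDL
74A-1R1-0.5	Carbonate sand (highly disturbed during core recovery)	0.5	4430	+	+	n.a.	6e2
75B-2R1-2.95	Rubble: metadolerite	2.95	148	-	n.a.	2e3	n.d.
76B-3R1-4.46	Metadolerite	4.46	29	-	n.a.	1e3	BDL
76B-5R1-7.08	Serpentinized harzburgite with talc-amph-chlorite alteration	7.08	BMQL (4.8)	-	n.a.	BDL	3e1
76B-7R1-10.76	Serpentinized harzburgite	10.76	BMQL (4.4)	n.c.	n.a.	BDL	2e3
76B-9R1-13.21	Serpentinized harzburgite with talc-amph-chlorite alteration and carbonate veins	13.21	44	n.c.	n.a.	1e2	8e1
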