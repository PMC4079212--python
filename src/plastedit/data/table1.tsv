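# Per-gene editing counts for the 14 plastid minicircle genes, transcribed
# from the source study's per-gene table.
# Columns A/G..A/U are counts per editing type (DNA base / RNA base, RNA
# notation).  types_consistent=0 flags the one row (16S rRNA) whose printed
# per-type digit run cannot be resolved to counts summing to the row total;
# that row stores NA per-type counts and only the total is used downstream.
# identity_* are percent amino-acid identities of the pre-/post-editing
# conceptual translation to the Heterocapsa triquetra homolog.
gene	molecule_class	minicircle_kb	cds_length_nt	n_edits	printed_frequency_pct	A/G	G/A	C/U	U/C	G/C	G/U	U/G	A/C	A/U	types_consistent	n_aa_substitutions	protein_length_aa	printed_aa_pct	n_stop_restorations	identity_pre_pct	identity_post_pct	start_override
psbA	protein_coding	2.4	1029	4	0.4	2	1	0	0	1	0	0	0	0	1	3	343	0.9	0	86	86	NA
psbB	protein_coding	2.5	1500	30	2.0	18	3	4	5	0	0	0	0	0	1	28	500	5.6	0	68	72	NA
psbC	protein_coding	2.5	1359	25	2.4	15	0	4	2	3	0	0	1	0	1	22	453	4.9	0	73	76	NA
psbD	protein_coding	2.2	1074	8	0.7	3	0	0	3	1	0	1	0	0	1	7	358	2.0	0	88	88	NA
psbE	protein_coding	1.8	234	9	3.8	4	0	1	0	2	1	0	1	0	1	8	78	10.3	0	67	71	NA
psbI	protein_coding	2.1	108	3	2.8	0	0	1	1	0	1	0	0	0	1	3	36	8.3	0	45	45	TTG
petB	protein_coding	2.3	657	23	3.5	5	1	2	6	9	0	0	0	0	1	22	219	10.0	1	67	72	NA
petD	protein_coding	2.2	477	33	6.9	12	4	2	6	8	0	0	1	0	1	28	159	17.6	1	51	54	ATA
psaA	protein_coding	3.3	2022	100	4.9	52	8	20	13	2	0	0	5	0	1	84	674	12.5	0	56	60	NA
psaB	protein_coding	3.2	2103	85	4.0	53	5	15	6	4	0	0	1	1	1	78	701	11.1	0	54	57	TTT
atpA	protein_coding	2.4	1434	43	3.0	28	3	5	6	1	0	0	0	0	1	37	478	7.7	0	67	70	NA
atpB	protein_coding	3.0	1971	50	2.5	29	3	5	10	2	0	0	1	0	1	44	657	6.7	0	51	53	NA
rrn16S	rRNA	2.35	794	22	2.8	NA	NA	NA	NA	NA	NA	NA	NA	NA	0	NA	NA	NA	0	NA	NA	NA
rrn23S	rRNA	2.5	1138	36	3.2	26	0	7	0	1	2	0	0	0	1	NA	NA	NA	0	NA	NA	NA
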