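# Core circadian clock and light signaling seed panel (Arabidopsis thaliana,
# Araport11 gene IDs). Columns: family_label, seed_gene_id, seed_source_species.
# Seed protein sequences are pulled from the loaded arabidopsis proteome at run
# time; this file ships only the curated family -> locus mapping.
LHY/CCA1	AT2G46830	arabidopsis
LHY/CCA1	AT1G01060	arabidopsis
RVE4/8	AT5G02840	arabidopsis
RVE4/8	AT3G09600	arabidopsis
PRR5/9	AT5G24470	arabidopsis
PRR5/9	AT2G46790	arabidopsis
PRR3/7	AT5G60100	arabidopsis
PRR3/7	AT5G02810	arabidopsis
PRR1	AT5G61380	arabidopsis
PIF3	AT1G09530	arabidopsis
PHYA	AT1G09570	arabidopsis
PHYB	AT2G18790	arabidopsis
LKP2	AT2G18915	arabidopsis
ZTL	AT5G57360	arabidopsis
SRR1	AT5G59560	arabidopsis
BOA	AT5G59570	arabidopsis
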