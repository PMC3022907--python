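# Curated catalog of the 45 rice (Oryza sativa) CESA/CSL superfamily gene models.
# Columns: gene name, family, TIGR locus identifier, Affymetrix probe set id(s)
# (semicolon-joined, empty when no probe maps to the gene), and whether a
# full-length KOME cDNA supports the model.
gene	family	locus	probe_ids	has_cdna
OsCESA1	CESA	LOC_Os05g08370	Os.10183.1.S2_at	true
OsCESA2	CESA	LOC_Os03g59340	Os.14979.1.S1_at	true
OsCESA3	CESA	LOC_Os07g24190	Os.10178.2.S1_a_at	true
OsCESA4	CESA	LOC_Os01g54620	Os.18724.2.S1_x_at	true
OsCESA5	CESA	LOC_Os03g62090	Os.4857.1.S1_at	true
OsCESA6	CESA	LOC_Os07g14850	Os.10926.1.S1_at	true
OsCESA7	CESA	LOC_Os10g32980	Os.3206.1.S1_at	true
OsCESA8	CESA	LOC_Os07g10770	Os.10176.1.S1_at	true
OsCESA9	CESA	LOC_Os09g25490	Os.10206.1.S1_at	true
OsCESA10	CESA	LOC_Os12g29300		false
OsCESA11	CESA	LOC_Os06g39970	OsAffx.15853.1.S1_at	false
OsCSLA1	CSLA	LOC_Os02g09930	Os.24972.1.S1_at	true
OsCSLA2	CSLA	LOC_Os10g26630	Os.15231.1.S1_at	false
OsCSLA3	CSLA	LOC_Os06g12460	OsAffx.15389.1.S1_at	false
OsCSLA4	CSLA	LOC_Os03g07350	OsAffx.12764.2.S1_x_at	false
OsCSLA5	CSLA	LOC_Os03g26044	Os.56873.1.S1_at	true
OsCSLA6	CSLA	LOC_Os02g51060	Os.6170.1.S1_at	true
OsCSLA7	CSLA	LOC_Os07g43710	Os.8080.1.S1_at;Os.8080.2.S1_x_at	true
OsCSLA9	CSLA	LOC_Os06g42020	Os.48268.1.S1_at	true
OsCSLA11	CSLA	LOC_Os08g33740	OsAffx.6015.1.S1_at	false
OsCSLC1	CSLC	LOC_Os01g56130	Os.29016.1.S1_at	true
OsCSLC2	CSLC	LOC_Os09g25900	Os.18770.1.S1_at	false
OsCSLC3	CSLC	LOC_Os08g15420	Os.55417.1.S1_at	true
OsCSLC7	CSLC	LOC_Os05g43530	Os.15705.1.S1_x_at	true
OsCSLC9	CSLC	LOC_Os03g56060	Os.10855.1.S1_at	true
OsCSLC10	CSLC	LOC_Os07g03260	OsAffx.28245.1.S1_at	false
OsCSLD1	CSLD	LOC_Os10g42750	Os.46811.1.S1_at	true
OsCSLD2	CSLD	LOC_Os06g02180	Os.25614.1.S1_at	true
OsCSLD3	CSLD	LOC_Os08g25710	OsAffx.17155.1.S1_x_at	false
OsCSLD4	CSLD	LOC_Os12g36890	Os.57510.1.S1_x_at;Os.57510.1.A1_at	true
OsCSLD5	CSLD	LOC_Os06g22980	Os.53359.1.S1_at	true
OsCSLE1	CSLE	LOC_Os09g30120	Os.6165.1.S1_a_at	true
OsCSLE2	CSLE	LOC_Os02g49332	Os.20406.3.S1_x_at;Os.20406.1.S1_a_at	true
OsCSLE6	CSLE	LOC_Os09g30130		true
OsCSLF1	CSLF	LOC_Os07g36700		false
OsCSLF2	CSLF	LOC_Os07g36690	Os.15704.1.S1_at	true
OsCSLF3	CSLF	LOC_Os07g36750	OsAffx.5550.1.S1_at	false
OsCSLF4	CSLF	LOC_Os07g36740		false
OsCSLF6	CSLF	LOC_Os08g06380	Os.9709.1.A1_at;Os.9709.2.S1_at	true
OsCSLF7	CSLF	LOC_Os10g20260	Os.46814.1.S1_at	true
OsCSLF8	CSLF	LOC_Os07g36630	Os.52482.1.S1_at	true
OsCSLF9	CSLF	LOC_Os07g36610	OsAffx.16586.1.S1_x_at	true
OsCSLH1	CSLH	LOC_Os10g20090	Os.11623.1.S1_a_at	true
OsCSLH2	CSLH	LOC_Os04g35020	Os.45970.1.S1_at	false
OsCSLH3	CSLH	LOC_Os04g35030	Os.26822.1.S1_at	false
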