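gene_id	gene_name	newer_product	older_product	newer_stratum	older_stratum	previously_known	comment
ENSMUSG00000029642	Polr1d	ENSMUSP00000106186	ENSMUSP00000058355	5	2	0	Same start as main gene, but acquired additional exons
ENSMUSG00000030970	Ctbp2	ENSMUSP00000127123	ENSMUSP00000033269	12	1	0	Same start as main gene, but acquired an additional internal exon
ENSMUSG00000035504	Reep6	ENSMUSP00000100994	ENSMUSP00000100995	17	2	0	New initiation codon creates second reading frame
ENSMUSG00000089756	Gm8898	ENSMUSP00000104646	ENSMUSP00000104577	18	2	0	Same start, but new splice variant; paralog of Gm4723
ENSMUSG00000078898	Gm4723	ENSMUSP00000104676	ENSMUSP00000104675	18	2	0	Same start, but new splice variant; paralog of Gm8898
ENSMUSG00000038227	Hoxa9	ENSMUSP00000133896	ENSMUSP00000046939	18	2	0	New starting exon initiates a separate reading frame
ENSMUSG00000067786	Nnat	ENSMUSP00000134415	ENSMUSP00000085836	18	16	0	Same start, alternative splicing leads to new reading frames
ENSMUSG00000044405	Adig	ENSMUSP00000105110	ENSMUSP00000051732	20	16	0	Same start as main gene, but acquired an additional internal exon
ENSMUSG00000025144	Stra13	ENSMUSP00000101761	ENSMUSP00000026137	20	2	0	Gain of alternative second exon induces a shift from the older frame
ENSMUSG00000033720	Sfxn5	ENSMUSP00000109417	ENSMUSP00000041872	20	2	0	Alternative first exon and last exons, common second exon
ENSMUSG00000063235	Ptpmt1	ENSMUSP00000107087	ENSMUSP00000077036	20	1	0	Alternative transcription start site and start codon
ENSMUSG00000044303	Cdkn2a	ENSMUSP00000030237	ENSMUSP00000061847	16	1	1	New starting exon initiates a separate reading frame. Also known as Arf, Pctr1, MTS1, Ink4a
ENSMUSG00000027523	Gnas	ENSMUSP00000104716	ENSMUSP00000085184	18	2	1	New initiation codon creates second reading frame. Also known as Nesp, GPSA
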