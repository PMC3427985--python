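# Published benchmark: ten experimentally validated Arabidopsis proteins
# carrying non-canonical PTS1 tripeptides, with the total prediction score,
# peroxisomal targeting probability and decision printed by the published
# plant PTS1 server.  Scores/probabilities are fixture INPUTS here: the
# server's trained matrix weights were never published, so these numbers
# are not recomputable from scratch.
# experimental: PTD = peroxisome targeting demonstrated (reporter fusion),
# FLP = demonstrated for the full-length protein.
agi	acronym	cterm14	experimental	score	probability	decision
At1g51745.1/2	Tudor	EARSRQQRRQRKRL	PTD	0.615	0.990	peroxisomal
At3g01980.1/3/4	SDRc	GAQSLTRPRLKSYM	PTD/FLP	0.610	0.989	peroxisomal
At4g16340.1	SPK1	AELSHYIPAILSEL	PTD	0.567	0.973	peroxisomal
At1g43770.2	PHD	YLWGVFKPRQTSRY	PTD	0.499	0.891	peroxisomal
At3g44830.1	LCAT	SDVMRMSERISIKL	PTD	0.438	0.657	peroxisomal
At5g28360.1	ACS31	YREKENYLRLVSPL	PTD	0.426	0.582	peroxisomal
At5g20070.1	NUDT19	VHSKQQAGVSLSSL	FLP	0.385	0.328	non-peroxisomal
At5g04870.1	CPK1	KMGLEKSFSIALKL	PTD	0.321	0.080	non-peroxisomal
At1g49350.1	pxPfkB	YNGAKMLMVHQSML	FLP	0.298	0.044	non-peroxisomal
At2g01880.1	PAP7	VLHRSSLSKRSAHL	PTD	0.130	0.000	non-peroxisomal
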