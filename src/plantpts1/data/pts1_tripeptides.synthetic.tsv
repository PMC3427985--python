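# Synthetic reconstruction of a validated plant PTS1 tripeptide registry.
# Assembled from tripeptides individually reported as experimentally
# validated in the plant PTS1 literature (fluorescent-reporter targeting
# assays); NOT the frequently updated list of the original web server.
tripeptide	validated	canonical	evidence	species
SKL	true	true	prototypical PTS1; reporter targeting in plants	Arabidopsis thaliana
SRM	true	true	reporter targeting assay	Arabidopsis thaliana
SKI	true	true	reporter targeting assay	Arabidopsis thaliana
AKL	true	true	reporter targeting assay	Arabidopsis thaliana
SKV	true	false	reporter targeting assay (ortholog set)	spermatophytes
VKL	true	false	reporter targeting assay (ortholog set)	spermatophytes
IKL	true	false	C-terminal 10 aa of LCAT (At3g44830.1) target reporter to peroxisomes	Arabidopsis thaliana
QRL	true	false	C-terminal 10 aa of At1g18700.2 target reporter to peroxisomes in onion epidermal cells	Arabidopsis thaliana
KRL	true	false	Tudor (At1g51745) validated peroxisomal	Arabidopsis thaliana
SYM	true	false	SDRc (At3g01980) validated peroxisomal	Arabidopsis thaliana
SEL	true	false	SPK1 (At4g16340.1) validated peroxisomal	Arabidopsis thaliana
SRY	true	false	PHD (At1g43770.2) validated peroxisomal	Arabidopsis thaliana
SPL	true	false	ACS31 (At5g28360.1) validated peroxisomal	Arabidopsis thaliana
SSL	true	false	NUDT19 (At5g20070.1) validated (full-length protein)	Arabidopsis thaliana
LKL	true	false	CPK1 (At5g04870.1) validated peroxisomal	Arabidopsis thaliana
SML	true	false	pxPfkB (At1g49350.1) validated (full-length protein)	Arabidopsis thaliana
AHL	true	false	PAP7 (At2g01880.1) validated peroxisomal	Arabidopsis thaliana
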