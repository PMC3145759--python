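# Pairwise native-contact weight table for sequence flavoring (20x20, symmetric, positive).
# SYNTHETIC RECONSTRUCTION: built as the outer product w_ij = q_i * q_j of the Miyazawa
# per-residue contact-energy (hydrophobicity) scale, Macromolecules 18:534-552 (1985),
# values as distributed in Biopython's Bio.SeqUtils.ProtParamData. This one-parameter
# factorization is a standard approximation to full pairwise contact statistical
# potentials. Only relative magnitudes matter: the builder normalizes the mean
# side-chain well depth to a configurable baseline before global thermal calibration.
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	28.4089	42.2669	19.1347	19.4545	48.1299	23.8784	27.1830	47.0639	15.7235	45.1451	47.7035	19.7743	20.6271	20.6271	22.2794	21.7997	23.9317	40.6679	40.8278	31.3937
C	42.2669	62.8849	28.4687	28.9445	71.6079	35.5264	40.4430	70.0219	23.3935	67.1671	70.9735	29.4203	30.6891	30.6891	33.1474	32.4337	35.6057	60.5059	60.7438	46.7077
D	19.1347	28.4687	12.8881	13.1035	32.4177	16.0832	18.3090	31.6997	10.5905	30.4073	32.1305	13.3189	13.8933	13.8933	15.0062	14.6831	16.1191	27.3917	27.4994	21.1451
E	19.4545	28.9445	13.1035	13.3225	32.9595	16.3520	18.6150	32.2295	10.7675	30.9155	32.6675	13.5415	14.1255	14.1255	15.2570	14.9285	16.3885	27.8495	27.9590	21.4985
F	48.1299	71.6079	32.4177	32.9595	81.5409	40.4544	46.0530	79.7349	26.6385	76.4841	80.8185	33.5013	34.9461	34.9461	37.7454	36.9327	40.5447	68.8989	69.1698	53.1867
G	23.8784	35.5264	16.0832	16.3520	40.4544	20.0704	22.8480	39.5584	13.2160	37.9456	40.0960	16.6208	17.3376	17.3376	18.7264	18.3232	20.1152	34.1824	34.3168	26.3872
H	27.1830	40.4430	18.3090	18.6150	46.0530	22.8480	26.0100	45.0330	15.0450	43.1970	45.6450	18.9210	19.7370	19.7370	21.3180	20.8590	22.8990	38.9130	39.0660	30.0390
I	47.0639	70.0219	31.6997	32.2295	79.7349	39.5584	45.0330	77.9689	26.0485	74.7901	79.0285	32.7593	34.1721	34.1721	36.9094	36.1147	39.6467	67.3729	67.6378	52.0087
K	15.7235	23.3935	10.5905	10.7675	26.6385	13.2160	15.0450	26.0485	8.7025	24.9865	26.4025	10.9445	11.4165	11.4165	12.3310	12.0655	13.2455	22.5085	22.5970	17.3755
L	45.1451	67.1671	30.4073	30.9155	76.4841	37.9456	43.1970	74.7901	24.9865	71.7409	75.8065	31.4237	32.7789	32.7789	35.4046	34.6423	38.0303	64.6261	64.8802	49.8883
M	47.7035	70.9735	32.1305	32.6675	80.8185	40.0960	45.6450	79.0285	26.4025	75.8065	80.1025	33.2045	34.6365	34.6365	37.4110	36.6055	40.1855	68.2885	68.5570	52.7155
N	19.7743	29.4203	13.3189	13.5415	33.5013	16.6208	18.9210	32.7593	10.9445	31.4237	33.2045	13.7641	14.3577	14.3577	15.5078	15.1739	16.6579	28.3073	28.4186	21.8519
P	20.6271	30.6891	13.8933	14.1255	34.9461	17.3376	19.7370	34.1721	11.4165	32.7789	34.6365	14.3577	14.9769	14.9769	16.1766	15.8283	17.3763	29.5281	29.6442	22.7943
Q	20.6271	30.6891	13.8933	14.1255	34.9461	17.3376	19.7370	34.1721	11.4165	32.7789	34.6365	14.3577	14.9769	14.9769	16.1766	15.8283	17.3763	29.5281	29.6442	22.7943
R	22.2794	33.1474	15.0062	15.2570	37.7454	18.7264	21.3180	36.9094	12.3310	35.4046	37.4110	15.5078	16.1766	16.1766	17.4724	17.0962	18.7682	31.8934	32.0188	24.6202
S	21.7997	32.4337	14.6831	14.9285	36.9327	18.3232	20.8590	36.1147	12.0655	34.6423	36.6055	15.1739	15.8283	15.8283	17.0962	16.7281	18.3641	31.2067	31.3294	24.0901
T	23.9317	35.6057	16.1191	16.3885	40.5447	20.1152	22.8990	39.6467	13.2455	38.0303	40.1855	16.6579	17.3763	17.3763	18.7682	18.3641	20.1601	34.2587	34.3934	26.4461
V	40.6679	60.5059	27.3917	27.8495	68.8989	34.1824	38.9130	67.3729	22.5085	64.6261	68.2885	28.3073	29.5281	29.5281	31.8934	31.2067	34.2587	58.2169	58.4458	44.9407
W	40.8278	60.7438	27.4994	27.9590	69.1698	34.3168	39.0660	67.6378	22.5970	64.8802	68.5570	28.4186	29.6442	29.6442	32.0188	31.3294	34.3934	58.4458	58.6756	45.1174
Y	31.3937	46.7077	21.1451	21.4985	53.1867	26.3872	30.0390	52.0087	17.3755	49.8883	52.7155	21.8519	22.7943	22.7943	24.6202	24.0901	26.4461	44.9407	45.1174	34.6921
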