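label	INLV1	BARV-1	HVLV-4	WHCV-1	WhIV-8	MaV	LORV	BCPV	BARV-2	BARV-3	BARV-4	AGV-3	HGSV-2	CiLV-C2	CiLV-C	SVD1	TANAV	BUSV
INLV1	*	77.2	76.3	50.5	47.0	46.1	46.9	46.0	31.4	32.9	32.9	31.5	37.4	32.7	33.6	32.5	30.4	30.0
BARV-1	69.2	*	77.6	52.6	50.5	48.3	43.8	46.8	32.2	32.8	32.0	33.0	36.5	36.4	34.5	33.8	33.1	31.7
HVLV-4	69.0	70.8	*	51.3	49.2	46.3	43.6	44.7	32.5	33.0	33.7	32.8	36.9	34.8	35.0	33.1	33.1	31.5
WHCV-1	57.2	57.2	56.6	*	66.0	54.1	49.1	53.0	34.3	37.3	35.4	35.5	39.4	35.4	35.3	36.2	33.6	34.2
WhIV-8	53.1	54.1	54.1	62.3	*	54.3	49.3	51.8	33.1	36.1	34.2	32.2	39.7	33.1	35.9	34.2	32.7	33.0
MaV	50.1	54.7	50.0	55.9	56.7	*	61.2	69.1	28.4	31.5	29.8	31.6	35.3	33.1	35.5	33.3	32.8	32.6
LORV	53.3	50.3	51.2	54.6	55.9	61.1	*	63.4	29.5	30.3	30.3	30.8	36.7	36.1	37.3	32.5	31.0	29.6
BCPV	49.5	52.3	51.2	56.0	54.4	64.2	60.7	*	30.0	31.5	32.0	32.0	36.0	37.0	37.6	32.8	32.3	30.3
BARV-2	50.0	46.1	47.8	48.2	45.1	43.0	45.0	43.2	*	79.5	79.2	53.0	31.2	28.6	28.8	25.4	25.4	24.5
BARV-3	50.3	45.7	47.2	50.5	47.6	44.2	43.7	43.5	72.8	*	83.1	55.1	33.0	29.9	30.1	26.3	27.1	26.6
BARV-4	49.7	46.4	48.1	48.3	46.4	43.7	43.2	45.2	73.1	74.0	*	55.1	32.3	30.1	30.3	26.1	27.1	25.9
AGV-3	47.5	44.3	44.2	47.4	44.6	42.1	43.5	41.6	62.2	60.9	59.7	*	34.6	34.0	34.2	26.6	26.3	26.7
HGSV-2	47.7	44.7	45.3	48.1	49.9	46.1	48.0	47.1	47.0	44.7	46.4	46.4	*	51.7	50.6	30.0	30.3	28.3
CiLV-C2	45.5	45.2	46.1	48.8	46.7	46.6	49.5	47.6	43.9	44.1	45.0	45.2	55.8	*	77.1	27.6	28.1	25.5
CiLV-C	45.9	44.6	45.1	48.2	46.9	48.1	49.5	45.9	44.9	46.5	43.8	44.9	57.3	68.8	*	29.6	26.6	24.9
SVD1	48.7	47.6	47.3	50.3	47.6	46.9	45.8	45.4	42.0	43.7	42.1	41.4	45.1	44.4	43.5	*	60.1	59.4
TANAV	43.8	45.3	45.7	45.4	46.3	44.5	44.0	44.1	41.2	41.7	40.9	40.9	45.2	44.2	40.8	61.7	*	66.9
BUSV	45.9	43.8	46.8	46.1	46.2	44.0	44.9	44.6	41.9	41.9	41.2	39.6	43.3	43.2	40.4	62.6	63.8	*
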