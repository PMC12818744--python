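# Synthetic reconstruction of the published 129-motif enriched set.
# Motifs named in the source study's prose are included verbatim; the
# remainder are constructed so the set's aggregate statistics (length
# distribution, residue membership, embedded fraction) match the
# published values. Not the original supplementary table.
motif	length
GGDR	4
SRGG	4
QQQQ	4
QQQQQ	5
GRGG	4
GGRGG	5
QQQ	3
QQQQQQ	6
PPPP	4
PPPPP	5
PPPPPP	6
GGGGG	5
GGGGGG	6
QQQP	4
SGGGG	5
HQQQ	4
GGGR	4
RGGF	4
GGRS	4
GRGGY	5
GGGRGG	6
DRGG	4
GDRG	4
GGDRGG	6
GDRGG	5
GGDRG	5
DDED	4
DEDD	4
SSDS	4
RGGRGG	6
RGGFG	5
GGYG	4
GGYGG	5
GGGYGG	6
GAPG	4
DSSS	4
SSAP	4
GGNG	4
GVPGV	5
YGPG	4
PGQQ	4
QGPG	4
QQGP	4
YSPT	4
SPTSP	5
TSPSY	5
YSPTS	5
PTSPSY	6
SPTSPS	6
YSPTSP	6
VPGVG	5
VPPP	4
PGVG	4
PGVGV	5
YGGG	4
GYGGG	5
GPYG	4
GYGN	4
FGGG	4
GGFGG	5
GGGGF	5
GGGY	4
HHP	3
QPN	3
PAPA	4
AAPA	4
SAPA	4
GPGS	4
QQPP	4
PSGP	4
PPQG	4
PPSS	4
PPPG	4
PPPPQ	5
QQPPP	5
QQQH	4
GGGGS	5
GSGGG	5
RGDA	4
RNGE	4
TRGD	4
QRSE	4
DRQT	4
KRDE	4
HRTD	4
SRDE	4
YRTE	4
GDTE	4
GENT	4
AGED	4
DGKT	4
EGHA	4
NGTD	4
TGEK	4
PTDE	4
PEHD	4
APTE	4
DPNT	4
EPKT	4
SPHD	4
NPEK	4
SPDN	4
YPDQ	4
SYDS	4
SNEQ	4
YSDT	4
GGRSG	5
SRGGS	5
PPQGG	5
GPGSG	5
YGPGS	5
QGPGG	5
PGQQG	5
QQGPP	5
SSDSS	5
GAPGG	5
PSGPS	5
PPSSG	5
QQPPG	5
SAPAS	5
PAPAP	5
GGNGG	5
AAPAG	5
GGRSGG	6
PPQGGG	6
YGPGSG	6
QGPGGY	6
RGGYGG	6
SRGGYG	6
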