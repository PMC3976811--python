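motif_id	width	consensus
motif1	29	ILDDGYRWRKYGQKVIKGNPYPRSYYRCT
motif2	29	PGCPVKKHVERSAEDPSMVITTYEGEHNH
motif3	21	WRKYGQKVVKGSPFPRSYYKC
motif4	21	RSLDGHVTEITYKGxHNCPKP
motif5	15	VREPRVAVQTKSEVD
motif6	28	LVEAMAAALTADPNFTAALAAAISSIIG
motif7	39	EELERLNAENKKLREMLDQMNENYNALQMHLVELMQKQK
motif8	26	PAAMAMASTTSAAASMLLSGSMPSAD
motif9	11	HPNCPAKKKVE
motif10	113	QNLQVQNFQNQNVQQAAPSFSTTPSFNAATPVPPISYRNAIIPLPFNVANPAPNTHFNTSSFGSFLQGINGVDFVQSSRFMANNNQGLLRNNGLLQDMFVPAHMEFGGGGGRR
motif11	24	CSASMATLSASAPFPTITLDLTQS
motif12	42	DITEIISAPTSVTNSPILDLDLLDNVELDSNFPFNTPELFS
motif13	15	KKRKMRVKRTVRVPA
motif14	91	MPPPPPSPPLPPLSPLPLPPFHQQTSSFGSFKDLLTIEDFDPALFDWNPTTTTNTAAAADVTSPPLFTTQISHPVPSPATSNILPEDSFDV
motif15	27	SGGGELDDDEPDAKRWKGEGENDGYSA
motif16	15	LLLNRTGHARFRRAP
motif17	26	MEHLHKWEQKALINELIQGMELARKL
motif18	14	MDDDWDLHAVVRGC
motif19	19	MSVMPEFLQQGLNSSPVNV
motif20	39	QCSGDIEGELTGEAMELGGEKAIESARALLSIGFEIKPC
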