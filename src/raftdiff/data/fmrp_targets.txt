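Actb
Aldoa
Atp1a1
Atp1a3
Atp1b1
Atp5a1
Atp5b
Atp6v0a1
Atp6v0d1
Atp6v1b2
Bsn
Calm1
Camk2a
Camk2b
Ckb
Cltc
Cnp
Dlg4
Dlgap3
Dpysl2
Gnao1
Gnas
Gnaz
Gnb1
Hk1
Iqsec2
Mbp
Myh10
Myo5a
Ncam1
Ncan
Pclo
Plp1
Sept4
Shank3
Snap25
Syngap1
Syt1
Tubb3
Vamp2
Ywhag
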