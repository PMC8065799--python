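# Curated T-cell marker panels (HGNC symbols).
checkpoint:
  - CTLA4
  - ICOS
  - HAVCR2
  - LAG3
  - PDCD1
  - BTLA
Treg:
  - CCR8
  - FOXP3
  - CD40LG
  - IL2RA
  - CCR6
  - CTLA4
  - ICOS
  - IL7R
  - IKZF2
  - PTPRC
  - LAG3
  - ITGAE
Th1:
  - IFNG
  - TBX21
  - IRF8
  - CCL5
  - PRF1
Th2:
  - GATA3
  - IL4
  - IKZF1
Th17:
  - RORC
  - HIF1A
  - IL17F
  - IL17A
  - KLRB1
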