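# SYNTHETIC demonstration clone set (20 heptapeptides, X = amber-encoded residue).
# Not experimental sequences: constructed to reproduce the reported summary
# statistics of a SIRT2 affinity selection round — 5/20 (25%) carry the
# consensus motif C-T-[V/F]-X-[V/I], 12/20 (60%) carry I/V/L/A at the +1
# position, and the -1/+3 positions are enriched for V/L/F and S/T.
CTVXVST
CTFXIST
CTVXISA
ACTFXVS
CTFXVTT
GLVXLST
ATVXVSS
CSVXSAT
CTAXVST
CTVXGST
WRLXAGT
HNFXLTS
SGVXTNT
CTLXMST
QDLXVPS
EKVXNFT
RVFXGHS
NTVXWGS
GPAXHSS
YLSXVRT
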