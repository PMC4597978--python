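# Baseline cleavage specificity table for the six-enzyme digestion panel.
# One row per enzyme.  side: C = cleave C-terminal to a target residue
# (target sits at P1), N = cleave N-terminal to it (target at P1').
# blocked_when: semicolon-separated context predicates POS=RESIDUES over
# positions P2, P1, P1', P2' around the candidate bond; the bond is left
# intact when any predicate matches.  Edit or replace this file to swap
# in higher-fidelity positional-exception matrices; the active table is
# recorded in run metadata.
enzyme	side	targets	blocked_when
TR	C	KR	P1'=P
CTR	C	FLMWY	P1'=P
PEP	C	FL	P1'=P
TLN	N	AFILMV	P1=P
LysC	C	K
PROK	C	AEFILTVWY
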