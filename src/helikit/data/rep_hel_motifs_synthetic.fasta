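>rep_two_his key=8,10 synthetic reference block: HUH replication-initiator two-His motif
GKNIRFVIHQHDLKTFE
>rep_two_tyr key=5,10 synthetic reference block: two catalytic tyrosines of the Rep domain
SEFLSYVQEMYRKDPTA
>hel_I key= synthetic reference block: SF1 helicase Walker A (motif I)
RNIVMTGPAGTGKSHL
>hel_Ia key= synthetic reference block: SF1 helicase motif Ia
QALRVALSGIAATLLH
>hel_Ib key= synthetic reference block: SF1 helicase motif Ib
PTELNKAFRGLDVVVT
>hel_II key= synthetic reference block: SF1 helicase Walker B (motif II)
FDLVIIDEVSMVSKQL
>hel_III key= synthetic reference block: SF1 helicase motif III
SVLLFGDFLQLPPVVK
>hel_IV key= synthetic reference block: SF1 helicase motif IV
TVMLTKNIDVTLGLCN
>hel_V key= synthetic reference block: SF1 helicase motif V
QFPVRLAWAMTIHKSQ
>hel_VI key= synthetic reference block: SF1 helicase motif VI
GMSGTVVDLQLNVIRM
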