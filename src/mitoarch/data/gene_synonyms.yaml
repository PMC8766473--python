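# Canonical gene symbol -> accepted aliases (case-insensitive).
# Unknown names pass through normalization unchanged (a warning is logged).
atp6: [atpase6, atp-6]
atp8: [atpase8, atp-8]
cob: [cytb, cyt-b, cyb]
cox1: [coi, co1, coxi]
cox2: [coii, co2, coxii]
cox3: [coiii, co3, coxiii]
nad1: [nd1]
nad2: [nd2]
nad3: [nd3]
nad4: [nd4]
nad4l: [nd4l]
nad5: [nd5]
nad6: [nd6]
rrnS: [12s, 12srrna, s-rrna, rrn12, srrna]
rrnL: [16s, 16srrna, l-rrna, rrn16, lrrna]
CR: [d-loop, dloop, control_region, control region, d_loop]
trnL1: [trnl(tag)]
trnL2: [trnl(taa)]
trnS1: [trns(gct)]
trnS2: [trns(tga)]
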