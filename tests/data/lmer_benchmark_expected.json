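{"parameter":["(Intercept)","tertile","sbp_baseline","cognition","ct"],"estimate":[11.573229954049,-0.09155394901651,0.1083517687959,-14.204783078578,0.5132798779215],"se":[14.037121595426,0.2225720473812,0.1077798746796,4.034076007905,0.3450963000334],"df":[9.131460352384,220.211650739381,8.844304729168,18.944547287704,220.170079425683],"t":[0.8244731567916,-0.4113452254842,1.005306130834,-3.521198671206,1.48735259657],"p":[0.4306796807147,0.6812194577317,0.3414596323888,0.002290901045993,0.1383524367755],"tau00":[45.422790347524],"sigma2":[136.889937338301],"reml_criterion":[-915.376504565889]}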