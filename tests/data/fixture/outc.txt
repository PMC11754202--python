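primaryid$outc_cod
10000011$HO
10000011$OT
10000021$LT
10000021$OT
10000031$HO
10000041$DE
10000041$OT
10000061$DE
10000061$OT
10000071$DE
10000071$OT
10000081$DE
10000081$HO
10000091$HO
10000091$LT
10000111$OT
10000121$OT
10000161$DE
10000171$OT
10000181$HO
10000181$OT
10000191$HO
10000211$LT
10000211$OT
10000221$OT
10000261$DE
10000261$HO
10000261$OT
10000271$DE
10000281$HO
10000282$HO
10000301$OT
10000311$DS
10000321$HO
10000331$DE
10000331$HO
10000361$OT
10000371$HO
10000391$HO
10000391$OT
10000401$DE
10000401$OT
10000411$DS
10000412$DS
10000421$OT
10000441$DE
10000441$OT
10000442$DE
10000442$OT
10000451$DE
10000451$OT
10000461$DE
10000461$OT
10000471$DS
10000491$OT
10000501$OT
10000511$DE
10000511$OT
10000531$DE
10000531$HO
10000531$LT
10000541$HO
10000551$DE
10000551$OT
10000571$DE
10000571$OT
10000581$OT
10000591$DE
10000591$OT
10000601$HO
10000601$OT
10000602$HO
10000602$OT
10000611$DE
10000611$OT
10000612$DE
10000612$OT
10000631$OT
10000651$DE
10000651$HO
10000652$DE
10000652$HO
10000661$HO
10000671$OT
10000691$DE
10000691$HO
10000691$OT
10000701$OT
10000721$DE
10000751$HO
10000761$HO
10000762$HO
10000791$DE
10000791$OT
10000801$HO
10000831$DE
10000831$OT
10000841$OT
10000851$HO
10000861$OT
10000871$OT
10000911$HO
10000921$DE
10000921$OT
10000922$DE
10000922$OT
10000931$OT
10000951$OT
10000981$HO
10000991$LT
10001001$HO
10001002$HO
10001011$DE
10001011$HO
10001021$OT
10001041$OT
10001051$DS
10001061$OT
10001091$DE
10001091$OT
10001101$RI
10001102$RI
10001111$DE
10001111$OT
10001121$OT
10001131$HO
10001131$LT
10001131$OT
10001141$DE
10001141$OT
10001151$DE
10001151$HO
10001161$HO
10001171$DS
10001171$HO
10001181$DE
10001181$HO
10001211$DE
10001221$OT
10001241$HO
10001251$HO
10001251$OT
10001261$OT
10001271$OT
10001281$OT
10001301$OT
10001311$DS
10001331$HO
10001331$OT
10001361$DE
10001371$DS
10001391$OT
10001401$OT
10001411$DE
10001411$OT
10001421$OT
10001441$OT
10001461$OT
10001481$DE
10001481$OT
10001511$OT
10001531$DE
10001531$HO
10001531$OT
10001551$DE
10001551$HO
10001561$DE
10001561$HO
10001561$OT
10001571$OT
10001581$OT
10001591$DE
10001611$HO
10001611$OT
10001621$DE
10001621$HO
10001621$OT
10001631$HO
10001631$OT
10001641$HO
10001651$OT
10001661$DE
10001661$OT
10001681$OT
10001691$DE
10001701$DE
10001701$HO
10001701$OT
10001711$OT
10001721$DE
10001731$HO
10001731$OT
10001741$OT
10001781$OT
10001782$OT
10001791$HO
10001791$OT
10001801$HO
10001801$OT
10001841$DE
10001851$DS
10001851$OT
10001871$HO
10001871$OT
10001881$DE
10001881$OT
10001911$OT
10001921$HO
10001921$OT
10001931$DE
10001941$DE
10001941$OT
10001951$HO
10001961$DE
10001961$HO
10001971$OT
10001981$OT
10001991$DE
10001991$OT
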