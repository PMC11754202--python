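primaryid$dsg_drug_seq$start_dt
10000001$1$201903
10000002$1$201903
10000011$1$20230311
10000021$1$20170524
10000031$1$20120805
10000041$1$202203
10000051$1$20210218
10000061$1$20191127
10000071$1$20230519
10000081$1$202308
10000111$1$20210904
10000121$1$20211025
10000141$1$20101209
10000142$1$20101209
10000151$1$20161105
10000161$1$202208
10000171$1$20210120
10000181$1$201707
10000191$1$20200810
10000211$1$20160520
10000221$1$20240916
10000231$1$201802
10000241$1$201606
10000242$1$201606
10000251$1$20190807
10000271$1$20210703
10000281$1$20240822
10000282$1$20240822
10000291$1$202007
10000301$1$20200609
10000311$1$20181228
10000331$1$201706
10000341$1$20090510
10000351$1$20230513
10000361$1$20180112
10000371$1$201911
10000391$1$20230523
10000401$1$20151111
10000421$1$20230204
10000441$1$202410
10000442$1$202410
10000451$1$20160623
10000461$1$20210313
10000471$1$20240923
10000481$1$20190525
10000511$1$202212
10000521$1$20240119
10000531$1$20210717
10000541$1$20240205
10000561$1$20190206
10000571$1$20170311
10000591$1$202312
10000601$1$20200101
10000602$1$20200101
10000611$1$20160626
10000612$1$20160626
10000621$1$20191125
10000631$1$20220204
10000641$1$20240510
10000651$1$20140804
10000652$1$20140804
10000661$1$201412
10000671$1$20180409
10000681$1$201406
10000691$1$20240909
10000701$1$201803
10000721$1$20160612
10000741$1$20240826
10000751$1$201906
10000761$1$20110816
10000762$1$20110816
10000791$1$20240414
10000811$1$20200515
10000831$1$20191217
10000841$1$20140916
10000851$1$20230715
10000861$1$20240703
10000871$1$20150107
10000881$1$20191101
10000901$1$20170925
10000911$1$201202
10000921$1$201606
10000922$1$201606
10000941$1$20121118
10000961$1$201304
10000971$1$20191114
10000981$1$20190923
10001001$1$20150409
10001002$1$20150409
10001011$1$201511
10001021$1$20220723
10001031$1$20210219
10001041$1$20211115
10001051$1$20121018
10001061$1$20160707
10001071$1$20230112
10001081$1$20200810
10001091$1$20200107
10001101$1$20171121
10001102$1$20171121
10001111$1$201610
10001121$1$20240817
10001131$1$20210322
10001141$1$201404
10001151$1$20240115
10001171$1$201702
10001181$1$20180912
10001191$1$202102
10001201$1$20180509
10001211$1$201903
10001241$1$20241124
10001251$1$201808
10001261$1$20180707
10001281$1$20200927
10001301$1$20201212
10001341$1$20160312
10001351$1$20180415
10001361$1$20191228
10001381$1$202208
10001391$1$201708
10001401$1$20171206
10001421$1$20171012
10001431$1$20170424
10001441$1$20200607
10001451$1$20190923
10001461$1$20160717
10001471$1$20160219
10001491$1$201303
10001501$1$20191123
10001511$1$20190312
10001521$1$20190717
10001531$1$20230915
10001551$1$202405
10001561$1$20230308
10001571$1$20161008
10001581$1$20160517
10001591$1$20170227
10001601$1$20181217
10001611$1$20190923
10001621$1$201608
10001631$1$20160705
10001651$1$20210925
10001671$1$20241015
10001681$1$201607
10001691$1$20180925
10001701$1$20240107
10001711$1$202110
10001721$1$20200719
10001731$1$20190611
10001741$1$20130225
10001761$1$202006
10001771$1$20190328
10001801$1$20160221
10001821$1$20190409
10001851$1$202403
10001871$1$20180118
10001881$1$20201203
10001901$1$20210707
10001921$1$20130404
10001941$1$20230828
10001951$1$20191001
10001961$1$20200206
10001991$1$201612
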