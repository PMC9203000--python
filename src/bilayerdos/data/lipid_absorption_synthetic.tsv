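# Absorption coefficient of pure lipid (soybean-oil-like), natural log, 1/mm.
# Synthetic stand-in: reconstructed by monotone-cubic interpolation through
# literature anchor points (van Veen et al. 2005 style).
# Columns: wavelength_nm  mua_lipid_mm-1
650.0	0.0001000
652.0	0.0000974
654.0	0.0000949
656.0	0.0000927
658.0	0.0000906
660.0	0.0000887
662.0	0.0000871
664.0	0.0000856
666.0	0.0000842
668.0	0.0000831
670.0	0.0000821
672.0	0.0000814
674.0	0.0000808
676.0	0.0000803
678.0	0.0000801
680.0	0.0000800
682.0	0.0000801
684.0	0.0000805
686.0	0.0000810
688.0	0.0000818
690.0	0.0000827
692.0	0.0000838
694.0	0.0000851
696.0	0.0000866
698.0	0.0000882
700.0	0.0000900
702.0	0.0000932
704.0	0.0000991
706.0	0.0001072
708.0	0.0001173
710.0	0.0001290
712.0	0.0001419
714.0	0.0001558
716.0	0.0001704
718.0	0.0001852
720.0	0.0002000
722.0	0.0002164
724.0	0.0002358
726.0	0.0002576
728.0	0.0002811
730.0	0.0003056
732.0	0.0003304
734.0	0.0003550
736.0	0.0003785
738.0	0.0004004
740.0	0.0004200
742.0	0.0004366
744.0	0.0004513
746.0	0.0004656
748.0	0.0004812
750.0	0.0005000
752.0	0.0005290
754.0	0.0005678
756.0	0.0006072
758.0	0.0006377
760.0	0.0006500
762.0	0.0006451
764.0	0.0006325
766.0	0.0006154
768.0	0.0005968
770.0	0.0005800
772.0	0.0005638
774.0	0.0005462
776.0	0.0005287
778.0	0.0005128
780.0	0.0005000
782.0	0.0004895
784.0	0.0004798
786.0	0.0004713
788.0	0.0004645
790.0	0.0004600
792.0	0.0004569
794.0	0.0004542
796.0	0.0004520
798.0	0.0004505
800.0	0.0004500
802.0	0.0004531
804.0	0.0004612
806.0	0.0004728
808.0	0.0004863
810.0	0.0005000
812.0	0.0005157
814.0	0.0005352
816.0	0.0005568
818.0	0.0005789
820.0	0.0006000
822.0	0.0006197
824.0	0.0006391
826.0	0.0006587
828.0	0.0006788
830.0	0.0007000
832.0	0.0007218
834.0	0.0007441
836.0	0.0007675
838.0	0.0007926
840.0	0.0008200
842.0	0.0008500
844.0	0.0008825
846.0	0.0009181
848.0	0.0009571
850.0	0.0010000
852.0	0.0010480
854.0	0.0011020
856.0	0.0011620
858.0	0.0012280
860.0	0.0013000
862.0	0.0013780
864.0	0.0014640
866.0	0.0015610
868.0	0.0016720
870.0	0.0018000
872.0	0.0019707
874.0	0.0021912
876.0	0.0024362
878.0	0.0026809
880.0	0.0029000
882.0	0.0030863
884.0	0.0032573
886.0	0.0034251
888.0	0.0036019
890.0	0.0038000
892.0	0.0040219
894.0	0.0042626
896.0	0.0045222
898.0	0.0048012
900.0	0.0051000
902.0	0.0054261
904.0	0.0057838
906.0	0.0061685
908.0	0.0065754
910.0	0.0070000
912.0	0.0074673
914.0	0.0079836
916.0	0.0085164
918.0	0.0090327
920.0	0.0095000
922.0	0.0099740
924.0	0.0104797
926.0	0.0109385
928.0	0.0112715
930.0	0.0114000
932.0	0.0113011
934.0	0.0110394
936.0	0.0106671
938.0	0.0102366
940.0	0.0098000
942.0	0.0092777
944.0	0.0086157
946.0	0.0079048
948.0	0.0072359
950.0	0.0067000
952.0	0.0062739
954.0	0.0058806
956.0	0.0055304
958.0	0.0052335
960.0	0.0050000
962.0	0.0048121
964.0	0.0046462
966.0	0.0045043
968.0	0.0043882
970.0	0.0043000
972.0	0.0042268
974.0	0.0041589
976.0	0.0041026
978.0	0.0040642
980.0	0.0040500
982.0	0.0040627
984.0	0.0040960
986.0	0.0041429
988.0	0.0041966
990.0	0.0042500
992.0	0.0043078
994.0	0.0043763
996.0	0.0044508
998.0	0.0045269
1000.0	0.0046000
1002.0	0.0046731
1004.0	0.0047492
1006.0	0.0048237
1008.0	0.0048922
1010.0	0.0049500
1012.0	0.0049979
1014.0	0.0050406
1016.0	0.0050794
1018.0	0.0051154
1020.0	0.0051500
1022.0	0.0051835
1024.0	0.0052155
1026.0	0.0052457
1028.0	0.0052739
1030.0	0.0053000
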