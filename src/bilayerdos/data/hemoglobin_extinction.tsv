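# Molar (decadic) extinction coefficients of human oxy- and deoxyhemoglobin.
# Source: compiled tabulation of W.B. Gratzer (650-800 nm) and N. Kollias
# (800-1000 nm) data; values above 1000 nm are a smooth extrapolation.
# Columns: wavelength_nm  eps_hbo2_cm-1_M-1  eps_hb_cm-1_M-1
# Units: decadic extinction, 1/(cm*M); convert to natural-log 1/mm per uM
# by multiplying with ln(10)*1e-7.
650.0	368.00	3750.120
652.0	356.80	3642.640
654.0	345.60	3535.160
656.0	335.20	3427.680
658.0	325.60	3320.200
660.0	319.60	3226.560
662.0	314.00	3140.280
664.0	308.40	3053.960
666.0	302.80	2967.680
668.0	298.00	2881.400
670.0	294.00	2795.120
672.0	290.00	2708.840
674.0	285.60	2627.640
676.0	282.00	2554.400
678.0	279.20	2481.160
680.0	277.60	2407.920
682.0	276.00	2334.680
684.0	274.40	2261.480
686.0	272.80	2188.240
688.0	274.40	2115.000
690.0	276.00	2051.960
692.0	277.60	2000.480
694.0	279.20	1949.040
696.0	282.00	1897.560
698.0	286.00	1846.080
700.0	290.00	1794.280
702.0	294.00	1741.000
704.0	298.00	1687.760
706.0	302.80	1634.480
708.0	308.40	1583.520
710.0	314.00	1540.480
712.0	319.60	1497.400
714.0	325.20	1454.360
716.0	332.00	1411.320
718.0	340.00	1368.280
720.0	348.00	1325.880
722.0	356.00	1285.160
724.0	364.00	1244.440
726.0	372.40	1203.680
728.0	381.20	1152.800
730.0	390.00	1102.200
732.0	398.80	1102.200
734.0	407.60	1102.200
736.0	418.80	1101.760
738.0	432.40	1100.480
740.0	446.00	1115.880
742.0	459.60	1161.640
744.0	473.20	1207.400
746.0	487.60	1266.040
748.0	502.80	1333.240
750.0	518.00	1405.240
752.0	533.20	1515.320
754.0	548.40	1541.760
756.0	562.00	1560.480
758.0	574.00	1560.480
760.0	586.00	1548.520
762.0	598.00	1508.440
764.0	610.00	1459.560
766.0	622.80	1410.520
768.0	636.40	1361.320
770.0	650.00	1311.880
772.0	663.60	1262.440
774.0	677.20	1213.000
776.0	689.20	1163.560
778.0	699.60	1114.800
780.0	710.00	1075.440
782.0	720.40	1036.080
784.0	730.80	996.720
786.0	740.00	957.360
788.0	748.00	921.800
790.0	756.00	890.800
792.0	764.00	859.800
794.0	772.00	828.800
796.0	786.40	802.960
798.0	807.20	782.360
800.0	816.00	761.720
802.0	828.00	743.840
804.0	836.00	737.080
806.0	844.00	730.280
808.0	856.00	723.520
810.0	864.00	717.080
812.0	872.00	711.840
814.0	880.00	706.600
816.0	887.20	701.320
818.0	901.60	696.080
820.0	916.00	693.760
822.0	930.40	693.600
824.0	944.80	693.480
826.0	956.40	693.320
828.0	965.20	693.200
830.0	974.00	693.040
832.0	982.80	692.920
834.0	991.60	692.760
836.0	1001.20	692.640
838.0	1011.60	692.480
840.0	1022.00	692.360
842.0	1032.40	692.200
844.0	1042.80	691.960
846.0	1050.00	691.760
848.0	1054.00	691.520
850.0	1058.00	691.320
852.0	1062.00	691.080
854.0	1066.00	690.880
856.0	1072.80	690.640
858.0	1082.40	692.440
860.0	1092.00	694.320
862.0	1101.60	696.200
864.0	1111.20	698.040
866.0	1118.40	699.920
868.0	1123.20	701.800
870.0	1128.00	705.840
872.0	1132.80	709.960
874.0	1137.60	714.080
876.0	1142.80	718.200
878.0	1148.40	722.320
880.0	1154.00	726.440
882.0	1159.60	729.840
884.0	1165.20	733.200
886.0	1170.00	736.600
888.0	1174.00	739.960
890.0	1178.00	743.600
892.0	1182.00	747.240
894.0	1186.00	750.880
896.0	1190.00	754.520
898.0	1194.00	758.160
900.0	1198.00	761.840
902.0	1202.00	765.040
904.0	1206.00	767.440
906.0	1209.20	769.800
908.0	1211.60	772.160
910.0	1214.00	774.560
912.0	1216.40	776.920
914.0	1218.80	778.400
916.0	1220.80	778.040
918.0	1222.40	777.720
920.0	1224.00	777.360
922.0	1225.60	777.040
924.0	1227.20	776.640
926.0	1226.80	772.360
928.0	1224.40	768.080
930.0	1222.00	763.840
932.0	1219.60	752.280
934.0	1217.20	737.560
936.0	1215.60	722.880
938.0	1214.80	708.160
940.0	1214.00	693.440
942.0	1213.20	678.720
944.0	1212.40	660.520
946.0	1210.40	641.080
948.0	1207.20	621.640
950.0	1204.00	602.240
952.0	1200.80	583.400
954.0	1197.60	568.920
956.0	1194.00	554.480
958.0	1190.00	540.040
960.0	1186.00	525.560
962.0	1182.00	511.120
964.0	1178.00	495.360
966.0	1173.20	473.320
968.0	1167.60	451.320
970.0	1162.00	429.320
972.0	1156.40	415.280
974.0	1150.80	402.280
976.0	1144.00	389.288
978.0	1136.00	374.944
980.0	1128.00	359.656
982.0	1120.00	344.372
984.0	1112.00	329.084
986.0	1102.40	313.796
988.0	1091.20	298.508
990.0	1080.00	283.220
992.0	1068.80	267.932
994.0	1057.60	252.648
996.0	1046.40	237.360
998.0	1035.20	222.072
1000.0	1024.00	206.784
1002.0	1012.80	196.158
1004.0	1001.60	187.106
1006.0	990.40	179.189
1008.0	979.20	171.966
1010.0	968.00	165.000
1012.0	956.77	158.178
1014.0	945.50	151.715
1016.0	934.25	145.663
1018.0	923.07	140.074
1020.0	912.00	135.000
1022.0	901.04	130.328
1024.0	890.16	125.944
1026.0	879.36	121.896
1028.0	868.64	118.232
1030.0	858.00	115.000
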