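# Absorption coefficient of pure water, natural log, 1/cm.
# Synthetic stand-in: reconstructed by monotone-cubic interpolation through
# literature anchor points (Hale & Querry 1973 / Kou et al. 1993 style).
# Columns: wavelength_nm  mua_water_cm-1
650.0	0.003200
652.0	0.003268
654.0	0.003343
656.0	0.003424
658.0	0.003510
660.0	0.003600
662.0	0.003700
664.0	0.003810
666.0	0.003925
668.0	0.004041
670.0	0.004150
672.0	0.004250
674.0	0.004345
676.0	0.004440
678.0	0.004540
680.0	0.004650
682.0	0.004776
684.0	0.004916
686.0	0.005063
688.0	0.005210
690.0	0.005350
692.0	0.005476
694.0	0.005592
696.0	0.005710
698.0	0.005842
700.0	0.006000
702.0	0.006193
704.0	0.006422
706.0	0.006690
708.0	0.006998
710.0	0.007350
712.0	0.007773
714.0	0.008293
716.0	0.008905
718.0	0.009609
720.0	0.010400
722.0	0.011419
724.0	0.012721
726.0	0.014172
728.0	0.015643
730.0	0.017000
732.0	0.018301
734.0	0.019633
736.0	0.020915
738.0	0.022065
740.0	0.023000
742.0	0.023749
744.0	0.024407
746.0	0.024990
748.0	0.025515
750.0	0.026000
752.0	0.026489
754.0	0.026891
756.0	0.027063
758.0	0.027162
760.0	0.027200
762.0	0.027054
764.0	0.026683
766.0	0.026185
768.0	0.025657
770.0	0.025200
772.0	0.024809
774.0	0.024417
776.0	0.024032
778.0	0.023658
780.0	0.023300
782.0	0.022951
784.0	0.022605
786.0	0.022274
788.0	0.021968
790.0	0.021700
792.0	0.021438
794.0	0.021171
796.0	0.020934
798.0	0.020765
800.0	0.020700
802.0	0.020804
804.0	0.021071
806.0	0.021436
808.0	0.021835
810.0	0.022200
812.0	0.022511
814.0	0.022813
816.0	0.023138
818.0	0.023523
820.0	0.024000
822.0	0.024712
824.0	0.025702
826.0	0.026857
828.0	0.028061
830.0	0.029200
832.0	0.030242
834.0	0.031262
836.0	0.032311
838.0	0.033440
840.0	0.034700
842.0	0.036297
844.0	0.038225
846.0	0.040215
848.0	0.041997
850.0	0.043300
852.0	0.044153
854.0	0.044827
856.0	0.045413
858.0	0.046007
860.0	0.046700
862.0	0.047528
864.0	0.048435
866.0	0.049378
868.0	0.050314
870.0	0.051200
872.0	0.052016
874.0	0.052791
876.0	0.053559
878.0	0.054351
880.0	0.055200
882.0	0.056095
884.0	0.057018
886.0	0.057994
888.0	0.059046
890.0	0.060200
892.0	0.061455
894.0	0.062818
896.0	0.064323
898.0	0.066006
900.0	0.067900
902.0	0.070066
904.0	0.072564
906.0	0.075428
908.0	0.078695
910.0	0.082400
912.0	0.086895
914.0	0.092388
916.0	0.098693
918.0	0.105625
920.0	0.113000
922.0	0.120780
924.0	0.129258
926.0	0.138747
928.0	0.149557
930.0	0.162000
932.0	0.179219
934.0	0.201819
936.0	0.226311
938.0	0.249201
940.0	0.267000
942.0	0.279430
944.0	0.289504
946.0	0.298663
948.0	0.308348
950.0	0.320000
952.0	0.335341
954.0	0.353723
956.0	0.373034
958.0	0.391164
960.0	0.406000
962.0	0.417693
964.0	0.428057
966.0	0.437473
968.0	0.446327
970.0	0.455000
972.0	0.464675
974.0	0.472949
976.0	0.475980
978.0	0.477445
980.0	0.478000
982.0	0.474798
984.0	0.466473
986.0	0.454950
988.0	0.442151
990.0	0.430000
992.0	0.417663
994.0	0.403731
996.0	0.389269
998.0	0.375337
1000.0	0.363000
1002.0	0.352416
1004.0	0.342752
1006.0	0.333580
1008.0	0.324472
1010.0	0.315000
1012.0	0.304953
1014.0	0.294614
1016.0	0.284298
1018.0	0.274322
1020.0	0.265000
1022.0	0.256271
1024.0	0.247880
1026.0	0.239853
1028.0	0.232218
1030.0	0.225000
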