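# unit: molar extinction coefficient, cm^-1 M^-1
# oxyhemoglobin, literature-style smooth NIR curve; near-isosbestic with Hb at 800-808 nm (crossing ~804 nm)
wavelength_nm,value
650.0,368.000000
652.0,356.689455
654.0,345.828364
656.0,335.822545
658.0,327.077818
660.0,320.000000
662.0,313.875636
664.0,307.812364
666.0,301.947636
668.0,296.418909
670.0,291.363636
672.0,286.919273
674.0,283.223273
676.0,280.413091
678.0,278.626182
680.0,278.000000
682.0,278.150857
684.0,278.589714
686.0,279.296000
688.0,280.249143
690.0,281.428571
692.0,282.813714
694.0,284.384000
696.0,286.118857
698.0,287.997714
700.0,290.000000
702.0,292.912158
704.0,297.227901
706.0,302.487567
708.0,308.231488
710.0,314.000000
712.0,319.935129
714.0,326.412283
716.0,333.321873
718.0,340.554309
720.0,348.000000
722.0,355.642105
724.0,363.587368
726.0,371.911579
728.0,380.690526
730.0,390.000000
732.0,399.952000
734.0,410.576000
736.0,421.824000
738.0,433.648000
740.0,446.000000
742.0,459.313829
744.0,473.701486
746.0,488.632229
748.0,503.575314
750.0,518.000000
752.0,531.914625
754.0,545.677590
756.0,559.283242
758.0,572.725929
760.0,586.000000
762.0,599.048242
764.0,611.879273
766.0,624.586182
768.0,637.262061
770.0,650.000000
772.0,663.092571
774.0,676.477714
776.0,689.716571
778.0,702.370286
780.0,714.000000
782.0,724.656319
784.0,734.723243
786.0,744.262007
788.0,753.333847
790.0,762.000000
792.0,770.174776
794.0,777.863863
796.0,785.265562
798.0,792.578174
800.0,800.000000
802.0,807.510633
804.0,815.000000
806.0,822.432554
808.0,830.000000
810.0,838.000000
812.0,846.123734
814.0,854.270071
816.0,862.554540
818.0,871.092673
820.0,880.000000
822.0,889.503013
824.0,899.552518
826.0,909.850516
828.0,920.099009
830.0,930.000000
832.0,939.679085
834.0,949.418761
836.0,959.156383
838.0,968.829306
840.0,978.374884
842.0,987.730471
844.0,996.833421
846.0,1005.621090
848.0,1014.030832
850.0,1022.000000
852.0,1029.631163
854.0,1037.073565
856.0,1044.334573
858.0,1051.421556
860.0,1058.341882
862.0,1065.102919
864.0,1071.712035
866.0,1078.176598
868.0,1084.503978
870.0,1090.701541
872.0,1096.776656
874.0,1102.736691
876.0,1108.589015
878.0,1114.340995
880.0,1120.000000
882.0,1125.708701
884.0,1131.535870
886.0,1137.378022
888.0,1143.131673
890.0,1148.693341
892.0,1153.959542
894.0,1158.826792
896.0,1163.191607
898.0,1166.950504
900.0,1170.000000
902.0,1172.609850
904.0,1175.115556
906.0,1177.512256
908.0,1179.795087
910.0,1181.959185
912.0,1183.999688
914.0,1185.911732
916.0,1187.690455
918.0,1189.330992
920.0,1190.828482
922.0,1192.178060
924.0,1193.374864
926.0,1194.414031
928.0,1195.290697
930.0,1196.000000
932.0,1196.617440
934.0,1197.214720
936.0,1197.781280
938.0,1198.306560
940.0,1198.780000
942.0,1199.191040
944.0,1199.529120
946.0,1199.783680
948.0,1199.944160
950.0,1200.000000
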