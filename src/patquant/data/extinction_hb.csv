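# unit: molar extinction coefficient, cm^-1 M^-1
# deoxyhemoglobin, literature-style smooth NIR curve with 760-nm band; crossing with HbO2 ~804 nm
wavelength_nm,value
650.0,3750.000000
652.0,3638.752333
654.0,3529.897000
656.0,3424.365501
658.0,3323.089334
660.0,3227.000000
662.0,3134.873754
664.0,3044.892240
666.0,2957.095035
668.0,2871.521722
670.0,2788.211878
672.0,2707.205083
674.0,2628.540919
676.0,2552.258964
678.0,2478.398797
680.0,2407.000000
682.0,2337.323571
684.0,2268.785013
686.0,2201.655660
688.0,2136.206846
690.0,2072.709906
692.0,2011.436173
694.0,1952.656982
696.0,1896.643666
698.0,1843.667561
700.0,1794.000000
702.0,1748.576746
704.0,1707.077651
706.0,1667.890183
708.0,1629.401810
710.0,1590.000000
712.0,1550.193046
714.0,1511.054386
716.0,1471.819203
718.0,1431.722680
720.0,1390.000000
722.0,1338.693953
724.0,1278.230698
726.0,1220.420465
728.0,1177.073488
730.0,1160.000000
732.0,1162.695652
734.0,1170.086957
736.0,1181.130435
738.0,1194.782609
740.0,1210.000000
742.0,1233.906424
744.0,1270.136662
746.0,1312.413689
748.0,1354.460477
750.0,1390.000000
752.0,1422.843871
754.0,1457.499355
756.0,1488.732903
758.0,1511.310968
760.0,1520.000000
762.0,1502.542439
764.0,1458.427317
766.0,1400.040976
768.0,1339.769756
770.0,1290.000000
772.0,1250.851420
774.0,1213.822554
776.0,1178.367977
778.0,1143.942267
780.0,1110.000000
782.0,1076.265639
784.0,1043.055740
786.0,1010.713022
788.0,979.580203
790.0,950.000000
792.0,918.771535
794.0,885.542193
796.0,854.927082
798.0,831.541314
800.0,820.000000
802.0,817.417321
804.0,815.000000
806.0,808.739919
808.0,800.000000
810.0,790.000000
812.0,779.600000
814.0,768.800000
816.0,758.200000
818.0,748.400000
820.0,740.000000
822.0,732.588235
824.0,725.564706
826.0,719.247059
828.0,713.952941
830.0,710.000000
832.0,706.867059
834.0,703.854118
836.0,701.010588
838.0,698.385882
840.0,696.029412
842.0,693.990588
844.0,692.318824
846.0,691.063529
848.0,690.274118
850.0,690.000000
852.0,690.063040
854.0,690.246845
856.0,690.543448
858.0,690.944879
860.0,691.443167
862.0,692.030345
864.0,692.698442
866.0,693.439489
868.0,694.245517
870.0,695.108557
872.0,696.020639
874.0,696.973793
876.0,697.960051
878.0,698.971443
880.0,700.000000
882.0,701.251985
884.0,702.885219
886.0,704.819068
888.0,706.972898
890.0,709.266076
892.0,711.617968
894.0,713.947940
896.0,716.175359
898.0,718.219590
900.0,720.000000
902.0,721.596987
904.0,723.146253
906.0,724.650117
908.0,726.110902
910.0,727.530927
912.0,728.912514
914.0,730.257983
916.0,731.569656
918.0,732.849852
920.0,734.100893
922.0,735.325100
924.0,736.524793
926.0,737.702294
928.0,738.859923
930.0,740.000000
932.0,741.118981
934.0,742.211723
936.0,743.278151
938.0,744.318189
940.0,745.331761
942.0,746.318792
944.0,747.279208
946.0,748.212931
948.0,749.119887
950.0,750.000000
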