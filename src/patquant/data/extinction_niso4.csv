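# unit: specific absorption, cm^-1 per g L^-1
# nickel sulfate unit spectrum (oxy-analog role): rises with wavelength over 730-830 nm; synthetic, consistent with the 14.28 CuSO4/NiSO4 ratio at 800 nm
wavelength_nm,value
650.0,0.120000
652.0,0.121076
654.0,0.122197
656.0,0.123360
658.0,0.124564
660.0,0.125807
662.0,0.127087
664.0,0.128403
666.0,0.129753
668.0,0.131135
670.0,0.132547
672.0,0.133987
674.0,0.135455
676.0,0.136947
678.0,0.138463
680.0,0.140000
682.0,0.141572
684.0,0.143194
686.0,0.144866
688.0,0.146589
690.0,0.148363
692.0,0.150187
694.0,0.152063
696.0,0.153990
698.0,0.155969
700.0,0.158000
702.0,0.160104
704.0,0.162295
706.0,0.164566
708.0,0.166908
710.0,0.169313
712.0,0.171773
714.0,0.174280
716.0,0.176825
718.0,0.179402
720.0,0.182000
722.0,0.184647
724.0,0.187371
726.0,0.190173
728.0,0.193050
730.0,0.196000
732.0,0.199063
734.0,0.202246
736.0,0.205498
738.0,0.208766
740.0,0.212000
742.0,0.215170
744.0,0.218310
746.0,0.221464
748.0,0.224680
750.0,0.228000
752.0,0.231434
754.0,0.234957
756.0,0.238562
758.0,0.242245
760.0,0.246000
762.0,0.249835
764.0,0.253757
766.0,0.257762
768.0,0.261844
770.0,0.266000
772.0,0.270158
774.0,0.274324
776.0,0.278612
778.0,0.283133
780.0,0.288000
782.0,0.293378
784.0,0.299242
786.0,0.305418
788.0,0.311728
790.0,0.318000
792.0,0.324458
794.0,0.331220
796.0,0.337954
798.0,0.344325
800.0,0.350000
802.0,0.354891
804.0,0.359295
806.0,0.363453
808.0,0.367608
810.0,0.372000
812.0,0.376666
814.0,0.381450
816.0,0.386300
818.0,0.391167
820.0,0.396000
822.0,0.400846
824.0,0.405738
826.0,0.410606
828.0,0.415383
830.0,0.420000
832.0,0.424517
834.0,0.429027
836.0,0.433505
838.0,0.437928
840.0,0.442272
842.0,0.446515
844.0,0.450633
846.0,0.454602
848.0,0.458399
850.0,0.462000
852.0,0.465451
854.0,0.468814
856.0,0.472092
858.0,0.475289
860.0,0.478408
862.0,0.481452
864.0,0.484424
866.0,0.487328
868.0,0.490166
870.0,0.492942
872.0,0.495659
874.0,0.498320
876.0,0.500928
878.0,0.503487
880.0,0.506000
882.0,0.508481
884.0,0.510936
886.0,0.513350
888.0,0.515710
890.0,0.518003
892.0,0.520216
894.0,0.522336
896.0,0.524348
898.0,0.526241
900.0,0.528000
902.0,0.529664
904.0,0.531280
906.0,0.532849
908.0,0.534370
910.0,0.535843
912.0,0.537270
914.0,0.538649
916.0,0.539981
918.0,0.541266
920.0,0.542505
922.0,0.543696
924.0,0.544842
926.0,0.545941
928.0,0.546993
930.0,0.548000
932.0,0.548968
934.0,0.549903
936.0,0.550804
938.0,0.551669
940.0,0.552496
942.0,0.553283
944.0,0.554029
946.0,0.554732
948.0,0.555389
950.0,0.556000
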