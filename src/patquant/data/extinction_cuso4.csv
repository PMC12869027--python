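# unit: specific absorption, cm^-1 per g L^-1
# copper sulfate unit spectrum (deoxy-analog role): monotonically increasing 730-830 nm toward a broad ~880-nm band; value at 800 nm is 14.28x the NiSO4 value
wavelength_nm,value
650.0,3.400000
652.0,3.432793
654.0,3.465175
656.0,3.497148
658.0,3.528715
660.0,3.559880
662.0,3.590644
664.0,3.621011
666.0,3.650984
668.0,3.680566
670.0,3.709759
672.0,3.738567
674.0,3.766992
676.0,3.795037
678.0,3.822706
680.0,3.850000
682.0,3.876780
684.0,3.902957
686.0,3.928607
688.0,3.953810
690.0,3.978644
692.0,4.003185
694.0,4.027514
696.0,4.051707
698.0,4.075843
700.0,4.100000
702.0,4.124323
704.0,4.148853
706.0,4.173508
708.0,4.198209
710.0,4.222876
712.0,4.247428
714.0,4.271784
716.0,4.295866
718.0,4.319593
720.0,4.342884
722.0,4.365659
724.0,4.387839
726.0,4.409342
728.0,4.430089
730.0,4.450000
732.0,4.468953
734.0,4.487001
736.0,4.504319
738.0,4.521084
740.0,4.537475
742.0,4.553668
744.0,4.569839
746.0,4.586167
748.0,4.602828
750.0,4.620000
752.0,4.637845
754.0,4.656271
756.0,4.675073
758.0,4.694047
760.0,4.712986
762.0,4.731687
764.0,4.749944
766.0,4.767552
768.0,4.784305
770.0,4.800000
772.0,4.814669
774.0,4.828579
776.0,4.841876
778.0,4.854706
780.0,4.867213
782.0,4.879543
784.0,4.891841
786.0,4.904253
788.0,4.916924
790.0,4.930000
792.0,4.943525
794.0,4.957304
796.0,4.971121
798.0,4.984758
800.0,4.998000
802.0,5.010979
804.0,5.023850
806.0,5.036431
808.0,5.048542
810.0,5.060000
812.0,5.070686
814.0,5.080771
816.0,5.090514
818.0,5.100171
820.0,5.110000
822.0,5.120160
824.0,5.130480
826.0,5.140720
828.0,5.150640
830.0,5.160000
832.0,5.169039
834.0,5.178095
836.0,5.187074
838.0,5.195884
840.0,5.204432
842.0,5.212625
844.0,5.220372
846.0,5.227578
848.0,5.234152
850.0,5.240000
852.0,5.245516
854.0,5.251109
856.0,5.256713
858.0,5.262258
860.0,5.267677
862.0,5.272902
864.0,5.277865
866.0,5.282499
868.0,5.286735
870.0,5.290505
872.0,5.293742
874.0,5.296378
876.0,5.298345
878.0,5.299575
880.0,5.300000
882.0,5.299420
884.0,5.297760
886.0,5.295140
888.0,5.291680
890.0,5.287500
892.0,5.282720
894.0,5.277460
896.0,5.271840
898.0,5.265980
900.0,5.260000
902.0,5.253059
904.0,5.244354
906.0,5.234058
908.0,5.222347
910.0,5.209394
912.0,5.195375
914.0,5.180463
916.0,5.164834
918.0,5.148662
920.0,5.132121
922.0,5.115387
924.0,5.098633
926.0,5.082034
928.0,5.065765
930.0,5.050000
932.0,5.034360
934.0,5.018362
936.0,5.002028
938.0,4.985377
940.0,4.968432
942.0,4.951212
944.0,4.933738
946.0,4.916031
948.0,4.898111
950.0,4.880000
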