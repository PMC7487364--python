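pig,side,thickness_um,burst_pressure_kPa,mu_kPa,alpha,r2_ogden,c1_kPa,r2_neohookean,rupture_stress_MPa
1,L,360,193,11.9,13.8,0.983,345,0.718,not_in_aoi
1,R,359,206,481,5.39,0.997,905,0.972,2.00
2,L,377,127,177,8.61,0.988,598,0.942,not_in_aoi
2,R,381,183,497,4.50,0.987,654,0.970,2.52
3,L,361,failed,failed,failed,failed,failed,failed,failed
3,R,390,141,273,5.64,0.997,490,0.973,not_in_aoi
4,L,400,150,136,10.3,0.990,591,0.943,1.72
4,R,327,failed,failed,failed,failed,failed,failed,failed
5,L,405,150,59.6,9.12,0.992,295,0.869,not_in_aoi
5,R,394,failed,failed,failed,failed,failed,failed,failed
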