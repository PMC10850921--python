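sample_id,species,site,country,peak,internal_peak,internal_size,diploid_flag
bispinosa_oki,T. bispinosa,"Oki village, Fukuoka",Japan,161.50,125.16,373245519,0
incisa_fukui,T. incisa,Fukui,Japan,115.55,98.40,373245519,1
japonica_hirosaki,T. japonica,Hirosaki,Japan,289.21,122.24,373245519,0
natans_kanzaki,T. natans,"Kanzaki city, Saga",Japan,133.87,122.82,373245519,1
bispinosa_liangzhu_4sp_green,T. bispinosa,"Liangzhu, 4 spines, green",China,195.35,162.40,373245519,0
bispinosa_liangzhu_4sp_red,T. bispinosa,"Liangzhu, 4 spines, red",China,254.66,197.39,373245519,0
bispinosa_liangzhu_2sp_red,T. bispinosa,"Liangzhu, 2 spines, red",China,258.66,204.49,373245519,0
japonica_ninpo,T. japonica,Ninpo,China,409.47,187.44,373245519,0
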