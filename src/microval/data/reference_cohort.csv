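specimen_id,free_height_mm,voxel_size_um,tot_bvtv_pct,af_exp_N,af_fe_12gpa_N,af_fe_4p6gpa_N
S#1,12.9,39.0,41.3,2953,6881,2643
S#2,12.6,38.6,40.3,1060,1910,734
S#3,10.8,38.6,32.7,1122,5256,2019
S#4,13.3,38.6,48.6,3028,6999,2689
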