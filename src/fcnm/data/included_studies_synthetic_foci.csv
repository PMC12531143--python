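# Included-studies table for the extraversion VBM literature (13 studies).
# Sample characteristics (n, F/M, age, scale) are as published; the x/y/z
# focus coordinates are SYNTHETIC placeholders at plausible cortical loci,
# because the source studies' peak tables are not redistributed here.
study_id,n,n_female,n_male,mean_age,sd_age,scale,contrast_id,x,y,z,space,sign
study01,30,13,17,23.57,3.70,NEO-PI-R,c1,2,52,-2,MNI,positive
study02,52,29,23,25.0,5.1,NEO-FFI,c1,-42,36,20,MNI,positive
study03,65,42,23,40.5,9.7,NEO-FFI,c1,24,-4,-18,MNI,positive
study04,116,58,58,22.9,5.5,NEO-PI-R,c1,44,-60,28,MNI,positive
study05,32,0,32,33.2,7.8,16PF,c1,-6,50,10,MNI,positive
study06,83,46,37,24.9,7.7,MPQ-BF,c1,36,20,-6,MNI,positive
study07,87,42,45,72,7.7,NEO-PI-R,c1,-38,-52,44,MNI,negative
study08,337,189,148,20.0,1.3,NEO-PI-R,c1,42,38,22,MNI,positive
study09,71,37,34,22.35,1.5,EPQ-RSC,c1,-24,-2,-20,MNI,negative
study10,41,22,19,23.8,5.4,NEO-PI-R,c1,0,-56,28,MNI,positive
study11,364,182,182,29.1,3.45,NEO-FFI,c1,-44,20,24,MNI,positive
study12,100,58,42,22.0,2.33,EPQ-RSC,c1,50,-54,30,MNI,positive
study13,100,50,50,21.91,2.29,EPQ-RSC,c1,-2,48,18,MNI,positive
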