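specimen,sub_tendon,csa_mm2,failure_force_n,ultimate_stress_mpa,ultimate_strain_pct,modulus_mpa,stiffness_n_mm
69 M,LG,13.6,325.0,24.0,9.7,353.9,79.9
69 M,MG,14.5,402.2,27.7,10.0,375.8,97.6
69 M,SOL,39.2,1701.2,45.3,19.1,399.4,260.6
78 F,LG,12.4,154.7,12.5,11.6,175.0,36.7
78 F,MG,10.8,571.1,52.6,8.9,771.1,145.6
78 F,SOL,20.6,1155.6,56.2,17.5,421.1,167.8
84 F,LG,5.7,503.6,89.0,8.9,1231.5,118.2
84 F,MG,10.7,621.8,58.3,12.2,636.9,121.4
84 F,SOL,30.9,1577.0,51.0,10.4,734.9,385.1
85 F,LG,10.4,787.5,75.8,11.9,853.6,151.7
85 F,MG,14.0,688.3,49.0,10.6,617.2,144.7
85 F,SOL,38.2,1090.9,28.6,15.8,239.9,156.6
87 M,LG,4.6,301.6,65.9,8.2,1033.4,80.9
87 M,MG,17.0,647.7,38.1,10.2,496.2,143.0
87 M,SOL,35.2,1578.5,44.9,10.8,606.2,349.6
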