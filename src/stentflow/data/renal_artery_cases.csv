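patient_id,side,tilt_angle,entry_depth,branch_diameter,aortic_diameter,patency
A,left,103.5,5.04,5.21,23.21,patent
A,right,105.6,10.06,5.10,23.21,patent
B,left,131.8,8.59,4.95,19.14,patent
B,right,126.7,7.88,5.72,19.14,patent
C,left,139.8,9.55,5.50,21.77,patent
C,right,106.7,6.16,5.50,21.77,patent
D,left,81.1,6.34,5.80,34.93,occluded
D,right,77.5,10.13,5.47,34.93,occluded
E,left,91.9,6.75,3.88,18.06,occluded
E,right,118.8,4.59,3.67,18.06,patent
F,left,80.5,5.67,3.92,21.88,occluded
F,right,127.1,4.80,4.20,21.88,patent
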