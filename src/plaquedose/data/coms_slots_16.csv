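group,x_mm,y_mm,z_mm,axis_x,axis_y,axis_z
2,5.809464,0.000000,-0.664118,-0.000000,1.000000,0.000000
2,4.107911,4.107911,-0.664118,-0.707107,0.707107,0.000000
2,0.000000,5.809464,-0.664118,-1.000000,0.000000,0.000000
2,-4.107911,4.107911,-0.664118,-0.707107,-0.707107,0.000000
2,-5.809464,0.000000,-0.664118,-0.000000,-1.000000,0.000000
2,-4.107911,-4.107911,-0.664118,0.707107,-0.707107,0.000000
2,-0.000000,-5.809464,-0.664118,1.000000,-0.000000,0.000000
2,4.107911,-4.107911,-0.664118,0.707107,0.707107,0.000000
1,4.701215,0.000000,-1.141406,-0.000000,1.000000,0.000000
1,0.000000,4.701215,-1.141406,-1.000000,0.000000,0.000000
1,-4.701215,0.000000,-1.141406,-0.000000,-1.000000,0.000000
1,-0.000000,-4.701215,-1.141406,1.000000,-0.000000,0.000000
3,0.000000,0.000000,-2.000000,1.000000,0.000000,0.000000
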