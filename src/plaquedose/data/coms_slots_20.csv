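group,x_mm,y_mm,z_mm,axis_x,axis_y,axis_z
2,9.123619,2.444666,1.936604,-0.258819,0.965926,0.000000
2,6.678953,6.678953,1.936604,-0.707107,0.707107,0.000000
2,2.444666,9.123619,1.936604,-0.965926,0.258819,0.000000
2,-2.444666,9.123619,1.936604,-0.965926,-0.258819,0.000000
2,-6.678953,6.678953,1.936604,-0.707107,-0.707107,0.000000
2,-9.123619,2.444666,1.936604,-0.258819,-0.965926,0.000000
2,-9.123619,-2.444666,1.936604,0.258819,-0.965926,0.000000
2,-6.678953,-6.678953,1.936604,0.707107,-0.707107,0.000000
2,-2.444666,-9.123619,1.936604,0.965926,-0.258819,0.000000
2,2.444666,-9.123619,1.936604,0.965926,0.258819,0.000000
2,6.678953,-6.678953,1.936604,0.707107,0.707107,0.000000
2,9.123619,-2.444666,1.936604,0.258819,0.965926,0.000000
3,5.386528,2.231173,-0.653961,0.830377,0.343954,0.438371
3,2.231173,5.386528,-0.653961,0.343954,0.830377,0.438371
3,-2.231173,5.386528,-0.653961,-0.343954,0.830377,0.438371
3,-5.386528,2.231173,-0.653961,-0.830377,0.343954,0.438371
3,-5.386528,-2.231173,-0.653961,-0.830377,-0.343954,0.438371
3,-2.231173,-5.386528,-0.653961,-0.343954,-0.830377,0.438371
3,2.231173,-5.386528,-0.653961,0.343954,-0.830377,0.438371
3,5.386528,-2.231173,-0.653961,0.830377,-0.343954,0.438371
1,2.275159,2.275159,-1.604933,-0.707107,0.707107,0.000000
1,-2.275159,2.275159,-1.604933,-0.707107,-0.707107,0.000000
1,-2.275159,-2.275159,-1.604933,0.707107,-0.707107,0.000000
1,2.275159,-2.275159,-1.604933,0.707107,0.707107,0.000000
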