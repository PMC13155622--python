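group,molecular_number,cho,chon,chos,chons,h_c_w,o_c_w,dbe_w,nosc_w,mz_w,ai_w
LFC-DOM-25C,4675,2235,1473,643,324,1.493,0.303,6.099,-0.817,358,1.807
LC-DOM-25C,3877,1996,889,679,313,1.456,0.313,6.553,-0.771,363,0.182
ANT-DOM-25C,4256,1466,1364,571,855,1.636,0.234,4.919,-1.037,355,0.087
LFC-DOM-50C,6840,3318,2300,940,282,1.287,0.402,8.236,-0.439,405,0.262
LC-DOM-50C,7876,3777,1855,1668,576,1.279,0.390,9.043,-0.448,440,0.266
ANT-DOM-50C,7476,3142,3348,709,277,1.685,0.261,4.857,-1.099,437,0.095
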