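radius_um,volume_fraction
1,0.0614452
1.25,0.0893051
1.5,0.0804089
1.75,0.0552386
2,0.0324532
2.25,0.017718
2.5,0.00999053
2.75,0.00688763
3,0.00656633
3.5,0.0102915
4,0.0167861
4.5,0.0241685
5,0.0312093
5.5,0.0370647
6,0.04127
6.5,0.0436947
7,0.0444511
7.5,0.0437947
8,0.0420419
8.5,0.0395113
9,0.0364892
9.5,0.0332135
10,0.0298694
10.5,0.0265926
11,0.023476
11.5,0.0205782
12,0.0179308
12.5,0.0155459
13,0.0134215
13.5,0.0115466
14,0.00990434
14.5,0.00847485
15,0.00723702
15.5,0.00616975
16,0.00525285
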