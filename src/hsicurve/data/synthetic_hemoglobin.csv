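wavelength_nm,mua_Hb_cm1,mua_HbO2_cm1
400,103.468,304.321
401,112.994,325.951
402,123.059,347.353
403,133.647,368.285
404,144.738,388.501
405,156.302,407.75
406,168.304,425.782
407,180.702,442.357
408,193.447,457.247
409,206.482,470.239
410,219.744,481.146
411,233.164,489.808
412,246.667,496.095
413,260.172,499.913
414,273.594,501.204
415,286.843,499.948
416,299.829,496.166
417,312.457,489.914
418,324.633,481.289
419,336.263,470.419
420,347.256,457.465
421,357.52,442.615
422,366.972,426.08
423,375.53,408.089
424,383.122,388.884
425,389.68,368.713
426,395.147,347.828
427,399.475,326.476
428,402.624,304.897
429,404.567,283.321
430,405.288,261.958
431,404.78,241.004
432,403.049,220.63
433,400.113,200.987
434,396,182.201
435,390.749,164.374
436,384.408,147.585
437,377.036,131.888
438,368.7,117.319
439,359.473,103.89
440,349.436,91.5994
441,338.675,80.4259
442,327.28,70.337
443,315.342,61.2886
444,302.957,53.2275
445,290.219,46.0942
446,277.222,39.8244
447,264.058,34.3514
448,250.816,29.607
449,237.582,25.5238
450,224.436,22.0357
451,211.454,19.0794
452,198.705,16.5947
453,186.253,14.5254
454,174.153,12.8196
455,162.457,11.4296
456,151.205,10.3125
457,140.434,9.42969
458,130.171,8.74683
459,120.439,8.2338
460,111.253,7.86423
461,102.622,7.61531
462,94.5495,7.46742
463,87.0339,7.40384
464,80.069,7.41039
465,73.6441,7.47513
466,67.7451,7.58811
467,62.3547,7.74102
468,57.4529,7.92702
469,53.0178,8.14045
470,49.0257,8.3767
471,45.452,8.63196
472,42.271,8.90315
473,39.457,9.18773
474,36.9839,9.48361
475,34.8262,9.78908
476,32.9589,10.1027
477,31.3575,10.4233
478,29.9987,10.7498
479,28.8601,11.0813
480,27.9207,11.417
481,27.1605,11.7562
482,26.561,12.0982
483,26.105,12.4424
484,25.7767,12.7881
485,25.5616,13.1349
486,25.4464,13.4822
487,25.4191,13.8295
488,25.4691,14.1763
489,25.5868,14.5221
490,25.7637,14.8667
491,25.9923,15.2096
492,26.2662,15.5507
493,26.5797,15.8898
494,26.9282,16.2268
495,27.3076,16.5621
496,27.7147,16.8958
497,28.1468,17.2286
498,28.6019,17.5612
499,29.0785,17.8948
500,29.5758,18.2309
501,30.0931,18.5713
502,30.6303,18.9182
503,31.1878,19.2746
504,31.7662,19.6435
505,32.3664,20.0289
506,32.9896,20.435
507,33.6372,20.867
508,34.3109,21.3303
509,35.0125,21.8308
510,35.7439,22.3752
511,36.5072,22.9704
512,37.3045,23.6234
513,38.1378,24.3418
514,39.0093,25.1327
515,39.921,26.0032
516,40.8747,26.9599
517,41.8722,28.0086
518,42.9152,29.1542
519,44.0047,30.4
520,45.142,31.748
521,46.3274,33.198
522,47.5614,34.7477
523,48.8436,36.3925
524,50.1733,38.1249
525,51.5494,39.9348
526,52.97,41.8092
527,54.4328,43.7321
528,55.9346,45.6851
529,57.4718,47.647
530,59.0401,49.5945
531,60.6345,51.5026
532,62.2493,53.3447
533,63.8783,55.0938
534,65.5146,56.7228
535,67.1508,58.205
536,68.7787,59.5154
537,70.3898,60.6309
538,71.9754,61.5314
539,73.5259,62.2005
540,75.032,62.6256
541,76.4839,62.7992
542,77.8716,62.7187
543,79.1855,62.3874
544,80.4158,61.8136
545,81.5529,61.0119
546,82.5877,60.0019
547,83.5114,58.8088
548,84.3158,57.4624
549,84.9934,55.9966
550,85.5372,54.4491
551,85.9411,52.8598
552,86.2001,51.2705
553,86.3099,49.7234
554,86.2673,48.2601
555,86.0702,46.9206
556,85.7176,45.7418
557,85.2095,44.7565
558,84.5472,43.9923
559,83.7329,43.4704
560,82.7701,43.2049
561,81.6633,43.2017
562,80.4179,43.4585
563,79.0402,43.9641
564,77.5377,44.6985
565,75.9183,45.6333
566,74.1909,46.7325
567,72.3648,47.9528
568,70.4499,49.2456
569,68.4565,50.5581
570,66.3952,51.8351
571,64.2765,53.0208
572,62.1115,54.061
573,59.9109,54.9046
574,57.6852,55.506
575,55.4449,55.8262
576,53.2001,55.8347
577,50.9605,55.5102
578,48.7352,54.8414
579,46.533,53.8272
580,44.3619,52.4768
581,42.2293,50.8086
582,40.1421,48.8497
583,38.1063,46.6346
584,36.1272,44.2034
585,34.2096,41.6004
586,32.3573,38.8723
587,30.5736,36.0663
588,28.8611,33.2289
589,27.2215,30.4039
590,25.6563,27.6315
591,24.1661,24.9473
592,22.7511,22.3813
593,21.4108,19.9581
594,20.1445,17.6959
595,18.9509,15.6076
596,17.8284,13.7002
597,16.7752,11.976
598,15.789,10.4329
599,14.8674,9.06489
600,14.0079,7.86334
601,13.2078,6.81727
602,12.4642,5.91423
603,11.7742,5.14088
604,11.135,4.48355
605,10.5436,3.92871
606,9.99706,3.46333
607,9.49265,3.07515
608,9.02756,2.75289
609,8.59909,2.48634
610,8.20465,2.26644
611,7.84177,2.08526
612,7.50806,1.93595
613,7.2013,1.81268
614,6.91935,1.71059
615,6.66023,1.6256
616,6.42207,1.55438
617,6.20314,1.49425
618,6.00182,1.44301
619,5.81663,1.39894
620,5.64618,1.36067
621,5.48921,1.32711
622,5.34455,1.29742
623,5.21114,1.27095
624,5.088,1.24718
625,4.97426,1.2257
626,4.86911,1.2062
627,4.77181,1.18844
628,4.68171,1.1722
629,4.5982,1.15734
630,4.52073,1.1437
631,4.44882,1.13119
632,4.38201,1.1197
633,4.31991,1.10915
634,4.26214,1.09946
635,4.20838,1.09056
636,4.15832,1.0824
637,4.11169,1.07492
638,4.06824,1.06806
639,4.02775,1.06178
640,3.99,1.05604
641,3.9548,1.05079
642,3.92198,1.04599
643,3.89139,1.04161
644,3.86287,1.03762
645,3.83628,1.03399
646,3.8115,1.03068
647,3.78841,1.02767
648,3.7669,1.02493
649,3.74687,1.02245
650,3.72823,1.0202
651,3.71088,1.01816
652,3.69475,1.01631
653,3.67975,1.01464
654,3.66581,1.01312
655,3.65287,1.01176
656,3.64085,1.01053
657,3.62971,1.00942
658,3.61938,1.00842
659,3.6098,1.00752
660,3.60093,1.00671
661,3.59272,1.00598
662,3.58513,1.00533
663,3.57811,1.00474
664,3.57163,1.00422
665,3.56565,1.00375
666,3.56012,1.00333
667,3.55503,1.00295
668,3.55034,1.00262
669,3.54602,1.00232
670,3.54205,1.00205
671,3.53839,1.00182
672,3.53503,1.00161
673,3.53195,1.00142
674,3.52911,1.00125
675,3.52652,1.0011
676,3.52414,1.00097
677,3.52195,1.00085
678,3.51996,1.00075
679,3.51813,1.00066
680,3.51646,1.00058
681,3.51494,1.00051
682,3.51355,1.00045
683,3.51228,1.00039
684,3.51112,1.00034
685,3.51006,1.0003
686,3.5091,1.00026
687,3.50823,1.00023
688,3.50743,1.0002
689,3.50671,1.00017
690,3.50606,1.00015
691,3.50546,1.00013
692,3.50492,1.00011
693,3.50443,1.0001
694,3.50399,1.00009
695,3.50359,1.00007
696,3.50323,1.00006
697,3.5029,1.00006
698,3.5026,1.00005
699,3.50233,1.00004
700,3.50209,1.00004
701,3.50188,1.00003
702,3.50168,1.00003
703,3.5015,1.00002
704,3.50134,1.00002
705,3.5012,1.00002
706,3.50107,1.00001
707,3.50096,1.00001
708,3.50086,1.00001
709,3.50076,1.00001
710,3.50068,1.00001
711,3.50061,1.00001
712,3.50054,1.00001
713,3.50048,1
714,3.50043,1
715,3.50038,1
716,3.50034,1
717,3.5003,1
718,3.50026,1
719,3.50023,1
720,3.50021,1
721,3.50018,1
722,3.50016,1
723,3.50014,1
724,3.50013,1
725,3.50011,1
726,3.5001,1
727,3.50009,1
728,3.50008,1
729,3.50007,1
730,3.50006,1
731,3.50005,1
732,3.50005,1
733,3.50004,1
734,3.50004,1
735,3.50003,1
736,3.50003,1
737,3.50002,1
738,3.50002,1
739,3.50002,1
740,3.50002,1
741,3.50001,1
742,3.50001,1
743,3.50001,1
744,3.50001,1
745,3.50001,1
746,3.50001,1
747,3.50001,1
748,3.50001,1
749,3.5,1
750,3.5,1
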