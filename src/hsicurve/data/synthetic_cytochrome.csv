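wavelength_nm,mua_CytO_cm1_per_mM,mua_CytOO2_cm1_per_mM
400,2.99955,82.4234
401,3.65552,87.6292
402,4.4352,92.9313
403,5.35731,98.3081
404,6.44243,103.736
405,7.71299,109.191
406,9.19318,114.646
407,10.9088,120.072
408,12.8873,125.442
409,15.157,130.724
410,17.7475,135.889
411,20.6885,140.906
412,24.0099,145.742
413,27.741,150.369
414,31.9098,154.754
415,36.5423,158.871
416,41.6617,162.689
417,47.2878,166.184
418,53.4356,169.329
419,60.1148,172.104
420,67.3291,174.487
421,75.0748,176.461
422,83.3403,178.013
423,92.1057,179.129
424,101.342,179.803
425,111.009,180.029
426,121.06,179.805
427,131.435,179.133
428,142.067,178.018
429,152.878,176.468
430,163.782,174.496
431,174.686,172.114
432,185.49,169.342
433,196.088,166.198
434,206.374,162.705
435,216.236,158.889
436,225.565,154.774
437,234.254,150.39
438,242.199,145.766
439,249.304,140.931
440,255.481,135.917
441,260.65,130.754
442,264.746,125.473
443,267.715,120.106
444,269.519,114.681
445,270.133,109.229
446,269.551,103.776
447,267.78,98.3499
448,264.843,92.9752
449,260.781,87.6754
450,255.647,82.4719
451,249.508,77.3842
452,242.441,72.4297
453,234.536,67.6239
454,225.891,62.9801
455,216.608,58.5096
456,206.795,54.2217
457,196.562,50.1235
458,186.019,46.2204
459,175.276,42.516
460,164.437,39.012
461,153.603,35.7086
462,142.867,32.6048
463,132.315,29.6978
464,122.026,26.984
465,112.067,24.4586
466,102.498,22.116
467,93.3676,19.9497
468,84.7143,17.9526
469,76.568,16.1171
470,68.9491,14.4354
471,61.8693,12.8993
472,55.3324,11.5004
473,49.335,10.2302
474,43.8677,9.08034
475,38.9153,8.04259
476,34.4583,7.1088
477,30.4736,6.27104
478,26.935,5.5217
479,23.8147,4.85345
480,21.0832,4.25932
481,18.7105,3.73267
482,16.6667,3.26728
483,14.9221,2.8573
484,13.4479,2.49727
485,12.2164,2.18211
486,11.2015,1.90715
487,10.3785,1.66807
488,9.72443,1.46093
489,9.21821,1.28212
490,8.84046,1.12838
491,8.57361,0.996742
492,8.40181,0.884545
493,8.31084,0.789396
494,8.28804,0.709154
495,8.32217,0.641915
496,8.4033,0.585989
497,8.52271,0.539881
498,8.67276,0.502275
499,8.84674,0.472016
500,9.03883,0.448093
501,9.24393,0.429626
502,9.45761,0.415851
503,9.676,0.406107
504,9.89572,0.399822
505,10.1138,0.396509
506,10.3277,0.395747
507,10.5352,0.397179
508,10.7341,0.400502
509,10.9229,0.405459
510,11.1,0.411833
511,11.2639,0.419442
512,11.4136,0.428135
513,11.548,0.437785
514,11.6662,0.448287
515,11.7674,0.459556
516,11.8511,0.47152
517,11.9166,0.484124
518,11.9636,0.49732
519,11.9918,0.511072
520,12.001,0.525351
521,11.9911,0.540133
522,11.9622,0.555403
523,11.9143,0.571147
524,11.8476,0.587356
525,11.7626,0.604023
526,11.6595,0.621145
527,11.5388,0.638721
528,11.4011,0.656748
529,11.2471,0.67523
530,11.0774,0.694167
531,10.8929,0.713562
532,10.6943,0.73342
533,10.4825,0.753742
534,10.2585,0.774534
535,10.0233,0.795801
536,9.77775,0.817545
537,9.523,0.839772
538,9.26007,0.862487
539,8.99002,0.885695
540,8.71389,0.909398
541,8.43277,0.933603
542,8.14769,0.958313
543,7.85969,0.983532
544,7.56981,1.00926
545,7.27903,1.03551
546,6.98833,1.06228
547,6.69865,1.08958
548,6.41089,1.11739
549,6.12595,1.14574
550,5.84466,1.17462
551,5.56784,1.20404
552,5.29629,1.23399
553,5.03078,1.26448
554,4.77207,1.29551
555,4.52091,1.32707
556,4.27807,1.35918
557,4.04435,1.39183
558,3.82056,1.42502
559,3.60761,1.45874
560,3.40647,1.49301
561,3.21822,1.52782
562,3.04407,1.56316
563,2.88541,1.59904
564,2.74379,1.63544
565,2.62101,1.67238
566,2.5191,1.70985
567,2.44036,1.74783
568,2.3874,1.78634
569,2.36313,1.82536
570,2.37075,1.86489
571,2.4138,1.90492
572,2.49611,1.94545
573,2.62174,1.98647
574,2.79498,2.02798
575,3.02029,2.06997
576,3.30213,2.11243
577,3.64496,2.15535
578,4.05303,2.19872
579,4.53029,2.24254
580,5.08017,2.28679
581,5.70546,2.33148
582,6.40811,2.37657
583,7.18901,2.42208
584,8.04784,2.46798
585,8.9829,2.51426
586,9.99093,2.56091
587,11.067,2.60792
588,12.2045,2.65528
589,13.3949,2.70297
590,14.628,2.75098
591,15.8917,2.7993
592,17.1726,2.84791
593,18.4555,2.8968
594,19.7245,2.94595
595,20.9623,2.99534
596,22.1515,3.04497
597,23.2745,3.09481
598,24.3137,3.14485
599,25.2525,3.19508
600,26.0754,3.24547
601,26.7685,3.29601
602,27.3196,3.34668
603,27.7191,3.39747
604,27.9597,3.44835
605,28.0371,3.49932
606,27.9496,3.55034
607,27.6987,3.60141
608,27.2887,3.6525
609,26.7267,3.7036
610,26.0221,3.75468
611,25.187,3.80574
612,24.2351,3.85674
613,23.1818,3.90768
614,22.0436,3.95853
615,20.8378,4.00927
616,19.5818,4.05989
617,18.2931,4.11037
618,16.9884,4.16069
619,15.6837,4.21082
620,14.3939,4.26076
621,13.1322,4.31049
622,11.9105,4.35998
623,10.7387,4.40922
624,9.62511,4.45818
625,8.5761,4.50687
626,7.59635,4.55524
627,6.68884,4.6033
628,5.85501,4.65102
629,5.09489,4.69839
630,4.4073,4.74538
631,3.79002,4.792
632,3.23996,4.83821
633,2.7534,4.884
634,2.32611,4.92937
635,1.95353,4.97429
636,1.63095,5.01876
637,1.35361,5.06275
638,1.1168,5.10627
639,0.915984,5.14928
640,0.746846,5.19179
641,0.605347,5.23379
642,0.487763,5.27525
643,0.3907,5.31617
644,0.311106,5.35655
645,0.246266,5.39637
646,0.19379,5.43562
647,0.151596,5.4743
648,0.11789,5.5124
649,0.0911373,5.5499
650,0.0700399,5.58682
651,0.053509,5.62314
652,0.0406386,5.65885
653,0.0306819,5.69396
654,0.023028,5.72845
655,0.0171815,5.76233
656,0.0127438,5.79559
657,0.00939657,5.82823
658,0.00688765,5.86025
659,0.00501887,5.89165
660,0.00363558,5.92244
661,0.00261803,5.9526
662,0.00187417,5.98214
663,0.00133376,6.01107
664,0.000943591,6.03938
665,0.00066363,6.06709
666,0.000463987,6.09418
667,0.000322496,6.12068
668,0.000222835,6.14657
669,0.000153069,6.17188
670,0.000104529,6.1966
671,7.09636e-05,6.22074
672,4.78948e-05,6.2443
673,3.21365e-05,6.26731
674,2.14376e-05,6.28975
675,1.42175e-05,6.31165
676,9.37467e-06,6.333
677,6.14587e-06,6.35383
678,4.0061e-06,6.37414
679,2.59651e-06,6.39394
680,1.67346e-06,6.41323
681,1.07257e-06,6.43204
682,6.83696e-07,6.45037
683,4.33489e-07,6.46824
684,2.73423e-07,6.48566
685,1.716e-07,6.50263
686,1.07184e-07,6.51917
687,6.66506e-08,6.5353
688,4.12776e-08,6.55103
689,2.54727e-08,6.56637
690,1.56733e-08,6.58133
691,9.62316e-09,6.59593
692,5.90163e-09,6.61018
693,3.61951e-09,6.62409
694,2.22323e-09,6.63769
695,1.37001e-09,6.65098
696,8.48625e-10,6.66398
697,5.29533e-10,6.6767
698,3.33594e-10,6.68915
699,2.12627e-10,6.70136
700,1.3737e-10,6.71333
701,9.00801e-11,6.72507
702,5.99971e-11,6.73661
703,4.0586e-11,6.74796
704,2.7864e-11,6.75913
705,1.93887e-11,6.77013
706,1.36505e-11,6.78098
707,9.70543e-12,6.79169
708,6.95532e-12,6.80227
709,5.01512e-12,6.81274
710,3.63264e-12,6.82311
711,2.63972e-12,6.8334
712,1.92224e-12,6.8436
713,1.40148e-12,6.85375
714,1.02233e-12,6.86384
715,7.4575e-13,6.8739
716,5.4376e-13,6.88392
717,3.96187e-13,6.89393
718,2.88385e-13,6.90393
719,2.09675e-13,6.91393
720,1.52255e-13,6.92395
721,1.10408e-13,6.93398
722,7.99488e-14,6.94405
723,5.78068e-14,6.95416
724,4.17338e-14,6.96432
725,3.00835e-14,6.97453
726,2.16517e-14,6.98481
727,1.55587e-14,6.99516
728,1.11627e-14,7.00558
729,7.99602e-15,7.01609
730,5.7186e-15,7.02669
731,4.08332e-15,7.03738
732,2.91101e-15,7.04817
733,2.07196e-15,7.05906
734,1.4724e-15,7.07007
735,1.04466e-15,7.08118
736,7.39994e-16,7.09241
737,5.23345e-16,7.10376
738,3.69533e-16,7.11523
739,2.60509e-16,7.12682
740,1.83358e-16,7.13853
741,1.28849e-16,7.15037
742,9.03995e-17,7.16233
743,6.33224e-17,7.17441
744,4.42847e-17,7.18662
745,3.09211e-17,7.19896
746,2.15557e-17,7.21141
747,1.50028e-17,7.22399
748,1.04253e-17,7.23669
749,7.23289e-18,7.24951
750,5.01001e-18,7.26243
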