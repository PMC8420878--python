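wavelength_nm,mua_bil_cm1_per_mM
400,20.6906
401,21.9284
402,23.2177
403,24.5587
404,25.9518
405,27.3972
406,28.8949
407,30.4446
408,32.0462
409,33.6991
410,35.4027
411,37.1561
412,38.9583
413,40.808
414,42.7038
415,44.6441
416,46.627
417,48.6504
418,50.7121
419,52.8095
420,54.94
421,57.1007
422,59.2884
423,61.4998
424,63.7315
425,65.9797
426,68.2405
427,70.5099
428,72.7837
429,75.0574
430,77.3266
431,79.5867
432,81.8329
433,84.0603
434,86.2641
435,88.4393
436,90.5808
437,92.6835
438,94.7426
439,96.7528
440,98.7093
441,100.607
442,102.441
443,104.207
444,105.9
445,107.515
446,109.048
447,110.495
448,111.852
449,113.116
450,114.281
451,115.347
452,116.308
453,117.163
454,117.909
455,118.544
456,119.066
457,119.474
458,119.766
459,119.941
460,120
461,119.941
462,119.766
463,119.474
464,119.066
465,118.544
466,117.909
467,117.163
468,116.308
469,115.347
470,114.281
471,113.116
472,111.852
473,110.495
474,109.048
475,107.515
476,105.9
477,104.207
478,102.441
479,100.607
480,98.7093
481,96.7528
482,94.7426
483,92.6835
484,90.5808
485,88.4393
486,86.2641
487,84.0603
488,81.8329
489,79.5867
490,77.3266
491,75.0574
492,72.7837
493,70.5099
494,68.2405
495,65.9797
496,63.7315
497,61.4998
498,59.2884
499,57.1007
500,54.94
501,52.8095
502,50.7121
503,48.6504
504,46.627
505,44.6441
506,42.7038
507,40.808
508,38.9583
509,37.1561
510,35.4027
511,33.6991
512,32.0462
513,30.4446
514,28.8949
515,27.3972
516,25.9518
517,24.5587
518,23.2177
519,21.9284
520,20.6906
521,19.5036
522,18.3667
523,17.2792
524,16.2402
525,15.2488
526,14.304
527,13.4046
528,12.5495
529,11.7375
530,10.9673
531,10.2376
532,9.54714
533,8.89457
534,8.27852
535,7.69761
536,7.15048
537,6.63575
538,6.15207
539,5.69808
540,5.27243
541,4.87382
542,4.50095
543,4.15255
544,3.82738
545,3.52422
546,3.24191
547,2.97931
548,2.7353
549,2.50883
550,2.29886
551,2.10441
552,1.92453
553,1.7583
554,1.60486
555,1.46339
556,1.33308
557,1.21319
558,1.10301
559,1.00185
560,0.909081
561,0.824098
562,0.746331
563,0.675242
564,0.610328
565,0.551117
566,0.497163
567,0.448055
568,0.403402
569,0.362846
570,0.326048
571,0.292696
572,0.262499
573,0.235188
574,0.210512
575,0.188242
576,0.168163
577,0.150079
578,0.13381
579,0.119187
580,0.106059
581,0.0942849
582,0.083736
583,0.0742947
584,0.0658536
585,0.0583146
586,0.0515882
587,0.0455932
588,0.0402555
589,0.035508
590,0.0312899
591,0.0275459
592,0.0242262
593,0.0212858
594,0.018684
595,0.0163843
596,0.0143535
597,0.0125622
598,0.0109838
599,0.00959426
600,0.00837235
601,0.00729893
602,0.00635692
603,0.00553108
604,0.00480784
605,0.00417508
606,0.00362206
607,0.00313923
608,0.0027181
609,0.00235117
610,0.00203179
611,0.00175408
612,0.00151285
613,0.00130352
614,0.00112206
615,0.00096492
616,0.000828975
617,0.000711487
618,0.000610055
619,0.000522573
620,0.000447198
621,0.000382322
622,0.000326539
623,0.000278622
624,0.000237505
625,0.000202258
626,0.000172074
627,0.000146251
628,0.000124183
629,0.000105341
630,8.92708e-05
631,7.55784e-05
632,6.39237e-05
633,5.40134e-05
634,4.55951e-05
635,3.84512e-05
636,3.23949e-05
637,2.7266e-05
638,2.29266e-05
639,1.92591e-05
640,1.61624e-05
641,1.35505e-05
642,1.13495e-05
643,9.49677e-06
644,7.93872e-06
645,6.62981e-06
646,5.53131e-06
647,4.61031e-06
648,3.83892e-06
649,3.19347e-06
650,2.65395e-06
651,2.20343e-06
652,1.8276e-06
653,1.51439e-06
654,1.25364e-06
655,1.03677e-06
656,8.56578e-07
657,7.07014e-07
658,5.82995e-07
659,4.80262e-07
660,3.95246e-07
661,3.24962e-07
662,2.66915e-07
663,2.19023e-07
664,1.79548e-07
665,1.47045e-07
666,1.20308e-07
667,9.83364e-08
668,8.0299e-08
669,6.55062e-08
670,5.33863e-08
671,4.34664e-08
672,3.53552e-08
673,2.87295e-08
674,2.33228e-08
675,1.8915e-08
676,1.53253e-08
677,1.24048e-08
678,1.0031e-08
679,8.10354e-09
680,6.54005e-09
681,5.27307e-09
682,4.24739e-09
683,3.41788e-09
684,2.74768e-09
685,2.20675e-09
686,1.77058e-09
687,1.41923e-09
688,1.13649e-09
689,9.09192e-10
690,7.26643e-10
691,5.80179e-10
692,4.62785e-10
693,3.68784e-10
694,2.9359e-10
695,2.335e-10
696,1.85527e-10
697,1.47266e-10
698,1.16782e-10
699,9.25177e-11
700,7.32232e-11
701,5.78961e-11
702,4.57325e-11
703,3.60892e-11
704,2.84515e-11
705,2.24083e-11
706,1.76315e-11
707,1.38594e-11
708,1.08837e-11
709,8.53851e-12
710,6.69215e-12
711,5.23992e-12
712,4.09883e-12
713,3.2031e-12
714,2.50067e-12
715,1.95038e-12
716,1.5197e-12
717,1.18297e-12
718,9.19946e-13
719,7.14708e-13
720,5.54716e-13
721,4.30119e-13
722,3.33182e-13
723,2.57841e-13
724,1.99341e-13
725,1.53964e-13
726,1.188e-13
727,9.15775e-14
728,7.05242e-14
729,5.42579e-14
730,4.17027e-14
731,3.20214e-14
732,2.45637e-14
733,1.88244e-14
734,1.44121e-14
735,1.10232e-14
736,8.42291e-15
737,6.42975e-15
738,4.90345e-15
739,3.73582e-15
740,2.84345e-15
741,2.16213e-15
742,1.64245e-15
743,1.24646e-15
744,9.45025e-16
745,7.15784e-16
746,5.41623e-16
747,4.09438e-16
748,3.09211e-16
749,2.33291e-16
750,1.75839e-16
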