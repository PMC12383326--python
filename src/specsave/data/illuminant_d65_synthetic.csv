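wavelength_nm,power
380,105.248751
381,105.478942
382,105.704870
383,105.926553
384,106.144008
385,106.357256
386,106.566315
387,106.771203
388,106.971942
389,107.168550
390,107.361048
391,107.549457
392,107.733798
393,107.914090
394,108.090357
395,108.262619
396,108.430899
397,108.595217
398,108.755598
399,108.912063
400,109.064635
401,109.213337
402,109.358191
403,109.499223
404,109.636454
405,109.769908
406,109.899610
407,110.025583
408,110.147852
409,110.266440
410,110.381372
411,110.492673
412,110.600366
413,110.704478
414,110.805032
415,110.902053
416,110.995567
417,111.085599
418,111.172173
419,111.255316
420,111.335051
421,111.411405
422,111.484403
423,111.554071
424,111.620433
425,111.683516
426,111.743345
427,111.799946
428,111.853343
429,111.903564
430,111.950633
431,111.994576
432,112.035419
433,112.073187
434,112.107906
435,112.139601
436,112.168299
437,112.194025
438,112.216803
439,112.236661
440,112.253623
441,112.267715
442,112.278962
443,112.287390
444,112.293023
445,112.295888
446,112.296010
447,112.293413
448,112.288122
449,112.280164
450,112.269562
451,112.256343
452,112.240529
453,112.222148
454,112.201222
455,112.177777
456,112.151838
457,112.123428
458,112.092573
459,112.059296
460,112.023622
461,111.985574
462,111.945178
463,111.902456
464,111.857433
465,111.810133
466,111.760578
467,111.708793
468,111.654801
469,111.598625
470,111.540289
471,111.479816
472,111.417228
473,111.352549
474,111.285801
475,111.217007
476,111.146189
477,111.073371
478,110.998574
479,110.921820
480,110.843132
481,110.762532
482,110.680041
483,110.595680
484,110.509473
485,110.421440
486,110.331602
487,110.239981
488,110.146597
489,110.051473
490,109.954627
491,109.856083
492,109.755858
493,109.653976
494,109.550455
495,109.445315
496,109.338578
497,109.230262
498,109.120388
499,109.008975
500,108.896042
501,108.781610
502,108.665698
503,108.548323
504,108.429507
505,108.309267
506,108.187622
507,108.064590
508,107.940191
509,107.814443
510,107.687363
511,107.558971
512,107.429283
513,107.298317
514,107.166092
515,107.032625
516,106.897932
517,106.762033
518,106.624943
519,106.486679
520,106.347260
521,106.206700
522,106.065017
523,105.922228
524,105.778348
525,105.633394
526,105.487383
527,105.340329
528,105.192249
529,105.043159
530,104.893074
531,104.742009
532,104.589981
533,104.437003
534,104.283091
535,104.128261
536,103.972526
537,103.815902
538,103.658404
539,103.500044
540,103.340839
541,103.180801
542,103.019946
543,102.858287
544,102.695838
545,102.532612
546,102.368623
547,102.203886
548,102.038411
549,101.872215
550,101.705308
551,101.537704
552,101.369417
553,101.200458
554,101.030841
555,100.860578
556,100.689681
557,100.518163
558,100.346035
559,100.173310
560,100.000000
561,99.826116
562,99.651671
563,99.476676
564,99.301142
565,99.125080
566,98.948503
567,98.771420
568,98.593844
569,98.415785
570,98.237254
571,98.058262
572,97.878818
573,97.698935
574,97.518622
575,97.337890
576,97.156748
577,96.975207
578,96.793277
579,96.610967
580,96.428288
581,96.245250
582,96.061861
583,95.878132
584,95.694071
585,95.509689
586,95.324993
587,95.139994
588,94.954701
589,94.769122
590,94.583266
591,94.397142
592,94.210758
593,94.024124
594,93.837247
595,93.650136
596,93.462800
597,93.275246
598,93.087482
599,92.899517
600,92.711358
601,92.523014
602,92.334492
603,92.145800
604,91.956945
605,91.767935
606,91.578777
607,91.389479
608,91.200048
609,91.010491
610,90.820815
611,90.631027
612,90.441135
613,90.251144
614,90.061062
615,89.870896
616,89.680652
617,89.490336
618,89.299956
619,89.109517
620,88.919026
621,88.728490
622,88.537913
623,88.347303
624,88.156665
625,87.966006
626,87.775331
627,87.584647
628,87.393958
629,87.203270
630,87.012590
631,86.821923
632,86.631274
633,86.440648
634,86.250052
635,86.059489
636,85.868967
637,85.678488
638,85.488060
639,85.297686
640,85.107372
641,84.917123
642,84.726943
643,84.536838
644,84.346811
645,84.156868
646,83.967013
647,83.777251
648,83.587587
649,83.398024
650,83.208567
651,83.019220
652,82.829988
653,82.640875
654,82.451885
655,82.263022
656,82.074290
657,81.885693
658,81.697235
659,81.508920
660,81.320751
661,81.132733
662,80.944870
663,80.757164
664,80.569620
665,80.382240
666,80.195030
667,80.007991
668,79.821128
669,79.634444
670,79.447942
671,79.261625
672,79.075497
673,78.889561
674,78.703820
675,78.518278
676,78.332936
677,78.147799
678,77.962869
679,77.778148
680,77.593641
681,77.409350
682,77.225277
683,77.041426
684,76.857799
685,76.674398
686,76.491227
687,76.308288
688,76.125583
689,75.943115
690,75.760887
691,75.578901
692,75.397159
693,75.215663
694,75.034417
695,74.853422
696,74.672681
697,74.492195
698,74.311967
699,74.131999
700,73.952294
701,73.772852
702,73.593677
703,73.414770
704,73.236133
705,73.057769
706,72.879678
707,72.701864
708,72.524327
709,72.347070
710,72.170094
711,71.993401
712,71.816993
713,71.640871
714,71.465038
715,71.289494
716,71.114241
717,70.939282
718,70.764616
719,70.590247
720,70.416175
721,70.242402
722,70.068929
723,69.895758
724,69.722889
725,69.550325
726,69.378067
727,69.206115
728,69.034472
729,68.863138
730,68.692114
731,68.521403
732,68.351004
733,68.180919
734,68.011150
735,67.841696
736,67.672560
737,67.503742
738,67.335244
739,67.167066
740,66.999209
741,66.831674
742,66.664463
743,66.497575
744,66.331013
745,66.164776
746,65.998866
747,65.833283
748,65.668028
749,65.503103
750,65.338507
751,65.174241
752,65.010306
753,64.846704
754,64.683434
755,64.520497
756,64.357893
757,64.195625
758,64.033691
759,63.872092
760,63.710830
761,63.549905
762,63.389316
763,63.229065
764,63.069153
765,62.909579
766,62.750344
767,62.591448
768,62.432893
769,62.274678
770,62.116803
771,61.959270
772,61.802078
773,61.645228
774,61.488720
775,61.332554
776,61.176731
777,61.021251
778,60.866115
779,60.711321
780,60.556872
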