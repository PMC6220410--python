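patient_id,group,gtvm_cm3,gtva_cm3,sensitivity,precision,dsc,msd_mm
D1-01,Database 1,73.1,61.4,0.619,0.736,0.683,4.8
D1-02,Database 1,10.4,8.9,0.759,0.886,0.818,2.1
D1-03,Database 1,3.5,3.7,0.689,0.653,0.670,4.1
D1-04,Database 1,14.5,16.9,0.832,0.715,0.769,2.6
D1-05,Database 1,25.9,22.6,0.736,0.844,0.786,2.5
D1-06,Database 1,27.1,25.7,0.770,0.812,0.791,3.7
D1-07,Database 1,11.8,11.6,0.713,0.723,0.718,7.0
D1-08,Database 1,37.5,28.1,0.422,0.562,0.482,10.3
D1-09,Database 1,65.7,69.5,0.841,0.794,0.817,2.9
D1-10,Database 1,13.3,12.1,0.534,0.588,0.560,11.5
D1-11,Database 1,26.7,26.3,0.787,0.799,0.793,1.8
D1-12,Database 1,17.6,13.5,0.601,0.783,0.680,8.0
D1-13,Database 1,44.0,44.5,0.873,0.863,0.868,1.2
D1-14,Database 1,51.8,48.2,0.788,0.847,0.817,2.5
D1-15,Database 1,73.1,58.2,0.729,0.915,0.812,2.5
D1-16,Database 1,147.5,147.1,0.782,0.784,0.783,2.5
D1-17,Database 1,12.1,14.4,0.820,0.692,0.750,2.6
D2-01,Database 2,24.5,30.7,0.594,0.475,0.528,13.1
D2-02,Database 2,80.4,74.0,0.791,0.859,0.824,1.7
D2-03,Database 2,18.3,20.6,0.918,0.815,0.863,2.9
D2-04,Database 2,18.2,17.3,0.772,0.815,0.793,6.7
D2-05,Database 2,69.8,43.0,0.478,0.775,0.591,6.7
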