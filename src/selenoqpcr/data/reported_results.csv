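gene,region,discovery_percent,replication_percent,combined_percent,discovery_p,replication_p,combined_p,label,note
Th,substantia nigra,-42.5,-68.2,-55.4,<0.05,<0.05,<0.05,significant_down,dopaminergic marker validating the model
Dio1,cerebellum,,,,,,,no_change,
Dio1,substantia nigra,,,,,,,no_change,
Dio1,cortex,,,,,,,no_change,
Dio1,pons,,,,,,,no_change,
Dio1,hippocampus,,,,,,,no_change,
Dio2,cerebellum,,,,,,,no_change,
Dio2,substantia nigra,,,,,,,no_change,
Dio2,cortex,,,,,,,no_change,
Dio2,pons,,,,,,,trend_down,trend of decrease; magnitude not printed
Dio2,hippocampus,,,,,,,no_change,
Dio3,cerebellum,,,,,,,no_change,
Dio3,substantia nigra,,,,,,,no_change,
Dio3,cortex,,,,,,,no_change,
Dio3,pons,,,,,,,no_change,
Dio3,hippocampus,,,,,,,no_change,
Gpx1,cerebellum,,,,,,,no_change,
Gpx1,substantia nigra,,,-20.6,,,<0.05,significant_down,
Gpx1,cortex,,,,,,,no_change,
Gpx1,pons,,,,,,,no_change,
Gpx1,hippocampus,,,-21.1,,,<0.05,significant_down,
Gpx2,cerebellum,,,-17.2,,,<0.05,significant_down,
Gpx2,substantia nigra,,,-21.4,,,=0.17,trend_down,
Gpx2,cortex,,,,,,,no_change,
Gpx2,pons,,,,,,,no_change,
Gpx2,hippocampus,,,-21.8,,,<0.05,significant_down,
Gpx3,cerebellum,,,-43.5,,,<0.05,significant_down,
Gpx3,substantia nigra,,,-39.8,,,<0.05,significant_down,
Gpx3,cortex,,,-18.8,,,=0.11,trend_down,
Gpx3,pons,,,,,,,no_change,
Gpx3,hippocampus,,,-19.5,,,=0.083,trend_down,
Gpx4,cerebellum,,,,,,,no_change,
Gpx4,substantia nigra,,,-28.2,,,<0.05,significant_down,
Gpx4,cortex,,,,,,,no_change,
Gpx4,pons,,,,,,,no_change,
Gpx4,hippocampus,,,,,,,no_change,combined-group p = 0.02 but repeatability gate failed; no combined call
Txnrd1,cerebellum,,,,,,,no_change,
Txnrd1,substantia nigra,,,-30.0,,,<0.05,significant_down,
Txnrd1,cortex,,,16.9,,,<0.05,significant_up,
Txnrd1,pons,,,-16.3,,,<0.05,significant_down,
Txnrd1,hippocampus,,,,,,,no_change,
Txnrd2,cerebellum,,,,,,,no_change,
Txnrd2,substantia nigra,,,-24.2,,,<0.05,significant_down,
Txnrd2,cortex,,,36.7,,,<0.05,significant_up,
Txnrd2,pons,,,24.6,,,<0.05,significant_up,
Txnrd2,hippocampus,,,,,,,no_change,
Txnrd3,cerebellum,,,,,,,no_change,
Txnrd3,substantia nigra,,,,,,,no_change,
Txnrd3,cortex,,,,,,,no_change,
Txnrd3,pons,,,,,,,no_change,
Txnrd3,hippocampus,,,-21.9,,,<0.05,significant_down,
Sep15,cerebellum,,,,,,,no_change,
Sep15,substantia nigra,,,-28.2,,,<0.05,significant_down,
Sep15,cortex,,,,,,,no_change,
Sep15,pons,,,,,,,no_change,
Sep15,hippocampus,,,-18.0,,,<0.05,significant_down,
Selm,cerebellum,,,21.6,,,<0.05,significant_up,
Selm,substantia nigra,,,-15.3,,,<0.05,significant_down,
Selm,cortex,,,-25.9,,,<0.05,significant_down,
Selm,pons,,,,,,,no_change,
Selm,hippocampus,,,,,,,no_change,
Selh,cerebellum,,,22.8,,,=0.062,trend_up,
Selh,substantia nigra,,,-31.3,,,<0.05,significant_down,
Selh,cortex,,,,,,,no_change,
Selh,pons,,,16.2,,,<0.05,significant_up,
Selh,hippocampus,,,,,,,no_change,
Selt,cerebellum,,,,,,,no_change,
Selt,substantia nigra,,,-11.6,,,<0.05,significant_down,
Selt,cortex,,,17.0,,,=0.1,trend_up,
Selt,pons,,,21.8,,,=0.065,trend_up,
Selt,hippocampus,,,,,,,no_change,
Sepw1,cerebellum,,,21.8,,,=0.06,trend_up,
Sepw1,substantia nigra,,,-40.0,,,<0.05,significant_down,
Sepw1,cortex,,,20.5,,,<0.05,significant_up,
Sepw1,pons,,,,,,,no_change,
Sepw1,hippocampus,,,29.3,,,<0.05,significant_up,
Selv,cerebellum,,,,,,,not_detected,not detectable in any brain region
Selv,substantia nigra,,,,,,,not_detected,not detectable in any brain region
Selv,cortex,,,,,,,not_detected,not detectable in any brain region
Selv,pons,,,,,,,not_detected,not detectable in any brain region
Selv,hippocampus,,,,,,,not_detected,not detectable in any brain region
Selk,cerebellum,,,,,,,no_change,
Selk,substantia nigra,,,-23.4,,,<0.05,significant_down,
Selk,cortex,,,,,,,no_change,
Selk,pons,,,,,,,no_change,
Selk,hippocampus,,,,,,,no_change,
Sels,cerebellum,,,,,,,no_change,
Sels,substantia nigra,,,-31.5,,,<0.05,significant_down,
Sels,cortex,,,,,,,no_change,
Sels,pons,,,,,,,no_change,
Sels,hippocampus,,,-14.5,,,=0.16,trend_down,
Seli,cerebellum,,,,,,,no_change,
Seli,substantia nigra,,,-15.0,,,<0.05,significant_down,
Seli,cortex,,,-21.1,,,<0.05,significant_down,
Seli,pons,,,,,,,no_change,
Seli,hippocampus,,,-16.3,,,<0.05,significant_down,
Sepp1,cerebellum,,,,,,,no_change,combined-group p = 0.01 but repeatability gate failed; no combined call
Sepp1,substantia nigra,,,-15.6,,,<0.05,significant_down,
Sepp1,cortex,,,,,,,no_change,combined-group p = 0.04 but repeatability gate failed; no combined call
Sepp1,pons,,,-16.7,,,<0.05,significant_down,
Sepp1,hippocampus,,,,,,,no_change,
Selo,cerebellum,,,29.0,,,<0.05,significant_up,
Selo,substantia nigra,,,-20.8,,,<0.05,significant_down,
Selo,cortex,,,,,,,no_change,
Selo,pons,,,19.4,,,<0.05,significant_up,
Selo,hippocampus,,,,,,,no_change,
Msrb1,cerebellum,,,,,,,no_change,
Msrb1,substantia nigra,,,-19.1,,,<0.05,significant_down,
Msrb1,cortex,,,-12.1,,,<0.05,significant_down,
Msrb1,pons,,,,,,,no_change,
Msrb1,hippocampus,,,19.2,,,<0.05,significant_up,
Sepn1,cerebellum,,,33.2,,,<0.05,significant_up,
Sepn1,substantia nigra,,,,,,,no_change,
Sepn1,cortex,,,,,,,no_change,
Sepn1,pons,,,-15.5,,,<0.05,significant_down,
Sepn1,hippocampus,,,,,,,no_change,
Sephs2,cerebellum,,,12.7,,,<0.05,significant_up,
Sephs2,substantia nigra,,,,,,,no_change,
Sephs2,cortex,,,18.4,,,<0.05,significant_up,
Sephs2,pons,,,,,,,no_change,
Sephs2,hippocampus,,,,,,,no_change,
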