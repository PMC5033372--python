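gene,region,bin
Dio1,cerebellum,barely_detectable
Dio1,substantia nigra,barely_detectable
Dio1,cortex,barely_detectable
Dio1,pons,barely_detectable
Dio1,hippocampus,barely_detectable
Dio2,cerebellum,medium
Dio2,substantia nigra,barely_detectable
Dio2,cortex,medium
Dio2,pons,medium
Dio2,hippocampus,medium
Dio3,cerebellum,barely_detectable
Dio3,substantia nigra,barely_detectable
Dio3,cortex,barely_detectable
Dio3,pons,barely_detectable
Dio3,hippocampus,barely_detectable
Gpx1,cerebellum,medium
Gpx1,substantia nigra,medium
Gpx1,cortex,medium
Gpx1,pons,medium
Gpx1,hippocampus,medium
Gpx2,cerebellum,barely_detectable
Gpx2,substantia nigra,barely_detectable
Gpx2,cortex,barely_detectable
Gpx2,pons,barely_detectable
Gpx2,hippocampus,barely_detectable
Gpx3,cerebellum,barely_detectable
Gpx3,substantia nigra,low
Gpx3,cortex,barely_detectable
Gpx3,pons,low
Gpx3,hippocampus,barely_detectable
Gpx4,cerebellum,high
Gpx4,substantia nigra,high
Gpx4,cortex,high
Gpx4,pons,high
Gpx4,hippocampus,high
Txnrd1,cerebellum,low
Txnrd1,substantia nigra,low
Txnrd1,cortex,low
Txnrd1,pons,medium
Txnrd1,hippocampus,low
Txnrd2,cerebellum,barely_detectable
Txnrd2,substantia nigra,barely_detectable
Txnrd2,cortex,barely_detectable
Txnrd2,pons,barely_detectable
Txnrd2,hippocampus,barely_detectable
Txnrd3,cerebellum,barely_detectable
Txnrd3,substantia nigra,barely_detectable
Txnrd3,cortex,barely_detectable
Txnrd3,pons,barely_detectable
Txnrd3,hippocampus,barely_detectable
Sep15,cerebellum,high
Sep15,substantia nigra,high
Sep15,cortex,high
Sep15,pons,high
Sep15,hippocampus,high
Selm,cerebellum,high
Selm,substantia nigra,high
Selm,cortex,high
Selm,pons,high
Selm,hippocampus,high
Selh,cerebellum,high
Selh,substantia nigra,medium
Selh,cortex,low
Selh,pons,medium
Selh,hippocampus,low
Selt,cerebellum,medium
Selt,substantia nigra,medium
Selt,cortex,medium
Selt,pons,medium
Selt,hippocampus,medium
Sepw1,cerebellum,high
Sepw1,substantia nigra,high
Sepw1,cortex,high
Sepw1,pons,high
Sepw1,hippocampus,high
Selv,cerebellum,barely_detectable
Selv,substantia nigra,barely_detectable
Selv,cortex,barely_detectable
Selv,pons,barely_detectable
Selv,hippocampus,barely_detectable
Selk,cerebellum,high
Selk,substantia nigra,medium
Selk,cortex,medium
Selk,pons,high
Selk,hippocampus,medium
Sels,cerebellum,low
Sels,substantia nigra,low
Sels,cortex,low
Sels,pons,low
Sels,hippocampus,low
Seli,cerebellum,low
Seli,substantia nigra,low
Seli,cortex,low
Seli,pons,low
Seli,hippocampus,medium
Sepp1,cerebellum,high
Sepp1,substantia nigra,high
Sepp1,cortex,high
Sepp1,pons,high
Sepp1,hippocampus,high
Selo,cerebellum,low
Selo,substantia nigra,low
Selo,cortex,low
Selo,pons,low
Selo,hippocampus,low
Msrb1,cerebellum,low
Msrb1,substantia nigra,low
Msrb1,cortex,low
Msrb1,pons,low
Msrb1,hippocampus,low
Sepn1,cerebellum,low
Sepn1,substantia nigra,low
Sepn1,cortex,barely_detectable
Sepn1,pons,barely_detectable
Sepn1,hippocampus,barely_detectable
Sephs2,cerebellum,low
Sephs2,substantia nigra,low
Sephs2,cortex,low
Sephs2,pons,low
Sephs2,hippocampus,low
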