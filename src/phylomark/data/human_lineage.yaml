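# The 31-clade NCBI taxonomy lineage of Homo sapiens (taxid 9606), with
# approximate TimeTree divergence ages in million years ago (Mya).
# Edit ages freely: this file is the calibration input, not a constant.
clades:
- {name: cellular organisms, node_id: 131567, age_mya: 4250.0}
- {name: Eukaryota, node_id: 2759, age_mya: 2100.0}
- {name: Opisthokonta, node_id: 33154, age_mya: 1300.0}
- {name: Metazoa, node_id: 33208, age_mya: 800.0}
- {name: Eumetazoa, node_id: 6072, age_mya: 700.0}
- {name: Bilateria, node_id: 33213, age_mya: 650.0}
- {name: Deuterostomia, node_id: 33511, age_mya: 600.0}
- {name: Chordata, node_id: 7711, age_mya: 550.0}
- {name: Craniata, node_id: 89593, age_mya: 535.0}
- {name: Vertebrata, node_id: 7742, age_mya: 525.0}
- {name: Gnathostomata, node_id: 7776, age_mya: 465.0}
- {name: Teleostomi, node_id: 117570, age_mya: 440.0}
- {name: Euteleostomi, node_id: 117571, age_mya: 430.0}
- {name: Sarcopterygii, node_id: 8287, age_mya: 415.0}
- {name: Dipnotetrapodomorpha, node_id: 1338369, age_mya: 410.0}
- {name: Tetrapoda, node_id: 32523, age_mya: 355.0}
- {name: Amniota, node_id: 32524, age_mya: 320.0}
- {name: Mammalia, node_id: 40674, age_mya: 180.0}
- {name: Theria, node_id: 32525, age_mya: 160.0}
- {name: Eutheria, node_id: 9347, age_mya: 105.0}
- {name: Boreoeutheria, node_id: 1437010, age_mya: 96.0}
- {name: Euarchontoglires, node_id: 314146, age_mya: 90.0}
- {name: Primates, node_id: 9443, age_mya: 74.0}
- {name: Haplorrhini, node_id: 376913, age_mya: 63.0}
- {name: Simiiformes, node_id: 314293, age_mya: 43.0}
- {name: Catarrhini, node_id: 9526, age_mya: 29.0}
- {name: Hominoidea, node_id: 314295, age_mya: 20.0}
- {name: Hominidae, node_id: 9604, age_mya: 16.0}
- {name: Homininae, node_id: 207598, age_mya: 9.0}
- {name: Homo, node_id: 9605, age_mya: 3.0}
- {name: Homo sapiens, node_id: 9606, age_mya: 0.0}
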