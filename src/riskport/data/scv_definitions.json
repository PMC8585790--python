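{
  "description": "Built-in single clinical variant definitions: Finnish founder FH variants in LDLR, the two thrombophilia variants (F5 Leiden, F2), and the SLCO1B1 statin-transporter pharmacogenetic variant. Coordinates are 1-based GRCh38 (HGVS g.); maf is the Finnish risk-allele frequency, null where not established here.",
  "variants": [
    {
      "id": "F5_Leiden",
      "chrom": "1",
      "pos": 169549811,
      "ref": "C",
      "alt": "T",
      "risk_allele": "T",
      "maf": 0.02,
      "category": "VTE",
      "hgvs": "NC_000001.11:g.169549811C>T"
    },
    {
      "id": "F2",
      "chrom": "11",
      "pos": 46739505,
      "ref": "G",
      "alt": "A",
      "risk_allele": "A",
      "maf": 0.0046,
      "category": "VTE",
      "hgvs": "NC_000011.10:g.46739505G>A"
    },
    {
      "id": "FH_Turku",
      "chrom": "19",
      "pos": 11129654,
      "ref": "G",
      "alt": "A",
      "risk_allele": "A",
      "maf": null,
      "category": "FH",
      "hgvs": "NC_000019.10:g.11129654G>A"
    },
    {
      "id": "FH_Pori",
      "chrom": "19",
      "pos": 11113293,
      "ref": "T",
      "alt": "A",
      "risk_allele": "A",
      "maf": null,
      "category": "FH",
      "hgvs": "NC_000019.10:g.11113293T>A"
    },
    {
      "id": "FH_Pogosta",
      "chrom": "19",
      "pos": 11116937,
      "ref": "G",
      "alt": "A",
      "risk_allele": "A",
      "maf": 0.0002,
      "category": "FH",
      "hgvs": "NC_000019.10:g.11116937G>A"
    },
    {
      "id": "SLCO1B1_rs4149056",
      "chrom": "12",
      "pos": 21178615,
      "ref": "T",
      "alt": "C",
      "risk_allele": "C",
      "maf": 0.21,
      "category": "pharmacogenetic",
      "hgvs": "NC_000012.12:g.21178615T>C"
    }
  ]
}
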