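# mtDNA (cyt b, 327 bp) simulated under the speciation history inferred
# from nuclear loci: isolation without gene flow, haploid deme sizes.
# Times in generations (1 generation = 1 year), sizes in gene copies.
name: rhinella_mtdna
focal: SCH
generation_time: 1.0
demes:
  - {name: LAB, size: 69000, samples: 22}
  - {name: RAB, size: 190000, samples: 43}
  - {name: SCH, size: 143000, samples: 27}
events:
  - {time: 325000, sources: [LAB, RAB], dest: ANC1, dest_size: 63000}
  - {time: 1690000, sources: [ANC1, SCH], dest: ROOT, dest_size: 103000}
mutation:
  mu: 0.69e-8        # substitutions / site / year
  L: 327
  ts_proportion: 0.9
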