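"""Generate synthetic studies and score the cytonuclear-discordance signature.

Compares the two generator modes: ``concordant`` (all loci follow the
species history) versus ``mtdna_capture`` (the RAB mitochondrial lineage
derives from R. schneideri).  For each mode the script reconstructs a
NJ/K2P tree per locus and reports whether the pooled R. marina sample
(LAB+RAB) is monophyletic.
"""

from cytodiscord.synth import StudyScenario, discordance_signature, generate_study

for mode in ("concordant", "mtdna_capture"):
    data = generate_study(StudyScenario(mode=mode, seed=42))
    sig = discordance_signature(data)
    calls = ", ".join(
        f"{name}={'mono' if v else 'NON-mono'}"
        for name, v in sig["marina_monophyly"].items()
    )
    print(f"mode={mode:>13}: marina monophyly per locus: {calls}")
    print(f"{'':>19} discordant signature: {sig['discordant']}")

print("\nIn mtdna_capture mode the marina sample is non-monophyletic at "
      "cyt b (SCH haplotypes nest inside RAB) while nuclear loci keep the "
      "species split — the study's fingerprint of mtDNA introgression.")
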