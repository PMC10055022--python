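"""Genotype the male-sterility locus with the in-silico CAPS assay.

Builds a synthetic fertile/sterile allele pair of the myb80-like gene (the
sterile allele carries the 4-nt AATT insertion that creates a Tru1I site),
amplifies both with the published primer pair, digests, and calls the
genotype from the band pattern: one ~300 bp band = MsMs (fertile), three
bands = Msms (fertile carrier), two bands at ~230/~70 bp = msms (sterile).
"""

from hybridplan import TRU1I, assay_diploid, digest, in_silico_pcr, synth_myb80_locus

locus = synth_myb80_locus(seed=1)

for name, template in [("fertile (Ms)", locus.fertile), ("sterile (ms)", locus.sterile)]:
    amp = in_silico_pcr(template, locus.fwd, locus.rev)[0]
    frags = digest(amp.sequence, TRU1I)
    print(f"{name}: amplicon {amp.length} bp -> fragments {frags}")

print()
for genotype in ("MsMs", "Msms", "msms"):
    a1, a2 = locus.alleles_for(genotype)
    call = assay_diploid(a1, a2, locus.fwd, locus.rev)
    print(f"true {genotype}: bands {call.bands} -> called {call.genotype} ({call.phenotype})")
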