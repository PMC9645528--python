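"""Published oligonucleotide substrates used in worked examples.

These are the synthesized RNA substrates from the structural / EMSA work on
mouse Dicer: two natural pre-miRNA precursors and two perfect-duplex
stem-loops capped by a GCAA tetraloop. They serve as ground-truth inputs
for the hairpin-geometry functions.
"""

# 59-nt mouse pre-miR-15a. The Dicer cleavage sites sit between bases
# G22/G23 (3' end of the 5p arm) and G37/C38 (5' end of the 3p arm),
# releasing a 22-nt duplex and a 15-nt loop.
PRE_MIR_15A = "UAGCAGCACAUAAUGGUUUGUGGAUGUUGAAAAGGUGCAGGCCAUACUGUGCUGCCUCA"
PRE_MIR_15A_CUT5 = 22   # last nucleotide of the 5p strand
PRE_MIR_15A_CUT3 = 38   # first nucleotide of the 3p strand

# 62-nt mouse pre-miR-145a. The canonical 3p arm (GGAUUCCUGGAAAUACUGUUCU)
# starts at precursor-local position 39; the 5p arm ends at position 22.
# A 2-nt-shorter 3p isomiR — its 5' end at the A at position 41, after the
# two G:C-paired guanosines — becomes highly abundant in Dicer helicase
# mutants, i.e. a +2 shift of the 3p 5'-end cleavage point.
PRE_MIR_145A = "GUCCAGUUUUCCCAGGAAUCCCUUGGAUGCUAAGAUGGGGAUUCCUGGAAAUACUGUUCUUG"
PRE_MIR_145A_CP_5P3 = 22
PRE_MIR_145A_CP_3P5 = 39
PRE_MIR_145A_ISOMIR_SHIFT = 2

# Perfect Watson-Crick stem-loops with a GCAA tetraloop and a 3' UU
# overhang, used as binding substrates ("30bp stem-loop", "42bp stem-loop").
STEMLOOP_30BP = (
    "AGAGGAGAGGGACAAUCAUAAAGGCCACUCGCAAGAGUGGCCUUUAUGAUUGUCCCUCUCCUCUUU"
)
STEMLOOP_42BP = (
    "AGAGGAGAGGGACAAUAGAGGAGAGGGACAAUCAUAAAGGCCGCAA"
    "GGCCUUUAUGAUUGUCCCUCUCCUCUAUUGUCCCUCUCCUCUUU"
)
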