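"""Experimentally characterised FXR response-element sequences.

These constants are the published, wet-lab-validated reference sequences the
package uses as worked examples and regression fixtures: the conserved
first-intron IR1 element of NDRG2 (human/mouse/rat), the human-specific
second IR1-like element, the 66 bp wild-type and IR1-mutated NDRG2 luciferase
reporter inserts, the IBABP tandem-IR1 reporter insert, and the ChIP-PCR
primer pair flanking the human NDRG2 intronic IR1 region.

The IBABP insert is given as its printed 60 nt top strand; the cloned
fragment is described as 68 bp counting the restriction-site overhangs of
the duplex, which are not part of the scanned sequence.
"""

IR1_HALFSITE = "[GA]GGT[TC]A"

#: conserved intronic IR1 present in human, mouse and rat NDRG2 (exact consensus)
NDRG2_IR1 = "GGGTTAGTGACCC"

#: second, human-specific IR1-like element just downstream (1 mismatch)
NDRG2_IR1_LIKE = "AGGTTGATGACCC"

#: reported gene-relative start of the intronic IR1 per species (+1 convention)
NDRG2_IR1_OFFSETS = {"human": 1560, "mouse": 757, "rat": 1394}

#: 66 bp wild-type NDRG2 response-element reporter insert (top strand)
NDRG2_RE_INSERT = (
    "GTACCACACTGGGGA" "GGGTTAGTGACC" "CGAGG" "AGGTTGATGACCC" "TGGGAGTCTGGGTCTTGGCTC"
)

#: 66 bp NDRG2 insert with both IR1 sites mutated (top strand)
NDRG2_RE_MUT_INSERT = (
    "GTACCACACTGGGGA" "CCC" "TTAGTGA" "GGGGAGG" "AGGTTGATGA" "GGGTGGGAGTCTGGGTCTTGGCTC"
)

#: IBABP tandem-IR1 reporter insert, printed top strand (each element carries
#: one mismatch to the consensus, at the 5th half-site position)
IBABP_INSERT = (
    "CCCCA" "GGGTGAATAACCT" "CGGGGCTCTGTCCCTCCAATCCCA" "GGGTGAATAACCT" "CGGGA"
)

#: single IBABP IR1-type element (1 mismatch to the consensus)
IBABP_IR1 = "GGGTGAATAACCT"

#: ChIP-PCR primers flanking the human NDRG2 first-intron IR1 region
CHIP_FORWARD_PRIMER = "GAACTGATGCCCTTGTAGCC"
CHIP_REVERSE_PRIMER = "CAACGAGGTGAATGACATGG"

#: reported amplicon size of the ChIP primer pair on the human locus (bp)
CHIP_AMPLICON_BP = 196
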