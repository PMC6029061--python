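LOCUS       SYN000001                471 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  ..
ACCESSION   SYN000001
VERSION     SYN000001.1
KEYWORDS    .
SOURCE      .
  ORGANISM  Synthetica exempli
            .
FEATURES             Location/Qualifiers
     source          1..471
                     /organism="Synthetica exempli"
                     /organelle="mitochondrion"
     gene            31..207
                     /gene="gen1"
     CDS             31..207
                     /gene="gen1"
                     /transl_table=1
                     /codon_start=1
     RNA_editing     64
                     /direction=C_to_U
                     /applied="yes"
     RNA_editing     118
                     /direction=C_to_U
                     /applied="yes"
     RNA_editing     160
                     /direction=C_to_U
                     /applied="yes"
     gene            238..441
                     /gene="gen2"
     CDS             238..441
                     /gene="gen2"
                     /transl_table=1
                     /codon_start=1
     RNA_editing     254
                     /direction=C_to_U
                     /applied="yes"
     RNA_editing     307
                     /direction=C_to_U
                     /applied="yes"
     RNA_editing     317
                     /direction=C_to_U
                     /applied="yes"
ORIGIN
        1 aggcttgtta aaatcactcc gccgctgata atggttaatt actcctccgg aatttgtcct
       61 acaccaccta gcatacccat gcgtcgactc gcacgctcgt tcaggtccac gttagtcccg
      121 gggttaagta gtttagtcac aatgtttccg ctatgcgctc ccaggttttt aaccttcggt
      181 acgctttcta gcagttattc attctaagga ctcatcctgg tatgggggtc ccgctgtatg
      241 tggctagagc cctccgattc ggtagtggat acgcggaatg gaggtccaaa cagaggcctt
      301 ctatcgctct taaagccacg ctcgatggga gcaacggaac caacaaacca cttacgagtt
      361 acagttttcc ccctccgatt agtaaatcta ggggaagttt ctagggtata caatcgttac
      421 ttcagatccg cgtccctgta agtctgaccg ccttcaccag cgtcagagct g
//
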