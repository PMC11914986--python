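band_cm-1,band_end_cm-1,substance
600,,Nucleotide
856,,Collagen
918,,"Proline, hydroxyproline acid"
1019,,Symmetrically telescopic C-C skeleton
1204,,Amide III
1224,,Amide III (beta-sheet structure)
1242,1266,Amide III collagen
1309,,Phosphodiester group in nucleic acid
1360,,Tryptophan
1654,,Deformed C-H (protein)
1684,,Amide I nu(C=O)
1687,,Tryptophan
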