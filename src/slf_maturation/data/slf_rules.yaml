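# Boolean ROI recipes for virtual dissection of the three SLF branches.
# Each rule keeps a streamline iff it visits EVERY include ROI ('AND')
# and touches NO exclude ROI ('NOT').  The neonatal protocol differs from
# the adult one only in the SLF II inclusion pair: the posterior
# middle-frontal box (MFg-P) replaces the parietal ROI, because neonatal
# SLF II streamlines do not yet reach the parietal cortex.
adult:
  SLF_I_L:   {include: [PaL, SFgL],      exclude: [TeL, Midsag]}
  SLF_II_L:  {include: [PaL, MFgL],      exclude: [TeL, Midsag]}
  SLF_III_L: {include: [PaL, PrgL],      exclude: [TeL, Midsag]}
  SLF_I_R:   {include: [PaR, SFgR],      exclude: [TeR, Midsag]}
  SLF_II_R:  {include: [PaR, MFgR],      exclude: [TeR, Midsag]}
  SLF_III_R: {include: [PaR, PrgR],      exclude: [TeR, Midsag]}
neonate:
  SLF_I_L:   {include: [PaL, SFgL],      exclude: [TeL, Midsag]}
  SLF_II_L:  {include: [MFgL-P, MFgL],   exclude: [TeL, Midsag]}
  SLF_III_L: {include: [PaL, PrgL],      exclude: [TeL, Midsag]}
  SLF_I_R:   {include: [PaR, SFgR],      exclude: [TeR, Midsag]}
  SLF_II_R:  {include: [MFgR-P, MFgR],   exclude: [TeR, Midsag]}
  SLF_III_R: {include: [PaR, PrgR],      exclude: [TeR, Midsag]}
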