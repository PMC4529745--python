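# Curated subcellular-location vocabulary -> package category scheme.
#
# Keys are lower-cased UniProt location terms (the phrase before any
# topology clause); values are LocationCategory names. The table is total
# by construction: any term absent here maps to the UNMAPPED sentinel and
# is retained verbatim, never dropped. Shipped as data so a vocabulary
# revision is a config update, not a code change.
version: 1
terms:
  secreted: SECRETED
  extracellular: SECRETED
  extracellular space: SECRETED
  extracellular matrix: SECRETED
  cell membrane: PLASMA_MEMBRANE
  plasma membrane: PLASMA_MEMBRANE
  cytoplasm: CYTOPLASM
  cytosol: CYTOPLASM
  cytoskeleton: CYTOSKELETON
  cytoplasm, cytoskeleton: CYTOSKELETON
  endoplasmic reticulum: ER_LUMEN
  endoplasmic reticulum lumen: ER_LUMEN
  endoplasmic reticulum membrane: ER_MEMBRANE
  sarcoplasmic reticulum: ER_LUMEN
  golgi apparatus: GOLGI_LUMEN
  golgi apparatus lumen: GOLGI_LUMEN
  golgi apparatus membrane: GOLGI_MEMBRANE
  nucleus: NUCLEAR_NONMEMBRANE
  nucleolus: NUCLEAR_NONMEMBRANE
  nucleoplasm: NUCLEAR_NONMEMBRANE
  nucleus membrane: NUCLEAR_MEMBRANE
  nuclear membrane: NUCLEAR_MEMBRANE
  nucleus envelope: NUCLEAR_MEMBRANE
  mitochondrion: MITO_NONMEMBRANE
  mitochondrion matrix: MITO_NONMEMBRANE
  mitochondrion membrane: MITO_MEMBRANE
  mitochondrion inner membrane: MITO_MEMBRANE
  mitochondrion outer membrane: MITO_MEMBRANE
  vacuole: VACUOLE_NONMEMBRANE
  vacuole membrane: VACUOLE_MEMBRANE
  lysosome: LYSOSOME
  lysosome membrane: LYSOSOME
  peroxisome: PEROXISOME
  membrane: OTHER_MEMBRANE
  gpi-anchor: GPI_ANCHORED
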