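# Default 12 -> 6 subcellular-compartment merge scheme.
# Seven fine-grained compartments collapse into "secretory-pathway";
# the remaining five raw labels map to a major label of their own
# (plasma membrane is shortened to "membrane").  Users may supply an
# alternative YAML with the same raw-label -> major-label shape.
extracellular: extracellular
plasma membrane: membrane
cytoplasm: cytoplasm
mitochondria: mitochondria
nucleus: nucleus
Golgi apparatus: secretory-pathway
endoplasmic reticulum: secretory-pathway
endosome: secretory-pathway
peroxisome: secretory-pathway
lysosome: secretory-pathway
vacuole: secretory-pathway
vesicles: secretory-pathway
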