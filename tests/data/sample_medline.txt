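PMID- 101
TI  - MEK1 phosphorylates ERK2 in vitro.
AB  - We show that MEK1 directly phosphorylates ERK2. The interaction
      requires the kinase domain.
MH  - Protein Binding
MH  - MAP Kinase Signaling System

PMID- 102
TI  - Expression profiling of murine liver tissue.
AB  - Liver samples were profiled across three developmental stages.
MH  - Mice
MH  - Gene Expression Profiling

PMID- 103
TI  - A note on sample preparation.
AB  -
MH  - Specimen Handling
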