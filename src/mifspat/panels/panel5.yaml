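# Panel 5 — myeloid suppressor cell phenotypes
panel_id: "5"
markers: [CK, Arg-1, CD11b, CD14, CD33, CD66b, CD68]
phenotypes:
  - name: CK+
    description: All malignant cells
  - name: CD68+
    description: All TAMs
  - name: CD68+Arg-1+
    description: TAM type II
  - name: CD68+CD11b+
    description: Dendritic macrophages
  - name: CD11b+CD66b+
    description: Polymorphonuclear leukocyte (PMN)
  - name: CD11b+Arg-1+CD14+CD33+
    description: Monocytic myeloid-derived suppressor cells (MDSC-M)
  - name: CD11b+CD66b+CD33+
    description: Granulocytic myeloid-derived suppressor cells (MDSC-PMN)
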