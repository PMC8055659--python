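# Panel 2 — activation and regulation of T cells (GBZ = granzyme B)
panel_id: "2"
markers: [CK, CD3, CD8, CD45RO, GBZ, FOXP3]
phenotypes:
  - name: CK+
    description: All malignant cells
  - name: CD3+
    description: All T lymphocytes
  - name: CD3+CD8+
    description: Cytotoxic T-cells
  - name: CD3+CD8+GBZ+
    description: Activated cytotoxic T-cells
  - name: CD3+CD45RO+
    description: Memory T-cells
  - name: CD3+CD8+CD45RO+
    description: Effector/memory T-cells
  - name: CD3+FOXP3+CD8-
    description: Regulatory T-cells
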