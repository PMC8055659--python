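# Panel 1 — PD-L1/PD-1 axis and T cells
panel_id: "1"
markers: [CK, CD3, CD8, PD-1, PD-L1, CD68]
phenotypes:
  - name: CK+
    description: All malignant cells
  - name: CK+PD-L1+
    description: All malignant cells expressing PD-L1
  - name: CD3+
    description: All T lymphocytes
  - name: CD3+CD8+
    description: Cytotoxic T-cells
  - name: CD3+PD-1+
    description: Antigen experienced T-cells
  - name: CD3+CD8+PD-1+
    description: Cytotoxic T-cells antigen experienced
  - name: CD68+
    description: All tumor associated macrophages (TAMs)
  - name: CD68+PD-L1+
    description: TAM expressing PD-L1
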