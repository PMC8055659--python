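# Panel 3 — immune checkpoint markers expressed by malignant cells
panel_id: "3"
markers: [CK, CD3, PD-L1, B7-H3, B7-H4, IDO-1, CD68]
phenotypes:
  - name: CK+
    description: All malignant cells
  - name: CK+PD-L1+
    description: Malignant cells expressing PD-L1
  - name: CK+B7-H3+
    description: Malignant cells expressing B7-H3
  - name: CK+B7-H4+
    description: Malignant cells expressing B7-H4
  - name: CK+IDO-1+
    description: Malignant cells expressing IDO-1
  - name: CD3+
    description: All T lymphocytes
  - name: CD3+PD-L1+
    description: T-cells expressing PD-L1
  - name: CD3+B7-H3+
    description: T-cells expressing B7-H3
  - name: CD3+B7-H4+
    description: T-cells expressing B7-H4
  - name: CD3+IDO-1+
    description: T-cells expressing IDO-1
  - name: CD68+
    description: All TAMs
  - name: CD68+PD-L1+
    description: TAM expressing PD-L1
  - name: CD68+B7-H3+
    description: TAM expressing B7-H3
  - name: CD68+B7-H4+
    description: TAM expressing B7-H4
  - name: CD68+IDO-1+
    description: TAM expressing IDO-1
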