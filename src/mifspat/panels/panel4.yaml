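# Panel 4 — costimulatory and inhibitory checkpoints on T cells
panel_id: "4"
markers: [CK, CD3, ICOS, LAG3, OX-40, TIM3, VISTA]
phenotypes:
  - name: CK+
    description: All malignant cells
  - name: CD3+
    description: All T lymphocytes
  - name: CD3+VISTA+
    description: T-cells expressing VISTA
  - name: CD3+ICOS+
    description: T-cells expressing ICOS
  - name: CD3+LAG3+
    description: T-cells expressing LAG3
  - name: CD3+OX-40+
    description: T-cells expressing OX-40
  - name: CD3+TIM3+
    description: T-cells expressing TIM3
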