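{
  "model_id": "fig4a",
  "title": "neuron_to_neuron_agnostic",
  "metadata": {
    "template": "neuron_to_neuron_agnostic"
  },
  "individuals": [
    {
      "id": "0006830#1",
      "class": "WBbt:0006830"
    },
    {
      "id": "0051899#1",
      "class": "GO:0051899"
    },
    {
      "id": "0051899#2",
      "class": "GO:0051899"
    },
    {
      "id": "VC_neuron#1",
      "class": "CeNCAM:VC_neuron"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "0006830#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Collins2016"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0051899#1",
      "rel": "RO:0002304",
      "o": "0051899#2",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Collins2016"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0051899#2",
      "rel": "BFO:0000066",
      "o": "VC_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Collins2016"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
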