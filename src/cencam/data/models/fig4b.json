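{
  "model_id": "fig4b",
  "title": "neuron_to_neuron_synaptic",
  "metadata": {
    "template": "neuron_to_neuron_synaptic"
  },
  "individuals": [
    {
      "id": "0006830#1",
      "class": "WBbt:0006830"
    },
    {
      "id": "0007268#1",
      "class": "GO:0007268"
    },
    {
      "id": "0051899#1",
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
      "s": "0007268#1",
      "rel": "BFO:0000066",
      "o": "VC_neuron#1",
      "evidence": [
        {
          "eco": "CeNCAM:synaptic_transmission_inhibition_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0007268#1",
      "rel": "RO:0002305",
      "o": "0051899#1",
      "evidence": [
        {
          "eco": "CeNCAM:synaptic_transmission_inhibition_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "0006830#1",
      "evidence": [
        {
          "eco": "CeNCAM:synaptic_transmission_inhibition_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
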