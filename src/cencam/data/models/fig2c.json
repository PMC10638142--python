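{
  "model_id": "fig2c",
  "title": "neuron_to_behavior_activation",
  "metadata": {
    "template": "neuron_to_behavior_activation"
  },
  "individuals": [
    {
      "id": "0006791#1",
      "class": "WBbt:0006791"
    },
    {
      "id": "0018991#1",
      "class": "GO:0018991"
    },
    {
      "id": "0051899#1",
      "class": "GO:0051899"
    },
    {
      "id": "negative_regulation_of_egg_deposition#1",
      "class": "CeNCAM:negative_regulation_of_egg_deposition"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "0006791#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Banerjee2017"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0051899#1",
      "rel": "BFO:0000050",
      "o": "negative_regulation_of_egg_deposition#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Banerjee2017"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "negative_regulation_of_egg_deposition#1",
      "rel": "BFO:0000050",
      "o": "0018991#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Banerjee2017"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
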