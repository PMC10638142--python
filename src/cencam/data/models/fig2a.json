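{
  "model_id": "fig2a",
  "title": "neuron_to_behavior_ablation",
  "metadata": {
    "template": "neuron_to_behavior_ablation"
  },
  "individuals": [
    {
      "id": "0006830#1",
      "class": "WBbt:0006830"
    },
    {
      "id": "0009987#1",
      "class": "GO:0009987"
    },
    {
      "id": "0018991#1",
      "class": "GO:0018991"
    },
    {
      "id": "positive_regulation_of_egg_deposition#1",
      "class": "CeNCAM:positive_regulation_of_egg_deposition"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0009987#1",
      "rel": "BFO:0000066",
      "o": "0006830#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Waggoner1998"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0009987#1",
      "rel": "RO:0002418",
      "o": "positive_regulation_of_egg_deposition#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Waggoner1998"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "positive_regulation_of_egg_deposition#1",
      "rel": "BFO:0000050",
      "o": "0018991#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Waggoner1998"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
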