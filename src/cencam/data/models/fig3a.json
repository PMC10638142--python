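{
  "model_id": "fig3a",
  "title": "input_neuron_behavior_rescue",
  "metadata": {
    "template": "input_neuron_behavior_rescue"
  },
  "individuals": [
    {
      "id": "0004993#1",
      "class": "GO:0004993"
    },
    {
      "id": "0006917#1",
      "class": "WBbt:0006917"
    },
    {
      "id": "0018991#1",
      "class": "GO:0018991"
    },
    {
      "id": "0098664#1",
      "class": "GO:0098664"
    },
    {
      "id": "28790#1",
      "class": "CHEBI:28790"
    },
    {
      "id": "99000001#1",
      "class": "WBGene:99000001"
    },
    {
      "id": "positive_regulation_of_egg_deposition#1",
      "class": "CeNCAM:positive_regulation_of_egg_deposition"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0004993#1",
      "rel": "RO:0012001",
      "o": "28790#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0004993#1",
      "rel": "RO:0002333",
      "o": "99000001#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0004993#1",
      "rel": "BFO:0000050",
      "o": "0098664#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "0098664#1",
      "rel": "BFO:0000066",
      "o": "0006917#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a5",
      "s": "0098664#1",
      "rel": "BFO:0000050",
      "o": "positive_regulation_of_egg_deposition#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a6",
      "s": "positive_regulation_of_egg_deposition#1",
      "rel": "BFO:0000050",
      "o": "0018991#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
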