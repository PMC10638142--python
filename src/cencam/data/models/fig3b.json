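{
  "model_id": "fig3b",
  "title": "npr-1 in URX rescues carbon dioxide avoidance",
  "metadata": {},
  "individuals": [
    {
      "id": "0004930#1",
      "class": "GO:0004930"
    },
    {
      "id": "0030522#1",
      "class": "GO:0030522"
    },
    {
      "id": "0050924#1",
      "class": "GO:0050924"
    },
    {
      "id": "0170015#1",
      "class": "GO:0170015"
    },
    {
      "id": "16526#1",
      "class": "CHEBI:16526"
    },
    {
      "id": "99000002#1",
      "class": "WBGene:99000002"
    },
    {
      "id": "URX_neuron#1",
      "class": "CeNCAM:URX_neuron"
    },
    {
      "id": "behavioral_response_to_carbon_dioxide#1",
      "class": "CeNCAM:behavioral_response_to_carbon_dioxide"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0170015#1",
      "rel": "RO:0012001",
      "o": "16526#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0170015#1",
      "rel": "BFO:0000050",
      "o": "0050924#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0004930#1",
      "rel": "RO:0002333",
      "o": "99000002#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "0004930#1",
      "rel": "BFO:0000050",
      "o": "0030522#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a5",
      "s": "0030522#1",
      "rel": "BFO:0000066",
      "o": "URX_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a6",
      "s": "0030522#1",
      "rel": "BFO:0000050",
      "o": "0050924#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a7",
      "s": "0050924#1",
      "rel": "BFO:0000050",
      "o": "behavioral_response_to_carbon_dioxide#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carrillo2013"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
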