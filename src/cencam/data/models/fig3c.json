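{
  "model_id": "fig3c",
  "title": "AFD response to carbon dioxide removal",
  "metadata": {},
  "individuals": [
    {
      "id": "0038023#1",
      "class": "GO:0038023"
    },
    {
      "id": "0051899#1",
      "class": "GO:0051899"
    },
    {
      "id": "16526#1",
      "class": "CHEBI:16526"
    },
    {
      "id": "AFD_neuron#1",
      "class": "CeNCAM:AFD_neuron"
    },
    {
      "id": "behavioral_response_to_carbon_dioxide#1",
      "class": "CeNCAM:behavioral_response_to_carbon_dioxide"
    },
    {
      "id": "decreasing_amount#1",
      "class": "CeNCAM:decreasing_amount"
    },
    {
      "id": "exposure_to_decreasing_carbon_dioxide#1",
      "class": "CeNCAM:exposure_to_decreasing_carbon_dioxide"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0038023#1",
      "rel": "RO:0002233",
      "o": "16526#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0038023#1",
      "rel": "BFO:0000050",
      "o": "0051899#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "AFD_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "0051899#1",
      "rel": "BFO:0000050",
      "o": "behavioral_response_to_carbon_dioxide#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a5",
      "s": "exposure_to_decreasing_carbon_dioxide#1",
      "rel": "RO:0000086",
      "o": "decreasing_amount#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
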