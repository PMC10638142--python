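{
  "model_id": "fig6c",
  "title": "food and CO2 signal integration",
  "metadata": {},
  "individuals": [
    {
      "id": "0007165#1",
      "class": "GO:0007165"
    },
    {
      "id": "0007165#2",
      "class": "GO:0007165"
    },
    {
      "id": "0038023#1",
      "class": "GO:0038023"
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
      "id": "99000004#1",
      "class": "WBGene:99000004"
    },
    {
      "id": "BAG_neuron#1",
      "class": "CeNCAM:BAG_neuron"
    },
    {
      "id": "behavioral_response_to_carbon_dioxide#1",
      "class": "CeNCAM:behavioral_response_to_carbon_dioxide"
    },
    {
      "id": "signal_integration_process#1",
      "class": "CeNCAM:signal_integration_process"
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
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0170015#1",
      "rel": "BFO:0000050",
      "o": "0007165#1",
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
      "s": "0038023#1",
      "rel": "RO:0002333",
      "o": "99000004#1",
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
      "s": "0038023#1",
      "rel": "BFO:0000050",
      "o": "0007165#1",
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
      "s": "0007165#1",
      "rel": "BFO:0000066",
      "o": "BAG_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a6",
      "s": "0007165#1",
      "rel": "BFO:0000050",
      "o": "signal_integration_process#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a7",
      "s": "0007165#2",
      "rel": "BFO:0000050",
      "o": "signal_integration_process#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bretscher2011"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a8",
      "s": "signal_integration_process#1",
      "rel": "BFO:0000050",
      "o": "behavioral_response_to_carbon_dioxide#1",
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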