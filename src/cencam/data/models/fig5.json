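{
  "model_id": "fig5",
  "title": "egg-laying circuit compilation",
  "metadata": {},
  "individuals": [
    {
      "id": "00006600#1",
      "class": "WBGene:00006600"
    },
    {
      "id": "0004510#1",
      "class": "GO:0004510"
    },
    {
      "id": "0004993#1",
      "class": "GO:0004993"
    },
    {
      "id": "0006830#1",
      "class": "WBbt:0006830"
    },
    {
      "id": "0006917#1",
      "class": "WBbt:0006917"
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
      "id": "0038023#1",
      "class": "GO:0038023"
    },
    {
      "id": "0042427#1",
      "class": "GO:0042427"
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
      "id": "0098664#1",
      "class": "GO:0098664"
    },
    {
      "id": "0099589#1",
      "class": "GO:0099589"
    },
    {
      "id": "28790#1",
      "class": "CHEBI:28790"
    },
    {
      "id": "28790#2",
      "class": "CHEBI:28790"
    },
    {
      "id": "99000001#1",
      "class": "WBGene:99000001"
    },
    {
      "id": "99000003#1",
      "class": "WBGene:99000003"
    },
    {
      "id": "AWC_neuron#1",
      "class": "CeNCAM:AWC_neuron"
    },
    {
      "id": "VC_neuron#1",
      "class": "CeNCAM:VC_neuron"
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
      "o": "AWC_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Chase2004"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0038023#1",
      "rel": "RO:0002333",
      "o": "99000003#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Chase2004"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0038023#1",
      "rel": "BFO:0000050",
      "o": "0009987#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Chase2004"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "0009987#1",
      "rel": "RO:0002212",
      "o": "0051899#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Chase2004"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a5",
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
      "id": "a6",
      "s": "0042427#1",
      "rel": "BFO:0000066",
      "o": "0006830#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a7",
      "s": "0004510#1",
      "rel": "RO:0002333",
      "o": "00006600#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a8",
      "s": "0004510#1",
      "rel": "BFO:0000050",
      "o": "0042427#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a9",
      "s": "0042427#1",
      "rel": "RO:0002234",
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
      "id": "a10",
      "s": "0042427#1",
      "rel": "RO:0002234",
      "o": "28790#2",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a11",
      "s": "0099589#1",
      "rel": "RO:0012001",
      "o": "28790#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Collins2016"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a12",
      "s": "0099589#1",
      "rel": "BFO:0000050",
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
      "id": "a13",
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
    },
    {
      "id": "a14",
      "s": "0051899#1",
      "rel": "RO:0002213",
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
      "id": "a15",
      "s": "0051899#2",
      "rel": "RO:0002212",
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
      "id": "a16",
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
      "id": "a17",
      "s": "0004993#1",
      "rel": "RO:0012001",
      "o": "28790#2",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Carnell2005"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a18",
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
      "id": "a19",
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
      "id": "a20",
      "s": "0051899#1",
      "rel": "RO:0002213",
      "o": "0098664#1",
      "evidence": [
        {
          "eco": "ECO:0006033",
          "reference": "Collins2016"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a21",
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
      "id": "a22",
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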