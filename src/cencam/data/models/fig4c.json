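{
  "model_id": "fig4c",
  "title": "vesicle loading mechanism of BAG-to-RIA activation",
  "metadata": {},
  "individuals": [
    {
      "id": "0005313#1",
      "class": "GO:0005313"
    },
    {
      "id": "0007268#1",
      "class": "GO:0007268"
    },
    {
      "id": "0008066#1",
      "class": "GO:0008066"
    },
    {
      "id": "0030672#1",
      "class": "GO:0030672"
    },
    {
      "id": "0051899#1",
      "class": "GO:0051899"
    },
    {
      "id": "99000006#1",
      "class": "WBGene:99000006"
    },
    {
      "id": "99000007#1",
      "class": "WBGene:99000007"
    },
    {
      "id": "BAG_neuron#1",
      "class": "CeNCAM:BAG_neuron"
    },
    {
      "id": "RIA_neuron#1",
      "class": "CeNCAM:RIA_neuron"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0005313#1",
      "rel": "RO:0002333",
      "o": "99000007#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0005313#1",
      "rel": "BFO:0000066",
      "o": "0030672#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0005313#1",
      "rel": "BFO:0000050",
      "o": "0007268#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "0007268#1",
      "rel": "BFO:0000066",
      "o": "BAG_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a5",
      "s": "0005313#1",
      "rel": "RO:0002304",
      "o": "0008066#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a6",
      "s": "0008066#1",
      "rel": "RO:0002333",
      "o": "99000006#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a7",
      "s": "0008066#1",
      "rel": "BFO:0000050",
      "o": "0051899#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a8",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "RIA_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Choi2021"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
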