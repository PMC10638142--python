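{
  "model_id": "fig2b",
  "title": "acetylcholine biosynthesis in VC regulates egg laying",
  "metadata": {},
  "individuals": [
    {
      "id": "0008292#1",
      "class": "GO:0008292"
    },
    {
      "id": "0018991#1",
      "class": "GO:0018991"
    },
    {
      "id": "0061526#1",
      "class": "GO:0061526"
    },
    {
      "id": "VC_neuron#1",
      "class": "CeNCAM:VC_neuron"
    },
    {
      "id": "negative_regulation_of_egg_deposition#1",
      "class": "CeNCAM:negative_regulation_of_egg_deposition"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0008292#1",
      "rel": "BFO:0000066",
      "o": "VC_neuron#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bany2003"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0008292#1",
      "rel": "RO:0002304",
      "o": "0061526#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bany2003"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0061526#1",
      "rel": "BFO:0000050",
      "o": "negative_regulation_of_egg_deposition#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bany2003"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "negative_regulation_of_egg_deposition#1",
      "rel": "BFO:0000050",
      "o": "0018991#1",
      "evidence": [
        {
          "eco": "ECO:0000059",
          "reference": "Bany2003"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
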