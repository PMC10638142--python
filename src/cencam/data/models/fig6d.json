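{
  "model_id": "fig6d",
  "title": "co-ordination of VM activity with locomotion",
  "metadata": {},
  "individuals": [
    {
      "id": "0006917#1",
      "class": "WBbt:0006917"
    },
    {
      "id": "0007626#1",
      "class": "GO:0007626"
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
      "id": "behavior_co_ordination_process#1",
      "class": "CeNCAM:behavior_co_ordination_process"
    }
  ],
  "assertions": [
    {
      "id": "a1",
      "s": "0051899#1",
      "rel": "BFO:0000066",
      "o": "0006917#1",
      "evidence": [
        {
          "eco": "CeNCAM:mechanical_perturbation_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a2",
      "s": "0051899#1",
      "rel": "BFO:0000050",
      "o": "behavior_co_ordination_process#1",
      "evidence": [
        {
          "eco": "CeNCAM:mechanical_perturbation_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a3",
      "s": "0007626#1",
      "rel": "BFO:0000050",
      "o": "behavior_co_ordination_process#1",
      "evidence": [
        {
          "eco": "CeNCAM:mechanical_perturbation_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    },
    {
      "id": "a4",
      "s": "behavior_co_ordination_process#1",
      "rel": "BFO:0000050",
      "o": "0018991#1",
      "evidence": [
        {
          "eco": "CeNCAM:mechanical_perturbation_evidence",
          "reference": "Kopchock2021"
        }
      ],
      "provenance": "asserted"
    }
  ]
}
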