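Local ID	Reference	Author Statement	Node 1	Relation 1	Node 2	Relation 2	Node 3	Relation 3	Node 4
EL12	Banerjee2017	Light stimulation of uv1 immediately following the initial egg-laying event significantly delays subsequent egg-laying events; uv1-mediated inhibition of egg-laying promotes periods of quiescence.	GO:0051899	BFO:0000066	WBbt:0006791	BFO:0000050	CeNCAM:negative_regulation_of_egg_deposition	BFO:0000050	GO:0018991
EL01	Waggoner1998	Elimination of the HSNs caused a substantial lengthening of the inactive phase and a slower overall rate of egg laying; the HSNs stimulate egg laying by inducing the active state.	GO:0009987	BFO:0000066	WBbt:0006830	RO:0002418	CeNCAM:positive_regulation_of_egg_deposition	BFO:0000050	GO:0018991
EL01	Waggoner1998	Elimination of the HSNs decreased the frequency of egg-laying clusters but did not slow the egg-laying rate within clusters.	GO:0009987	BFO:0000066	WBbt:0006830	RO:0002418	CeNCAM:positive_regulation_of_egg_deposition	BFO:0000050	GO:0018991
EL07	Kopchock2021	Blocking VC synaptic transmission with tetanus toxin increased HSN calcium transient frequency, consistent with VC neurotransmission being inhibitory toward the HSNs.	GO:0007268	BFO:0000066	CeNCAM:VC_neuron	RO:0002305	GO:0051899	BFO:0000066	WBbt:0006830
CA03	Bretscher2011	Restoring tax-2 to the BAG neurons rescued CO2 avoidance on food but not off food, implicating BAG in CO2 avoidance behavior.	GO:0007165	BFO:0000066	CeNCAM:BAG_neuron	BFO:0000050	CeNCAM:signal_integration_process	BFO:0000050	CeNCAM:behavioral_response_to_carbon_dioxide
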