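# Synthetic fixture: hand-derived mini-connectome covering the neurons of
# the worked CO2-avoidance / egg-laying overlay example.  Edges are
# illustrative of the described topology (ASH synaptically upstream of HSN;
# the HSN/VC/VM egg-laying motor group; sensory neurons feeding forward),
# not an electron-microscopy reconstruction.
pre	post	kind	weight
ASH	HSN	chemical_synapse	3
AWC	ASH	chemical_synapse	2
BAG	ASH	chemical_synapse	1
AFD	BAG	chemical_synapse	1
HSN	VC	chemical_synapse	4
VC	HSN	chemical_synapse	2
HSN	VM	chemical_synapse	6
VC	VM	chemical_synapse	5
uv1	VM	chemical_synapse	1
uv1	VM	gap_junction	2
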