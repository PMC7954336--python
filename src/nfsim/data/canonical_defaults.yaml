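# Canonical rate constants (s^-1), speeds (um/s unless noted) and axon
# geometry (um) for the node/internode NF transport models.
gamma_10: 0.14
gamma_01: 0.064
gamma_off: 0.00445
gamma_ra: 1.4e-5
gamma_ar: 4.2e-6
v_a: 0.52
v_r: -0.36
# on-track rates of the six-state chain (selected by phospho label in the
# six-with-phospho variant): slow = phosphorylated/internode, fast =
# dephosphorylated/node
gamma_on_internode: 2.75e-4
gamma_on_node: 5.16e-3
# phosphorylation / dephosphorylation rates per region
gamma_ph_internode: 0.8
gamma_de_internode: 0.1
gamma_ph_node: 0.1
gamma_de_node: 0.8
# eight-state on-track rates; gamma_on2 values quoted from the velocity
# reconstruction at v_internode and v_node = 7.6 x v_internode
gamma_on1: 2.75e-4
gamma_on2_internode: 5.16e-3
gamma_on2_node: 6.01e-2
v_internode_mm_day: 1.01
v_node_factor: 7.6
# axon geometry: node of Ranvier occupies [node_start, node_end)
axon_length: 50.0
node_start: 20.0
node_end: 30.0
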